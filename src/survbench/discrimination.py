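"""Censoring-aware discrimination metrics.

Two complementary views of a risk score's ranking ability:

* Harrell's C-index uses the full censored cohort. Over every *comparable*
  patient pair (the patient with the shorter follow-up died, so their
  relative ordering is known), it is the fraction in which the
  earlier-dying patient carried the higher risk score, with half credit
  for tied scores.
* Fixed-time ROC/AUC treats death by a horizon ``t`` as a binary outcome
  on the *evaluable* subset (patients whose status at ``t`` is known), so
  AUC = P(score_case > score_control) + 0.5 * P(tie).

Confidence intervals come from a stratified bootstrap (resampling cases
and controls separately) or, for AUC, from the DeLong large-sample
covariance estimator.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve

from .cohort import label_at_horizon

__all__ = [
    "RocResult",
    "ConcordanceResult",
    "roc_auc",
    "auc_confidence_interval",
    "harrell_c",
    "concordance_confidence_interval",
    "subgroup_auc",
    "age_tertile_groups",
]


@dataclasses.dataclass(frozen=True)
class RocResult:
    auc: float
    ci_low: float
    ci_high: float
    roc_points: np.ndarray  # (m, 2) array of (fpr, tpr), (0,0) -> (1,1)
    thresholds: np.ndarray
    n_cases: int
    n_controls: int


@dataclasses.dataclass(frozen=True)
class ConcordanceResult:
    c_index: float
    ci_low: float
    ci_high: float
    n_comparable_pairs: int
    n_concordant_pairs: int
    n_tied_score_pairs: int


def _check_binary(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise ValueError("AUC undefined: need at least one case and one control")
    return labels


def roc_auc(scores, labels) -> RocResult:
    """Rank-based AUC with the full ROC curve, higher score = higher risk.

    The AUC equals the trapezoidal area under the returned ROC points and,
    identically, the Mann-Whitney pair statistic with half credit for ties.
    No confidence interval is attached (``ci_low``/``ci_high`` are NaN);
    see :func:`auc_confidence_interval`.
    """
    scores = np.asarray(scores, dtype=float)
    labels = _check_binary(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    fpr, tpr, thr = roc_curve(labels, scores, drop_intermediate=False)
    points = np.column_stack([fpr, tpr])
    auc = float(np.trapezoid(tpr, fpr))
    return RocResult(
        auc=auc,
        ci_low=float("nan"),
        ci_high=float("nan"),
        roc_points=points,
        thresholds=thr,
        n_cases=int(labels.sum()),
        n_controls=int((~labels).sum()),
    )


def _auc_point(scores: np.ndarray, labels: np.ndarray) -> float:
    # Mann-Whitney via midranks; equals the trapezoidal ROC area.
    r = stats.rankdata(scores)
    n1 = labels.sum()
    n0 = labels.size - n1
    return float((r[labels].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def _delong_variance(scores: np.ndarray, labels: np.ndarray) -> float:
    cases = scores[labels]
    ctrls = scores[~labels]
    m, n = cases.size, ctrls.size
    # placement values: P(case beats a control) per case, and vice versa
    psi = (cases[:, None] > ctrls[None, :]).astype(float)
    psi += 0.5 * (cases[:, None] == ctrls[None, :])
    v10 = psi.mean(axis=1)
    v01 = psi.mean(axis=0)
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return s10 / m + s01 / n


def auc_confidence_interval(
    scores,
    labels,
    method: str = "bootstrap",
    n_boot: int = 2000,
    seed: int = 0,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """95% (by default) CI for the fixed-time AUC.

    ``bootstrap`` draws ``n_boot`` stratified resamples (cases and controls
    resampled separately, preserving class sizes) and takes percentile
    endpoints; ``analytic`` is the DeLong large-sample normal interval.
    """
    scores = np.asarray(scores, dtype=float)
    labels = _check_binary(labels)
    if method == "analytic":
        auc = _auc_point(scores, labels)
        z = stats.norm.ppf(1 - alpha / 2)
        se = np.sqrt(_delong_variance(scores, labels))
        return (max(0.0, auc - z * se), min(1.0, auc + z * se))
    if method != "bootstrap":
        raise ValueError(f"unknown method {method!r}")
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    rng = np.random.default_rng(seed)
    cases = scores[labels]
    ctrls = scores[~labels]
    m, n = cases.size, ctrls.size
    boots = np.empty(n_boot)
    for b in range(n_boot):
        cs = cases[rng.integers(0, m, m)]
        ct = ctrls[rng.integers(0, n, n)]
        bl = np.concatenate([np.ones(m, bool), np.zeros(n, bool)])
        boots[b] = _auc_point(np.concatenate([cs, ct]), bl)
    lo, hi = np.percentile(boots, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


def _concordance_counts(
    scores: np.ndarray, time: np.ndarray, event: np.ndarray
) -> tuple[float, int, int]:
    """(concordance-weighted count, comparable pairs, tied-score pairs).

    Pair (i, j) is comparable when i's death is known to precede j's
    follow-up: time_i < time_j with event_i, or time_i == time_j with
    event_i and not event_j. Tied event times with both events are not
    comparable, per the classical Harrell convention.
    """
    conc = 0.0
    n_comp = 0
    n_tied = 0
    for i in np.flatnonzero(event):
        later = (time > time[i]) | ((time == time[i]) & ~event)
        if not later.any():
            continue
        s_later = scores[later]
        higher = int((scores[i] > s_later).sum())
        ties = int((scores[i] == s_later).sum())
        conc += higher + 0.5 * ties
        n_comp += int(later.sum())
        n_tied += ties
    return conc, n_comp, n_tied


def harrell_c(scores, time, event) -> ConcordanceResult:
    """Harrell's concordance index for right-censored data.

    Higher score must mean higher risk (expected shorter survival). No CI
    is attached (NaN); see :func:`concordance_confidence_interval`.
    """
    scores = np.asarray(scores, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    if not (scores.shape == time.shape == event.shape):
        raise ValueError("scores, time and event must have equal length")
    conc, n_comp, n_tied = _concordance_counts(scores, time, event)
    if n_comp == 0:
        raise ValueError("no comparable pairs (no events, or all times tied events)")
    return ConcordanceResult(
        c_index=conc / n_comp,
        ci_low=float("nan"),
        ci_high=float("nan"),
        n_comparable_pairs=n_comp,
        n_concordant_pairs=int(conc - 0.5 * n_tied),
        n_tied_score_pairs=n_tied,
    )


def concordance_confidence_interval(
    scores, time, event, n_boot: int = 2000, seed: int = 0, alpha: float = 0.05
) -> tuple[float, float]:
    """Percentile bootstrap CI for the C-index (patient-level resampling)."""
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    scores = np.asarray(scores, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    rng = np.random.default_rng(seed)
    n = scores.size
    boots = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        conc, n_comp, _ = _concordance_counts(scores[idx], time[idx], event[idx])
        if n_comp > 0:
            boots.append(conc / n_comp)
    lo, hi = np.percentile(boots, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


def age_tertile_groups(ages: np.ndarray) -> tuple[pd.Series, list[str]]:
    """Split by age into three near-equal groups, ties to the lower group.

    Boundaries are the empirical tertiles (inverse ECDF); labels report the
    observed min-max age within each group.
    """
    ages = np.asarray(ages, dtype=float)
    q1, q2 = np.quantile(ages, [1 / 3, 2 / 3], method="inverted_cdf")
    group = np.where(ages <= q1, 0, np.where(ages <= q2, 1, 2))
    labels = []
    for g in range(3):
        sel = ages[group == g]
        if sel.size:
            labels.append(f"{sel.min():g}-{sel.max():g}")
        else:
            labels.append("empty")
    return pd.Series([labels[g] for g in group]), labels


def subgroup_auc(
    cohort: pd.DataFrame,
    horizon_days: float,
    grouping: str,
    score_columns: tuple[str, ...] = ("eolci_score", "stanford_prob"),
    ci_method: str = "bootstrap",
    n_boot: int = 2000,
    seed: int = 0,
) -> pd.DataFrame:
    """Fixed-time AUC per demographic subgroup for each score.

    ``grouping`` is a categorical column of the cohort, or the rule
    ``"age_tertile"`` which splits the evaluable cohort into three
    near-equal age groups. Groups lacking both a case and a control are
    reported as not estimable (NaN AUC) rather than aborting the run.
    """
    labeled = label_at_horizon(cohort, horizon_days)
    data = labeled.data
    if grouping == "age_tertile":
        groups, _ = age_tertile_groups(data["age"].to_numpy())
        groups.index = data.index
    elif grouping in data.columns:
        groups = data[grouping].astype(str)
    else:
        raise ValueError(f"unknown grouping column {grouping!r}")

    rows = []
    for g in sorted(groups.unique()):
        sub = data.loc[groups == g]
        y = sub["is_case"].to_numpy()
        row: dict = {"group": g, "n": len(sub)}
        for col in score_columns:
            if y.all() or not y.any():
                row[f"{col}_auc"] = np.nan
                row[f"{col}_ci_low"] = np.nan
                row[f"{col}_ci_high"] = np.nan
                row["estimable"] = False
                continue
            s = sub[col].to_numpy(float)
            row[f"{col}_auc"] = roc_auc(s, y).auc
            lo, hi = auc_confidence_interval(
                s, y, method=ci_method, n_boot=n_boot, seed=seed
            )
            row[f"{col}_ci_low"] = lo
            row[f"{col}_ci_high"] = hi
            row.setdefault("estimable", True)
        rows.append(row)
    return pd.DataFrame(rows)
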