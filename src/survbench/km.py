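"""Kaplan-Meier estimation, risk-tertile stratification, follow-up summaries.

The product-limit estimator with Greenwood variance underlies three
reporting needs here: overall survival at fixed horizons with
complementary-log-log confidence bands, survival curves for tertiles of
each risk score (the visual check that a score separates prognosis), and
the reverse-KM median follow-up (the KM median of the censoring
distribution, obtained by flipping the event flag).

The curve itself is fitted with :class:`lifelines.KaplanMeierFitter`;
survival, variance and the bands are derived from its event table, which
applies the standard convention that deaths at a time are processed before
censorings at the same time.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats

__all__ = [
    "KMCurve",
    "SurvivalAt",
    "RiskTertiles",
    "FollowupSummary",
    "km_estimate",
    "km_survival_at",
    "tertile_curves",
    "followup_summary",
    "DAYS_PER_MONTH",
]

DAYS_PER_MONTH = 30.44


@dataclasses.dataclass(frozen=True)
class KMCurve:
    """Product-limit estimate evaluated at the event times.

    ``variance`` is the Greenwood estimate of Var(S_hat) at each event
    time; ``n_at_risk``/``n_events`` come from the underlying life table.
    ``max_observed_time`` marks the end of follow-up (event or censoring),
    beyond which the step function is an extrapolation.
    """

    event_times: np.ndarray
    survival: np.ndarray
    variance: np.ndarray
    n_at_risk: np.ndarray
    n_events: np.ndarray
    max_observed_time: float
    n_subjects: int

    def survival_at(self, t: float) -> float:
        """Step-function evaluation (value at the last event time <= t)."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclasses.dataclass(frozen=True)
class SurvivalAt:
    estimate: float
    ci_low: float
    ci_high: float
    extrapolated: bool = False


@dataclasses.dataclass(frozen=True)
class RiskTertiles:
    """Tertile assignment of a risk score (higher score = higher risk).

    ``boundaries`` are the two inverse-ECDF cut values; assignment ties go
    to the lower-risk group. ``score_ranges`` reports the observed min-max
    of the score within the low, medium and high groups.
    """

    score_name: str
    boundaries: tuple[float, float]
    group: np.ndarray  # 0 = low risk, 1 = medium, 2 = high
    score_ranges: tuple[tuple[float, float], ...]
    labels: tuple[str, ...] = ("low", "medium", "high")


@dataclasses.dataclass(frozen=True)
class FollowupSummary:
    """Follow-up duration in months under three median conventions.

    The estimator behind a reported "median follow-up" is often left
    unstated; all three common variants are given: the plain median over
    all patients, the median among censored patients only, and the
    reverse-KM median (KM median of the censoring distribution).
    """

    median_all: float
    median_censored: float
    reverse_km_median: float
    range: tuple[float, float]


def km_estimate(time, event) -> KMCurve:
    """Kaplan-Meier product-limit estimate with Greenwood variance."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    if time.size == 0:
        raise ValueError("empty input")
    if not (time > 0).all():
        raise ValueError("all times must be positive")
    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=event)
    table = kmf.event_table  # indexed by time; deaths precede censorings
    dead = table["observed"].to_numpy(float)
    at_risk = table["at_risk"].to_numpy(float)
    times = table.index.to_numpy(float)
    has_event = dead > 0
    # product-limit and Greenwood accumulation over event times only
    frac = np.ones_like(dead)
    frac[has_event] = 1.0 - dead[has_event] / at_risk[has_event]
    surv_all = np.cumprod(frac)
    gw_terms = np.zeros_like(dead)
    nz = has_event & (at_risk > dead)
    gw_terms[nz] = dead[nz] / (at_risk[nz] * (at_risk[nz] - dead[nz]))
    # at_risk == dead drives S to 0 with infinite relative variance; the
    # Greenwood sum is conventionally carried forward (variance -> 0 via S^2)
    gw_cum = np.cumsum(gw_terms)
    variance = surv_all**2 * gw_cum
    return KMCurve(
        event_times=times[has_event],
        survival=surv_all[has_event],
        variance=variance[has_event],
        n_at_risk=at_risk[has_event].astype(int),
        n_events=dead[has_event].astype(int),
        max_observed_time=float(time.max()),
        n_subjects=int(time.size),
    )


def km_survival_at(
    curve: KMCurve, t: float, ci: bool = True, alpha: float = 0.05
) -> SurvivalAt:
    """Survival probability at ``t`` with a complementary-log-log CI.

    The band exponentiates a normal interval on log(-log S), keeping the
    endpoints inside (0, 1). Querying beyond the last observed follow-up
    returns the last value with ``extrapolated=True`` and a warning.
    """
    if t < 0:
        raise ValueError("t must be nonnegative")
    extrapolated = t > curve.max_observed_time
    if extrapolated:
        warnings.warn(
            f"t={t} exceeds the last observed follow-up "
            f"({curve.max_observed_time}); the estimate is carried forward",
            stacklevel=2,
        )
    idx = np.searchsorted(curve.event_times, t, side="right") - 1
    if idx < 0:
        s = 1.0
        var = 0.0
    else:
        s = float(curve.survival[idx])
        var = float(curve.variance[idx])
    if not ci or s <= 0.0 or s >= 1.0 or var == 0.0:
        # degenerate band: no events yet (S = 1, var 0) or S has hit 0
        return SurvivalAt(s, s, s, extrapolated)
    z = stats.norm.ppf(1 - alpha / 2)
    se_cloglog = np.sqrt(var) / (s * abs(np.log(s)))
    lo = s ** np.exp(z * se_cloglog)
    hi = s ** np.exp(-z * se_cloglog)
    return SurvivalAt(s, float(lo), float(hi), extrapolated)


def tertile_curves(
    cohort: pd.DataFrame, score_name: str, n_groups: int = 3
) -> tuple[RiskTertiles, list[KMCurve]]:
    """Stratify the whole cohort into score tertiles and fit KM per group.

    Quantile boundaries use the inverse ECDF; patients tied at a boundary
    go to the lower-risk group. ``n_groups`` defaults to tertiles but any
    number of quantile groups (e.g. quartiles) is supported; labels beyond
    three groups are ``q1..qk`` from low to high risk.
    """
    if score_name not in cohort.columns:
        raise ValueError(f"unknown score column {score_name!r}")
    if len(cohort) < n_groups:
        raise ValueError(f"need at least {n_groups} patients")
    scores = cohort[score_name].to_numpy(float)
    qs = np.quantile(
        scores, [(k + 1) / n_groups for k in range(n_groups - 1)],
        method="inverted_cdf",
    )
    group = np.searchsorted(qs, scores, side="left")  # ties to lower group
    if len(np.unique(group)) < n_groups:
        raise ValueError(
            f"too few distinct {score_name!r} values to form {n_groups} nonempty groups"
        )
    curves = []
    ranges = []
    for g in range(n_groups):
        sel = group == g
        ranges.append((float(scores[sel].min()), float(scores[sel].max())))
        curves.append(
            km_estimate(cohort.loc[sel, "followup_days"], cohort.loc[sel, "event"])
        )
    labels = ("low", "medium", "high") if n_groups == 3 else tuple(
        f"q{k + 1}" for k in range(n_groups)
    )
    tertiles = RiskTertiles(
        score_name=score_name,
        boundaries=tuple(float(q) for q in qs),
        group=group,
        score_ranges=tuple(ranges),
        labels=labels,
    )
    return tertiles, curves


def followup_summary(cohort: pd.DataFrame) -> FollowupSummary:
    """Median follow-up (three conventions) and range, in months."""
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    days = cohort["followup_days"].to_numpy(float)
    event = cohort["event"].to_numpy(bool)
    months = days / DAYS_PER_MONTH
    censored = months[~event]
    median_censored = float(np.median(censored)) if censored.size else float("nan")
    # reverse KM: the censoring distribution's KM median (event flag flipped)
    kmf = KaplanMeierFitter()
    kmf.fit(months, event_observed=~event)
    rkm = float(kmf.median_survival_time_)
    return FollowupSummary(
        median_all=float(np.median(months)),
        median_censored=median_censored,
        reverse_km_median=rkm,
        range=(float(months.min()), float(months.max())),
    )
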