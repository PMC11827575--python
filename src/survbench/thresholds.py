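"""Binary high-risk flag diagnostics at a score cutoff.

Given a cutoff on a risk score and case/control labels at a horizon, the
2x2 confusion table yields PPV, sensitivity, specificity, the likelihood
ratios and the diagnostic odds ratio. :func:`matched_count_cutoff` picks a
cutoff for a comparator score so that it flags (as nearly as ties permit)
the same number of patients as a reference flag — the construction used to
compare scores without a pre-specified threshold on one of them. PPV is
strongly prevalence-dependent; the likelihood ratios and the DOR are not,
which is why both families are reported.
"""

from __future__ import annotations

import dataclasses

import numpy as np

__all__ = [
    "ConfusionAtT",
    "MatchedCutoff",
    "flag_high_risk",
    "confusion_metrics",
    "matched_count_cutoff",
    "gini_index",
]


def _ratio(num: float, den: float) -> float:
    """Safe ratio; zero denominator yields NaN ("undefined"), not an error."""
    return num / den if den > 0 else float("nan")


@dataclasses.dataclass(frozen=True)
class ConfusionAtT:
    """2x2 table of a high-risk flag against case/control labels.

    Ratios with a zero denominator are NaN and listed in ``undefined``;
    batch reports render them as "undefined" rather than failing.
    """

    tp: int
    fp: int
    fn: int
    tn: int
    cutoff: float = float("nan")
    horizon_days: float = float("nan")

    @property
    def n_cases(self) -> int:
        return self.tp + self.fn

    @property
    def n_controls(self) -> int:
        return self.fp + self.tn

    @property
    def n_flagged(self) -> int:
        return self.tp + self.fp

    @property
    def ppv(self) -> float:
        return _ratio(self.tp, self.tp + self.fp)

    @property
    def npv(self) -> float:
        return _ratio(self.tn, self.tn + self.fn)

    @property
    def sensitivity(self) -> float:
        return _ratio(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return _ratio(self.tn, self.fp + self.tn)

    @property
    def lr_pos(self) -> float:
        return _ratio(self.sensitivity, 1.0 - self.specificity)

    @property
    def lr_neg(self) -> float:
        return _ratio(1.0 - self.sensitivity, self.specificity)

    @property
    def dor(self) -> float:
        """Diagnostic odds ratio, (tp*tn)/(fp*fn) == lr_pos/lr_neg."""
        return _ratio(self.tp * self.tn, self.fp * self.fn)

    @property
    def undefined(self) -> tuple[str, ...]:
        return tuple(
            name
            for name in ("ppv", "npv", "sensitivity", "specificity",
                         "lr_pos", "lr_neg", "dor")
            if np.isnan(getattr(self, name))
        )

    def as_dict(self) -> dict:
        d = {k: getattr(self, k) for k in ("tp", "fp", "fn", "tn")}
        for k in ("ppv", "npv", "sensitivity", "specificity",
                  "lr_pos", "lr_neg", "dor"):
            v = getattr(self, k)
            d[k] = "undefined" if np.isnan(v) else v
        d["cutoff"] = self.cutoff
        d["horizon_days"] = self.horizon_days
        return d


@dataclasses.dataclass(frozen=True)
class MatchedCutoff:
    cutoff: float
    n_flagged: int
    n_target: int

    @property
    def discrepancy(self) -> int:
        """Signed shortfall: n_flagged - n_target (0 when attained exactly)."""
        return self.n_flagged - self.n_target


def flag_high_risk(scores, cutoff: float, inclusive: bool = True) -> np.ndarray:
    """Boolean high-risk flag: score >= cutoff (inclusive) or > cutoff."""
    scores = np.asarray(scores, dtype=float)
    return scores >= cutoff if inclusive else scores > cutoff


def confusion_metrics(
    flags, labels, cutoff: float = float("nan"), horizon_days: float = float("nan")
) -> ConfusionAtT:
    """Build the 2x2 table of a flag vector against case labels."""
    flags = np.asarray(flags, dtype=bool)
    labels = np.asarray(labels, dtype=bool)
    if flags.shape != labels.shape:
        raise ValueError("flags and labels must have equal length")
    return ConfusionAtT(
        tp=int((flags & labels).sum()),
        fp=int((flags & ~labels).sum()),
        fn=int((~flags & labels).sum()),
        tn=int((~flags & ~labels).sum()),
        cutoff=cutoff,
        horizon_days=horizon_days,
    )


def matched_count_cutoff(scores, n_target: int) -> MatchedCutoff:
    """Largest cutoff whose strictly-greater count is nearest ``n_target``.

    The flag is ``score > cutoff`` (exclusive). With all-distinct scores
    the target is always attainable exactly. Ties at the boundary can make
    it unattainable; then the nearest attainable count is returned,
    preferring the smaller count on equidistance, and ``discrepancy``
    records the difference.
    """
    scores = np.asarray(scores, dtype=float)
    n = scores.size
    if not 1 <= n_target <= n:
        raise ValueError(f"n_target must be in [1, {n}]")
    # candidate cutoffs: every observed level, plus one below the minimum so
    # that flagging everyone (count = n) stays attainable
    levels = np.unique(scores)  # ascending
    levels = np.concatenate([[levels[0] - 1.0], levels])
    # count of scores strictly greater than each candidate cutoff
    counts = n - np.searchsorted(np.sort(scores), levels, side="right")
    # choose nearest attainable count, smaller count on ties, then the
    # largest cutoff achieving it
    best = min(zip(np.abs(counts - n_target), counts), key=lambda t: (t[0], t[1]))[1]
    cutoff = levels[counts == best].max()
    return MatchedCutoff(cutoff=float(cutoff), n_flagged=int(best), n_target=n_target)


def gini_index(auc: float) -> float:
    """Gini index of a score, the AUC rescaled to [-1, 1]: 2*AUC - 1
    (the Somers' D identity)."""
    if not 0.0 <= auc <= 1.0:
        raise ValueError("auc must lie in [0, 1]")
    return 2.0 * auc - 1.0
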