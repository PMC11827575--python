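"""Reference discrete-time survival model and per-patient influence ranking.

The model partitions follow-up into K intervals (default 12 spanning 0-5
years, with 1 year an exact interval edge). A single linear predictor
``lp_i = x_i . beta`` over standardized features feeds K per-interval
logistic hazards

    h_ik = sigmoid(alpha_k - lp_i),

so a *larger* linear predictor means *lower* hazard, i.e. longer predicted
survival — the orientation under which the per-patient influence of
feature ``j`` is simply ``beta_j * x_ij``: positive values push predicted
survival up relative to a "typical" patient sitting at the training mean
(x = 0 after standardization). Survival is the product of interval-wise
complements, S(t_k) = prod_{m<=k} (1 - h_m).

Fitting maximizes the discrete-time censored log likelihood: a patient
contributes log(1 - h_m) for every interval fully survived plus log(h_m)
for the interval containing death; a censored patient contributes only
fully survived intervals (a partially survived final interval contributes
nothing). An L2 penalty on beta (not on the interval intercepts) controls
overfitting; its strength is chosen by patient-level cross-validated
held-out log likelihood.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit

__all__ = [
    "DEFAULT_INTERVAL_EDGES_DAYS",
    "FeatureMatrix",
    "DiscreteTimeSurvModel",
    "InfluenceRanking",
    "standardize",
    "fit_discrete_time_model",
    "data_log_likelihood",
    "select_l2",
    "predict_survival",
    "influence_ranking",
    "aggregate_influences",
]

#: 12 intervals over 0-5 years (in days); 1 year (365 d) is an exact edge.
DEFAULT_INTERVAL_EDGES_DAYS = 365.0 * np.array(
    [0, 0.25, 0.5, 0.75, 1, 1.5, 2, 2.5, 3, 3.5, 4, 4.5, 5]
)


@dataclasses.dataclass(frozen=True)
class FeatureMatrix:
    """Standardized feature matrix with its training-split statistics.

    Standardization uses the *training* mean and SD; missing entries are
    imputed with the training mean, hence are exactly 0 in standardized
    space. Held-out data standardized with training statistics may have
    nonzero column means — no re-centering happens outside training.
    """

    values: np.ndarray  # (n, p), standardized, imputed
    feature_names: tuple[str, ...]
    train_means: np.ndarray
    train_sds: np.ndarray
    dropped: tuple[str, ...] = ()


def standardize(
    raw: np.ndarray | pd.DataFrame,
    feature_names: Sequence[str] | None = None,
    train_means: np.ndarray | None = None,
    train_sds: np.ndarray | None = None,
) -> FeatureMatrix:
    """Center/scale features and mean-impute missing entries.

    Missing values are NaN in ``raw``. With ``train_means``/``train_sds``
    omitted, statistics are computed from ``raw`` itself (the training
    split) over observed entries; zero-variance columns are dropped with a
    warning, except all-missing columns, which are retained as all-zero
    (imputed) with unit scale.
    """
    if isinstance(raw, pd.DataFrame):
        feature_names = tuple(raw.columns.astype(str))
        raw = raw.to_numpy(float)
    else:
        raw = np.asarray(raw, dtype=float)
        if feature_names is None:
            feature_names = tuple(f"x{j}" for j in range(raw.shape[1]))
        feature_names = tuple(feature_names)
    missing = np.isnan(raw)

    if train_means is None or train_sds is None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
            means = np.nanmean(raw, axis=0)
            sds = np.nanstd(raw, axis=0, ddof=0)
        all_missing = missing.all(axis=0)
        means[all_missing] = 0.0
        sds[all_missing] = 1.0
        zero_var = (sds == 0) & ~all_missing
        if zero_var.any():
            names = [feature_names[j] for j in np.flatnonzero(zero_var)]
            warnings.warn(f"dropping zero-variance feature(s): {names}", stacklevel=2)
        keep = ~zero_var
        means, sds = means[keep], sds[keep]
        raw = raw[:, keep]
        missing = missing[:, keep]
        dropped = tuple(feature_names[j] for j in np.flatnonzero(zero_var))
        feature_names = tuple(feature_names[j] for j in np.flatnonzero(keep))
    else:
        train_means = np.asarray(train_means, dtype=float)
        train_sds = np.asarray(train_sds, dtype=float)
        if (train_sds <= 0).any():
            raise ValueError("train_sds must be positive for all retained features")
        means, sds = train_means, train_sds
        dropped = ()

    x = (raw - means) / sds
    x[missing] = 0.0  # training-mean imputation in standardized space
    return FeatureMatrix(
        values=x,
        feature_names=feature_names,
        train_means=means,
        train_sds=sds,
        dropped=dropped,
    )


@dataclasses.dataclass(frozen=True)
class DiscreteTimeSurvModel:
    interval_edges: np.ndarray  # K+1 increasing times starting at 0
    alpha: np.ndarray  # K per-interval hazard intercepts
    beta: np.ndarray  # p feature coefficients (larger lp = longer survival)
    l2_strength: float
    feature_names: tuple[str, ...]
    log_likelihood: float
    n_iter: int
    converged: bool

    @property
    def n_intervals(self) -> int:
        return self.alpha.size

    def linear_predictor(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        return x @ self.beta

    def hazards(self, x: np.ndarray) -> np.ndarray:
        """(n, K) per-interval conditional death probabilities."""
        lp = self.linear_predictor(x)
        return expit(self.alpha[None, :] - lp[:, None])


def _interval_masks(
    time: np.ndarray, event: np.ndarray, edges: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """One-hot death-interval mask and fully-survived-interval mask, (n, K).

    Death in interval m (edges[m-1] < t <= edges[m]) contributes the death
    term there and survival terms for earlier intervals. A censored patient
    contributes survival terms for every interval whose right edge is at or
    below the censoring time; the partially lived final interval is ignored
    (the conservative convention). Follow-up beyond the last edge counts as
    surviving every interval whatever the event flag.
    """
    K = edges.size - 1
    n = time.size
    died = np.zeros((n, K))
    surv = np.zeros((n, K))
    right = edges[1:]
    beyond = time > right[-1]
    death_iv = np.searchsorted(right, time, side="left")  # valid where ~beyond
    n_full = np.searchsorted(right, time, side="right")  # intervals fully lived
    col = np.arange(K)
    ev_in = event & ~beyond
    died[np.flatnonzero(ev_in), death_iv[ev_in]] = 1.0
    surv_count = np.where(ev_in, death_iv, n_full)
    surv_count = np.where(beyond, K, surv_count)
    surv = (col[None, :] < surv_count[:, None]).astype(float)
    return died, surv


def _neg_penalized_loglik(
    params: np.ndarray,
    X: np.ndarray,
    died: np.ndarray,
    surv: np.ndarray,
    l2: float,
    K: int,
):
    alpha = params[:K]
    beta = params[K:]
    lp = X @ beta
    eta = alpha[None, :] - lp[:, None]
    h = expit(eta)
    eps = 1e-12
    ll = float(np.sum(died * np.log(h + eps) + surv * np.log(1 - h + eps)))
    pen = l2 * float(beta @ beta)
    # gradient wrt eta: died*(1-h) - surv*h
    g_eta = died * (1.0 - h) - surv * h
    g_alpha = g_eta.sum(axis=0)
    g_beta = -X.T @ g_eta.sum(axis=1) - 2.0 * l2 * beta
    grad = np.concatenate([g_alpha, g_beta])
    return -(ll - pen), -grad


def data_log_likelihood(
    model: DiscreteTimeSurvModel, x: np.ndarray, time, event
) -> float:
    """Unpenalized discrete-time log likelihood of data under the model."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    died, surv = _interval_masks(time, event, model.interval_edges)
    h = model.hazards(np.atleast_2d(x))
    eps = 1e-12
    return float(np.sum(died * np.log(h + eps) + surv * np.log(1 - h + eps)))


def fit_discrete_time_model(
    features: FeatureMatrix | np.ndarray,
    time,
    event,
    interval_edges: np.ndarray = DEFAULT_INTERVAL_EDGES_DAYS,
    l2_strength: float = 0.0,
    max_iter: int = 500,
) -> DiscreteTimeSurvModel:
    """Fit by deterministic quasi-Newton (L-BFGS-B) from zero initialization.

    With no features the optimum is the interval-wise empirical life-table
    hazard (deaths over at-risk per interval). The L2 penalty applies to
    the feature coefficients only, never to the interval intercepts.
    """
    if isinstance(features, FeatureMatrix):
        X = features.values
        names = features.feature_names
    else:
        X = np.asarray(features, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if X.size == 0:
            X = X.reshape(len(np.asarray(time)), 0)
        names = tuple(f"x{j}" for j in range(X.shape[1]))
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    edges = np.asarray(interval_edges, dtype=float)
    if edges[0] != 0 or not (np.diff(edges) > 0).all():
        raise ValueError("interval_edges must increase from 0")
    if l2_strength < 0:
        raise ValueError("l2_strength must be nonnegative")
    if not event.any():
        raise ValueError("need at least one event to fit")

    K = edges.size - 1
    died, surv = _interval_masks(time, event, edges)
    x0 = np.zeros(K + X.shape[1])
    res = minimize(
        _neg_penalized_loglik,
        x0,
        args=(X, died, surv, l2_strength, K),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "ftol": 1e-12, "gtol": 1e-10},
    )
    if not res.success and "REL_REDUCTION" not in str(res.message):
        raise RuntimeError(
            f"discrete-time model did not converge within {max_iter} iterations: "
            f"{res.message} (|grad|={np.max(np.abs(res.jac)):.3g})"
        )
    alpha = res.x[:K]
    beta = res.x[K:]
    pen = l2_strength * float(beta @ beta)
    return DiscreteTimeSurvModel(
        interval_edges=edges,
        alpha=alpha,
        beta=beta,
        l2_strength=l2_strength,
        feature_names=names,
        log_likelihood=float(-res.fun) + pen,
        n_iter=int(res.nit),
        converged=True,
    )


def select_l2(
    features: FeatureMatrix | np.ndarray,
    time,
    event,
    interval_edges: np.ndarray = DEFAULT_INTERVAL_EDGES_DAYS,
    grid: Sequence[float] = (0.0, 0.1, 1.0, 10.0, 100.0),
    n_folds: int = 5,
    seed: int = 0,
) -> float:
    """Cross-validated L2 strength: maximal mean held-out log likelihood.

    Folds are patient-level and seeded. A fold whose training split has no
    events triggers a refold with a new seed; after 3 attempts an error is
    raised. Exact ties in held-out likelihood resolve to the larger
    penalty (the more conservative model).
    """
    if len(grid) == 0:
        raise ValueError("grid must be nonempty")
    if n_folds < 2:
        raise ValueError("n_folds must be at least 2")
    X = features.values if isinstance(features, FeatureMatrix) else np.asarray(features, float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    n = time.size

    folds = None
    for attempt in range(3):
        rng = np.random.default_rng(seed + attempt)
        perm = rng.permutation(n)
        candidate = np.array_split(perm, n_folds)
        if all(event[np.setdiff1d(perm, f)].any() for f in candidate):
            folds = candidate
            break
    if folds is None:
        raise ValueError("could not form folds with events in every training split")

    edges = np.asarray(interval_edges, dtype=float)
    mean_ll = []
    for l2 in grid:
        held_out = []
        for test_idx in folds:
            train_idx = np.setdiff1d(np.arange(n), test_idx)
            model = fit_discrete_time_model(
                X[train_idx], time[train_idx], event[train_idx], edges, l2
            )
            died, surv = _interval_masks(time[test_idx], event[test_idx], edges)
            h = model.hazards(X[test_idx])
            eps = 1e-12
            held_out.append(
                float(np.sum(died * np.log(h + eps) + surv * np.log(1 - h + eps)))
            )
        mean_ll.append(float(np.mean(held_out)))
    # ties -> larger penalty
    best = max(zip(mean_ll, grid), key=lambda t: (t[0], t[1]))
    return float(best[1])


def predict_survival(model: DiscreteTimeSurvModel, x: np.ndarray, t: float) -> float:
    """Survival probability at ``t`` for one patient.

    Exact product of interval complements at interval edges; strictly
    inside an interval the log-survival is interpolated linearly between
    the bracketing edges. ``t`` beyond the last edge is an error.
    """
    edges = model.interval_edges
    if t < 0:
        raise ValueError("t must be nonnegative")
    if t > edges[-1]:
        raise ValueError(f"t={t} beyond the model horizon {edges[-1]}")
    h = model.hazards(np.atleast_2d(x))[0]
    log_s_edges = np.concatenate([[0.0], np.cumsum(np.log1p(-h))])
    k = np.searchsorted(edges, t, side="left")
    if edges[k] == t:
        return float(np.exp(log_s_edges[k]))
    frac = (t - edges[k - 1]) / (edges[k] - edges[k - 1])
    log_s = log_s_edges[k - 1] + frac * (log_s_edges[k] - log_s_edges[k - 1])
    return float(np.exp(log_s))


@dataclasses.dataclass(frozen=True)
class InfluenceRanking:
    """Top-k signed feature influences ``beta_j * x_ij`` for one patient.

    ``positive`` lists the features pushing predicted survival up the most
    (largest products), ``negative`` those pulling it down (smallest).
    Zero-influence features (at the training mean or imputed) never enter
    either list; a patient sitting entirely at the training mean has empty
    lists and ``uninformative=True``.
    """

    positive: tuple[tuple[str, float], ...]
    negative: tuple[tuple[str, float], ...]

    @property
    def uninformative(self) -> bool:
        return not self.positive and not self.negative


def influence_ranking(
    model: DiscreteTimeSurvModel, x: np.ndarray, k: int = 5
) -> InfluenceRanking:
    """Rank features by their signed influence on one patient's prediction.

    Ties are broken by feature index. ``k`` beyond the feature count
    truncates with a warning.
    """
    if k < 1:
        raise ValueError("k must be at least 1")
    x = np.asarray(x, dtype=float).ravel()
    p = model.beta.size
    if x.size != p:
        raise ValueError(f"expected {p} features, got {x.size}")
    if k > p:
        warnings.warn(f"k={k} exceeds {p} features; truncating", stacklevel=2)
        k = p
    infl = model.beta * x
    order = np.lexsort((np.arange(p), -infl))  # descending, index breaks ties
    pos = [(model.feature_names[j], float(infl[j])) for j in order[:k] if infl[j] > 0]
    order_neg = np.lexsort((np.arange(p), infl))  # ascending
    neg = [(model.feature_names[j], float(infl[j])) for j in order_neg[:k] if infl[j] < 0]
    return InfluenceRanking(positive=tuple(pos), negative=tuple(neg))


def aggregate_influences(rankings: Sequence[InfluenceRanking]) -> pd.DataFrame:
    """Cohort-level frequency of top-k appearances per feature and direction.

    Returns one row per (direction, feature) sorted by count descending —
    how many patients had the feature among their strongest
    survival-improving (direction "positive") or survival-worsening
    ("negative") influences.
    """
    counts: dict[tuple[str, str], int] = {}
    for r in rankings:
        for name, _ in r.positive:
            counts[("positive", name)] = counts.get(("positive", name), 0) + 1
        for name, _ in r.negative:
            counts[("negative", name)] = counts.get(("negative", name), 0) + 1
    rows = [
        {"direction": d, "feature": f, "n_patients": c}
        for (d, f), c in counts.items()
    ]
    df = pd.DataFrame(rows, columns=["direction", "feature", "n_patients"])
    return df.sort_values(
        ["direction", "n_patients", "feature"], ascending=[False, False, True]
    ).reset_index(drop=True)
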