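"""Synthetic cohorts with analytically controlled discrimination.

The generator emulates the statistical structure the validation pipeline
assumes: an outpatient oncology-like cohort with ~23% 1-year mortality
among evaluable patients, right censoring, two positively correlated risk
scores of configurable discrimination, demographic strata, and (for the
modeling stage) a standardized feature matrix with known coefficients.

Construction. Each patient carries a latent risk ``u ~ N(0, 1)``; the
death time is exponential with rate ``baseline_hazard * exp(frailty_sd *
u)`` and censoring is an independent (or, when
``informative_censoring_strength > 0``, u-tilted) exponential truncated at
an administrative cutoff. Each risk score is a binormal blend ``s = w*u +
sqrt(1 - w^2)*eps``. Because everything downstream of ``u`` has closed
form, the evaluable-set AUC of such a score at the calibration horizon is
a two-dimensional Gauss-Hermite integral, and the latent weight ``w``
achieving a target AUC is found by root-finding on that exact expression —
the generator's discrimination is calibrated, not tuned by trial. The
baseline hazard achieving a target evaluable-set prevalence is found the
same way.

Score A is emitted as a 0-100 integer (rank-preserving probit scaling,
emulating an integer risk index; the discretization attenuates its AUC by
well under 0.01 at 101 levels). Score B is mapped through the true
exponential model to a 1-year death probability in [0, 1]. Demographics
are sampled independently of risk.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm

from .cohort import validate_cohort

__all__ = [
    "SyntheticConfig",
    "FeatureCohort",
    "generate_cohort",
    "generate_feature_cohort",
    "prevalence_sweep",
    "calibrate_score_weight",
    "tune_baseline_hazard",
    "evaluable_auc",
    "DEFAULT_DEMOGRAPHICS",
]

#: Demographic strata mirroring a large academic oncology outpatient mix.
DEFAULT_DEMOGRAPHICS: dict[str, dict[str, float]] = {
    "sex": {"Female": 0.55, "Male": 0.45},
    "race": {
        "White": 0.52,
        "Asian": 0.26,
        "Other/multiple": 0.17,
        "Black": 0.03,
        "Unknown": 0.02,
    },
    "ethnicity": {"Not Hispanic": 0.85, "Hispanic": 0.13, "Unknown": 0.02},
    "clinic": {
        "Thoracic": 0.30,
        "Breast": 0.25,
        "Urologic": 0.20,
        "Gynecologic": 0.15,
        "Head and neck": 0.10,
    },
}


@dataclasses.dataclass
class SyntheticConfig:
    """Generator parameters; the defaults are the reference study conditions.

    ``baseline_hazard=None`` means: tune it so that the 1-year mortality
    among evaluable patients equals ``target_prevalence`` (default 23%).
    ``censoring_rate`` defaults to ~8% of patients censored within the
    first year, and the administrative cutoff to ~33 months — the
    follow-up pattern of a two-year accrual cohort with a later data lock.
    """

    n_patients: int = 1399
    baseline_hazard: float | None = None  # events/day; None -> tuned
    target_prevalence: float = 0.23
    calibration_horizon_days: float = 365.0
    frailty_sd: float = 1.5
    target_auc_score_a: float = 0.73
    target_auc_score_b: float = 0.82
    score_correlation: float = 0.6
    censoring_rate: float = 2.4e-4  # events/day
    informative_censoring_strength: float = 0.0
    admin_cutoff_days: float = 1004.0
    demographic_spec: Mapping[str, Mapping[str, float]] = dataclasses.field(
        default_factory=lambda: DEFAULT_DEMOGRAPHICS
    )
    age_mean: float = 65.0
    age_sd: float = 13.0
    age_range: tuple[float, float] = (22.0, 99.0)
    # feature-cohort parameters
    n_features: int = 10
    n_nonzero: int = 3
    coefficient_scale: float = 0.5
    missing_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 1:
            raise ValueError("n_patients must be positive")
        for name in ("censoring_rate", "informative_censoring_strength",
                     "frailty_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        for name in ("target_auc_score_a", "target_auc_score_b"):
            v = getattr(self, name)
            if not 0.5 <= v < 1.0:
                raise ValueError(f"{name} must lie in [0.5, 1)")
        if not -1.0 <= self.score_correlation <= 1.0:
            raise ValueError("score_correlation must lie in [-1, 1]")
        if not 0.0 < self.target_prevalence < 1.0:
            raise ValueError("target_prevalence must lie in (0, 1)")
        if self.admin_cutoff_days < self.calibration_horizon_days:
            raise ValueError("admin_cutoff_days must reach the calibration horizon")
        for col, probs in self.demographic_spec.items():
            total = sum(probs.values())
            if abs(total - 1.0) > 1e-8:
                raise ValueError(f"proportions for {col!r} sum to {total}, not 1")
        if self.n_nonzero > self.n_features:
            raise ValueError("n_nonzero cannot exceed n_features")


# ---------------------------------------------------------------------------
# analytic machinery: evaluable-set case/control probabilities given u

_GH_NODES = 96


def _gh_grid() -> tuple[np.ndarray, np.ndarray]:
    x, w = np.polynomial.hermite.hermgauss(_GH_NODES)
    return np.sqrt(2.0) * x, w / np.sqrt(np.pi)  # u ~ N(0,1) nodes/weights


def _evaluable_probs(
    u: np.ndarray,
    base: float,
    frailty_sd: float,
    cens_rate: float,
    cens_strength: float,
    horizon: float,
) -> tuple[np.ndarray, np.ndarray]:
    """P(evaluable case | u), P(evaluable control | u) at the horizon.

    A case must die by the horizon *before* being censored; a control must
    have neither died nor been censored by the horizon. Both are closed
    forms for exponential death/censoring (the administrative cutoff lies
    at or beyond the horizon, so it never censors before it).
    """
    lam = base * np.exp(frailty_sd * u)
    gam = cens_rate * np.exp(cens_strength * u)
    tot = lam + gam
    p_case = np.where(
        tot > 0, lam / np.where(tot > 0, tot, 1.0) * -np.expm1(-tot * horizon), 0.0
    )
    p_ctrl = np.exp(-tot * horizon)
    return p_case, p_ctrl


def evaluable_auc(
    w: float,
    base: float,
    frailty_sd: float,
    cens_rate: float = 0.0,
    cens_strength: float = 0.0,
    horizon: float = 365.0,
) -> float:
    """Exact evaluable-set AUC of the score ``w*u + sqrt(1-w^2)*eps``.

    AUC = P(s_case > s_control) over independent (case, control) draws
    from the evaluable subsets, by 2-D Gauss-Hermite quadrature over the
    latent risks of the pair.
    """
    w = min(max(w, 0.0), 1.0 - 1e-9)
    u, gw = _gh_grid()
    p_case, p_ctrl = _evaluable_probs(
        u, base, frailty_sd, cens_rate, cens_strength, horizon
    )
    a = p_case * gw
    b = p_ctrl * gw
    scale = np.sqrt(2.0 * (1.0 - w * w))
    win = norm.cdf(w * (u[:, None] - u[None, :]) / scale)
    return float(a @ win @ b / (a.sum() * b.sum()))


def _evaluable_prevalence(
    base: float, frailty_sd: float, cens_rate: float, cens_strength: float,
    horizon: float,
) -> float:
    u, gw = _gh_grid()
    p_case, p_ctrl = _evaluable_probs(
        u, base, frailty_sd, cens_rate, cens_strength, horizon
    )
    a = float(p_case @ gw)
    b = float(p_ctrl @ gw)
    return a / (a + b)


def tune_baseline_hazard(
    target_prevalence: float,
    frailty_sd: float,
    cens_rate: float = 0.0,
    cens_strength: float = 0.0,
    horizon: float = 365.0,
) -> float:
    """Baseline hazard (events/day) hitting a target evaluable prevalence,
    by root-finding on the closed-form prevalence."""

    def f(log10_base: float) -> float:
        return (
            _evaluable_prevalence(
                10.0**log10_base, frailty_sd, cens_rate, cens_strength, horizon
            )
            - target_prevalence
        )

    return 10.0 ** brentq(f, -9.0, 0.0, xtol=1e-12)


def calibrate_score_weight(
    target_auc: float,
    base: float,
    frailty_sd: float,
    cens_rate: float = 0.0,
    cens_strength: float = 0.0,
    horizon: float = 365.0,
) -> float:
    """Latent weight ``w`` whose score attains the target evaluable AUC.

    Raises if the target exceeds the maximum attainable AUC (that of the
    latent risk itself, ``w = 1``), naming the feasible region.
    """
    if target_auc == 0.5:
        return 0.0  # pure noise score
    auc_max = evaluable_auc(1.0, base, frailty_sd, cens_rate, cens_strength, horizon)
    if target_auc >= auc_max:
        raise ValueError(
            f"target AUC {target_auc} not attainable: with frailty_sd="
            f"{frailty_sd} the latent risk itself has evaluable AUC "
            f"{auc_max:.4f}; feasible targets lie in (0.5, {auc_max:.4f})"
        )
    return brentq(
        lambda w: evaluable_auc(
            w, base, frailty_sd, cens_rate, cens_strength, horizon
        )
        - target_auc,
        1e-6,
        1.0 - 1e-9,
        xtol=1e-10,
    )


def _resolve_latents(config: SyntheticConfig) -> tuple[float, float, float, float]:
    """(baseline hazard, w_a, w_b, residual score-noise correlation)."""
    base = config.baseline_hazard
    if base is None:
        base = tune_baseline_hazard(
            config.target_prevalence,
            config.frailty_sd,
            config.censoring_rate,
            config.informative_censoring_strength,
            config.calibration_horizon_days,
        )
    args = (
        base,
        config.frailty_sd,
        config.censoring_rate,
        config.informative_censoring_strength,
        config.calibration_horizon_days,
    )
    w_a = calibrate_score_weight(config.target_auc_score_a, *args)
    w_b = calibrate_score_weight(config.target_auc_score_b, *args)
    denom = np.sqrt((1.0 - w_a**2) * (1.0 - w_b**2))
    shared = w_a * w_b
    if denom == 0:
        rho_eps = 0.0
        if abs(config.score_correlation - shared) > 1e-9:
            raise ValueError("score_correlation fixed at w_a*w_b for noiseless scores")
    else:
        rho_eps = (config.score_correlation - shared) / denom
        if not -1.0 <= rho_eps <= 1.0:
            lo, hi = shared - denom, shared + denom
            raise ValueError(
                f"score_correlation {config.score_correlation} unattainable at "
                f"these AUC targets; feasible range is [{lo:.4f}, {hi:.4f}]"
            )
    return base, w_a, w_b, rho_eps


def _survival_draw(
    rng: np.random.Generator, u: np.ndarray, base: float, config: SyntheticConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Observed follow-up time and event flag given latent risks."""
    lam = base * np.exp(config.frailty_sd * u)
    death = rng.exponential(1.0 / lam)
    if config.censoring_rate > 0:
        gam = config.censoring_rate * np.exp(
            config.informative_censoring_strength * u
        )
        cens = rng.exponential(1.0 / gam)
    else:
        cens = np.full_like(death, np.inf)
    cens = np.minimum(cens, config.admin_cutoff_days)
    followup = np.minimum(death, cens)
    event = death <= cens
    return np.maximum(followup, 1e-6), event


def _sample_demographics(
    rng: np.random.Generator, n: int, spec: Mapping[str, Mapping[str, float]]
) -> dict[str, np.ndarray]:
    out = {}
    for col, probs in spec.items():
        labels = list(probs.keys())
        p = np.array(list(probs.values()), dtype=float)
        out[col] = rng.choice(labels, size=n, p=p / p.sum())
    return out


def generate_cohort(config: SyntheticConfig) -> pd.DataFrame:
    """Draw a cohort table in the canonical schema, seed-deterministic.

    The frame's ``attrs["truth"]`` dict records the resolved latent
    parameters (baseline hazard, score weights, per-patient latent risk)
    for downstream recovery checks.
    """
    base, w_a, w_b, rho_eps = _resolve_latents(config)
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    u = rng.standard_normal(n)
    followup, event = _survival_draw(rng, u, base, config)

    eps = rng.multivariate_normal(
        [0.0, 0.0], [[1.0, rho_eps], [rho_eps, 1.0]], size=n
    )
    s_a = w_a * u + np.sqrt(1.0 - w_a**2) * eps[:, 0]
    s_b = w_b * u + np.sqrt(1.0 - w_b**2) * eps[:, 1]
    eolci = np.clip(np.rint(100.0 * norm.cdf(s_a)), 0, 100).astype(int)
    stanford = -np.expm1(
        -base
        * np.exp(config.frailty_sd * s_b)
        * config.calibration_horizon_days
    )

    age = np.clip(
        rng.normal(config.age_mean, config.age_sd, n), *config.age_range
    ).round(0)
    demo = _sample_demographics(rng, n, config.demographic_spec)

    df = pd.DataFrame(
        {
            "patient_id": [f"P{i:05d}" for i in range(n)],
            "eolci_score": eolci,
            "stanford_prob": stanford,
            "followup_days": followup,
            "event": event,
            "age": age,
            **demo,
        }
    )
    df = validate_cohort(df)
    df.attrs["truth"] = {
        "baseline_hazard": base,
        "w_a": w_a,
        "w_b": w_b,
        "rho_eps": rho_eps,
        "frailty_sd": config.frailty_sd,
        "latent_u": u,
        "true_1yr_death_prob": (
            -np.expm1(
                -base * np.exp(config.frailty_sd * u) * config.calibration_horizon_days
            )
        ),
    }
    return df


@dataclasses.dataclass(frozen=True)
class FeatureCohort:
    """Raw feature matrix (NaN = missing) with its generating truth."""

    features: pd.DataFrame
    time: np.ndarray
    event: np.ndarray
    true_beta: np.ndarray


def generate_feature_cohort(config: SyntheticConfig) -> FeatureCohort:
    """Standard-normal features driving survival through known coefficients.

    The linear predictor ``lp = X @ true_beta`` (``n_nonzero`` entries of
    magnitude ``coefficient_scale``, random signs) is oriented so a larger
    predictor means longer survival: the death hazard is
    ``baseline * exp(-lp)``. A ``missing_fraction`` of entries is masked
    NaN after survival is drawn.
    """
    rng = np.random.default_rng(config.seed)
    n, p = config.n_patients, config.n_features
    X = rng.standard_normal((n, p))
    beta = np.zeros(p)
    idx = rng.choice(p, size=config.n_nonzero, replace=False)
    beta[idx] = config.coefficient_scale * rng.choice([-1.0, 1.0], config.n_nonzero)
    lp = X @ beta

    base = config.baseline_hazard
    if base is None:
        lp_sd = max(config.coefficient_scale * np.sqrt(config.n_nonzero), 1e-9)
        base = tune_baseline_hazard(
            config.target_prevalence,
            lp_sd,
            config.censoring_rate,
            config.informative_censoring_strength,
            config.calibration_horizon_days,
        )
    lam = base * np.exp(-lp)  # larger predictor -> lower hazard
    death = rng.exponential(1.0 / np.maximum(lam, 1e-300))
    if config.censoring_rate > 0:
        cens = rng.exponential(1.0 / config.censoring_rate, n)
    else:
        cens = np.full(n, np.inf)
    cens = np.minimum(cens, config.admin_cutoff_days)
    time = np.maximum(np.minimum(death, cens), 1e-6)
    event = death <= cens

    raw = X.copy()
    if config.missing_fraction > 0:
        mask = rng.random((n, p)) < config.missing_fraction
        raw[mask] = np.nan
    features = pd.DataFrame(raw, columns=[f"x{j}" for j in range(p)])
    return FeatureCohort(features=features, time=time, event=event, true_beta=beta)


def prevalence_sweep(
    config: SyntheticConfig,
    prevalence_grid: Sequence[float],
    cutoff: float = 45.0,
    inclusive: bool = True,
    horizon_days: float = 365.0,
) -> pd.DataFrame:
    """Threshold metrics at a fixed cutoff across event prevalences.

    Holds the score construction fixed (latent weights calibrated once at
    the config's own prevalence) and re-tunes the baseline hazard per grid
    point, isolating the prevalence dependence of PPV at a constant
    operating point — the mechanism by which the same flag's PPV climbs
    when applied in a sicker population.
    """
    from .cohort import label_at_horizon
    from .thresholds import confusion_metrics, flag_high_risk

    base0, w_a, w_b, rho_eps = _resolve_latents(config)
    rows = []
    for p_target in prevalence_grid:
        if not 0.0 < p_target < 1.0:
            raise ValueError("prevalence grid values must lie in (0, 1)")
        base = tune_baseline_hazard(
            p_target,
            config.frailty_sd,
            config.censoring_rate,
            config.informative_censoring_strength,
            horizon_days,
        )
        cfg = dataclasses.replace(
            config, baseline_hazard=base, target_prevalence=p_target
        )
        # fixed score construction: reuse the calibrated weights
        rng = np.random.default_rng(cfg.seed)
        n = cfg.n_patients
        u = rng.standard_normal(n)
        followup, event = _survival_draw(rng, u, base, cfg)
        eps = rng.multivariate_normal(
            [0.0, 0.0], [[1.0, rho_eps], [rho_eps, 1.0]], size=n
        )
        s_a = w_a * u + np.sqrt(1.0 - w_a**2) * eps[:, 0]
        eolci = np.clip(np.rint(100.0 * norm.cdf(s_a)), 0, 100).astype(int)
        df = pd.DataFrame(
            {
                "patient_id": [f"P{i:05d}" for i in range(n)],
                "eolci_score": eolci,
                "stanford_prob": 0.0,
                "followup_days": followup,
                "event": event,
                "age": 60.0,
            }
        )
        labeled = label_at_horizon(validate_cohort(df), horizon_days)
        flags = flag_high_risk(
            labeled.data["eolci_score"].to_numpy(float), cutoff, inclusive
        )
        cm = confusion_metrics(flags, labeled.labels, cutoff, horizon_days)
        rows.append(
            {
                "target_prevalence": p_target,
                "prevalence": labeled.n_cases / labeled.n_evaluable,
                "n_evaluable": labeled.n_evaluable,
                "ppv": cm.ppv,
                "sensitivity": cm.sensitivity,
                "specificity": cm.specificity,
            }
        )
    return pd.DataFrame(rows)
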