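# Methods

This note documents the statistical conventions, numerical choices and
known limitations of `survbench`. Everything stated here is computed by
the test suite or by `scripts/acceptance.py`; nothing is asserted about
real data that the code does not itself verify.

## Outcome labeling under right censoring

Fixed-time metrics need a binary outcome at a horizon *t*. Deaths are
compared with a closed bound (death at exactly *t* is a case); a patient
censored exactly at *t* is a control (their status at *t* is known);
patients censored strictly before *t* are excluded under the primary
convention, or counted as controls under the `censored_as_alive`
sensitivity analysis. This makes the partition
cases + controls + excluded = cohort size exact and deterministic, and the
case count nondecreasing in *t*. Time is handled in days throughout; one
year is 365 days and follow-up is reported in months as days/30.44.

The estimator behind a "median follow-up" is often ambiguous, so three are
reported side by side: the plain median over all patients, the median of
censored patients only, and the reverse-KM median (the KM median of the
censoring distribution, obtained by flipping the event flag). None is
privileged.

## Discrimination

**C-index.** Classical Harrell convention: pair (i, j) is comparable when
i's death is known to precede j's follow-up — time_i < time_j with
event_i, or tied times with exactly one event (the censored patient is the
survivor). Tied event times with two deaths are not comparable. Tied
scores on comparable pairs credit ½. The implementation is an O(n·events)
vectorized pair count; tests check exact agreement with exhaustive
enumeration and with an independent library implementation.

**Fixed-time AUC.** The ROC curve is swept over the distinct score values
(scikit-learn, `drop_intermediate=False`) and the AUC is the trapezoidal
area, which equals the Mann–Whitney statistic with ½ credit for ties. No
censoring-distribution modelling (IPCW) is used: the exclusion convention
*is* the estimator.

**Confidence intervals.** The default is a stratified percentile bootstrap
(cases and controls resampled separately, preserving class sizes; 2,000
resamples; seeded) for both AUC and C-index (the C-index bootstrap
resamples patients). A DeLong large-sample interval is available for AUC
as the analytic alternative; its coverage is verified by simulation
against a binormal truth. Because bootstrap and analytic intervals differ
in the third decimal, CI endpoints are tolerance-checked, never asserted
exactly.

**Subgroups.** Age tertiles split the evaluable cohort into three
near-equal groups at the empirical (inverse-ECDF) tertiles with ties
assigned to the lower group; printed age ranges are derived from the data.
A subgroup without both a case and a control is reported not-estimable and
the run continues.

## Threshold metrics

All 2×2 quantities follow the standard identities; DOR = LR+/LR− =
(TP·TN)/(FP·FN) holds to 1e−12 by construction. Ratios with zero
denominators are reported as an explicit "undefined" marker rather than
raising, so batch reports always complete. The high-risk band on the
0–100 integer score is operationalized as score ≥ 45 (the inclusive rule;
where published band edges overlap, the operational "45 or greater" rule
wins). The matched-count cutoff returns the largest cutoff whose
strictly-greater count is nearest the target, preferring the smaller count
on equidistance and recording any tie-induced discrepancy; with distinct
scores the target is always attained exactly. Gini = 2·AUC − 1 (the
Somers' D identity).

## Kaplan–Meier

Product-limit estimate built on the lifelines event table (deaths at a
time processed before censorings at the same time), with Greenwood
variance accumulated at event times. Confidence bands use the
complementary log-log transform — normal on log(−log S) — which keeps
endpoints inside (0, 1); the transform behind published bands is typically
unstated, so band endpoints are tolerance checks. Queries beyond the last
observed follow-up carry the last value forward with an explicit
`extrapolated` flag and a warning. Risk-group stratification defaults to
tertiles over the *whole* cohort (not only evaluable patients), with
inverse-ECDF boundaries and ties toward the lower-risk group; any number
of quantile groups (e.g. quartiles) is supported by parameter.

## Discrete-time survival model

Follow-up is partitioned into K intervals (default 12 spanning 0–5 years,
edges at 0, 0.25, 0.5, 0.75, 1, 1.5, …, 5 years so that 1 year — the
consumed output — is an exact edge; fully configurable). A single linear
predictor lp = xᵀβ over standardized features feeds per-interval logistic
hazards h_k = σ(α_k − lp): per-interval intercepts plus a shared slope,
the simplest architecture consistent with a single linear first layer. The
sign is fixed so a larger predictor means longer survival, which makes the
influence products β_j·x_ij read directly as survival-improving (> 0) or
survival-worsening (< 0).

The likelihood is the standard discrete-time censored one: log(1 − h_m)
for every interval fully survived, log(h_m) for the interval containing
death; a censored patient's partially lived final interval contributes
nothing (the conservative convention). Follow-up beyond the last edge
counts as surviving every interval. The objective adds an L2 penalty on β
only (never on α) and is maximized by L-BFGS-B with analytic gradients
from a zero start — deterministic, no stochastic initialization. With no
features the optimum separates per interval and equals the empirical
life-table hazard (deaths over contributors), which the tests verify to
1e−6. Survival between edges is interpolated linearly on the log-survival
scale.

L2 strength is selected on a grid by mean held-out log likelihood over
seeded patient-level folds; exact ties resolve to the larger penalty, and
a fold arrangement whose training split lacks events is reshuffled (new
seed) up to three times before erroring.

Standardization uses training-split means and SDs; missing entries are
imputed with the training mean and are therefore exactly 0 in standardized
space, so an imputed feature has exactly zero influence and never enters a
top-k list (zero products are excluded from both directions; a patient
entirely at the training mean is flagged uninformative). Held-out data are
standardized with the training statistics — no re-centering. Zero-variance
training columns are dropped with a warning, except all-missing columns,
which are retained as all-zero. Influence attribution on standardized
(not raw-scale) products is assumed, matching the standardization step
that precedes the attribution definition.

## Synthetic data generator

The generator emulates the structure the pipeline assumes — not any real
EMR feature set. Each patient has a latent risk u ~ N(0,1); death time is
exponential with rate `baseline_hazard`·exp(`frailty_sd`·u); censoring is
an exponential (rate `censoring_rate`, optionally u-tilted by
`informative_censoring_strength`) truncated at an administrative cutoff.
Scores are binormal blends s = w·u + √(1−w²)·ε with correlated noise
across the two scores.

Because death and censoring are exponential given u, the probability that
a patient is an evaluable case or control at the horizon has closed form,
and the evaluable-set AUC of a blend with weight w is a two-dimensional
Gauss–Hermite integral (96 nodes). The weight hitting a target AUC and the
baseline hazard hitting a target evaluable prevalence are found by
root-finding on these expressions — calibration is analytic, not
trial-and-error. Verified behaviour: across 20 seeds at n = 5,000 the
empirical evaluable-set AUC sits within ±0.03 of target per seed and
within ±0.01 on average.

Default conditions (chosen once as the reference cohort profile): 1,399
patients; target AUCs 0.73 and 0.82 at the 1-year horizon; 23% evaluable
1-year mortality; latent score correlation 0.6; censoring rate 2.4e−4/day
(≈8% censored within the first year) with a 1,004-day administrative
cutoff; demographic strata sampled independently of risk. The integer
score is a probit rank transform to 0–100 (≈101 levels; the discretization
attenuates its AUC by well under 0.01); the probability score maps the
score blend through the true exponential model, so it is monotone and
roughly calibrated.

What the generator does **not** emulate: staggered accrual (follow-up is
longer and more uniform than a real two-year accrual window produces, so
the generator's median follow-up exceeds a typical study's), correlation
between demographics and risk, integer-score distributions skewed like a
real vendor index, and any real joint feature distribution. Passing tests
therefore demonstrate correctness of the *estimators* under the assumed
data-generating process, not performance claims about any real population.
With `informative_censoring_strength` > 0 the generator reproduces the
classic bias mechanism — sicker patients lost earlier make naive KM
overestimate survival — which the tests demonstrate against the
generator's known truth.

Feature cohorts use iid standard-normal features, `n_nonzero` coefficients
of magnitude `coefficient_scale` with random signs, hazard
`baseline`·exp(−lp) (larger predictor ⇒ longer survival), and optional
missingness masks applied after survival is drawn.

## Pipeline and reproducibility

Every run report embeds the resolved configuration and package version;
all randomness (bootstrap, folds, generation) flows from explicit seeds,
and repeated runs are byte-identical. Stage failures (e.g. a zero-death
cohort makes the C-index undefined) are caught per stage and reported by
name while the remaining stages complete. Input files are never mutated
and JSON outputs are written atomically.

Problem sizes used by the automated checks — n = 5,000 × 20 seeds for
generator calibration, n = 2,000 × 20 replicates for coefficient recovery,
n = 4,000 for the prevalence sweep, n ≤ 12 × 200 instances for the
exhaustive pair-enumeration oracles — were chosen to make sampling noise
small relative to the tolerances while keeping the whole suite fast on a
single CPU.

## Known limitations

- The exclusion convention for fixed-time AUC is the method under
  evaluation, not a recommendation; IPCW-style estimators that model the
  censoring distribution are deliberately out of scope.
- The discrete-time reference model is faithful in kind (interval grid,
  linear first layer, L2, likelihood) to production-scale clinical
  survival models but is not a reconstruction of any particular deployed
  model; deeper hazard maps are out of scope.
- Calibration assessment (reliability curves, net benefit, decision
  curves) is out of scope: the integer risk index compared here is not
  meant to be a calibrated probability.
- The bootstrap C-index interval is O(n²·resamples) and dominates the
  runtime of a full report on cohorts beyond ~5,000 patients; lower
  `n_boot` or use the analytic AUC interval where speed matters.
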