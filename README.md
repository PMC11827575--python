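# survbench

Head-to-head validation of time-to-event risk scores under right censoring.

Hospitals increasingly receive mortality predictions from more than one
model — say, a vendor-supplied 0–100 risk index and an in-house model's
predicted 1-year death probability — and need to know which one to trust
for a given population. `survbench` implements the complete comparison
protocol for that question on a per-patient cohort table (two scores,
follow-up time, death indicator, demographics):

- **Harrell's C-index** on the full censored cohort: over every comparable
  pair (the patient with shorter follow-up died, so the ordering is
  known), the fraction in which the earlier death carried the higher
  score, with ½ credit for score ties.
- **Fixed-time ROC/AUC** for the binary outcome "died by horizon *t*",
  computed on the *evaluable* subset — patients deceased at any time or
  followed past *t*; patients censored before *t* are excluded (their
  status is unknown), with a sensitivity analysis that counts them as
  alive instead.
- **Threshold diagnostics** at a high-risk cutoff: PPV, sensitivity,
  specificity, LR+, LR−, and the diagnostic odds ratio
  DOR = (TP·TN)/(FP·FN) = LR+/LR−; plus **matched-count cutoff selection**
  so a comparator score flags the same number of patients as a reference
  flag, and the Gini index 2·AUC − 1.
- **Kaplan–Meier curves** with Greenwood variance and complementary
  log-log confidence bands, overall and for score tertiles, plus
  follow-up summaries (plain, censored-only, and reverse-KM medians).
- **Subgroup AUC tables** by demographic strata and age tertiles.
- A reference **discrete-time survival model**: K interval hazards
  h<sub>ik</sub> = σ(α<sub>k</sub> − x<sub>i</sub>ᵀβ) over standardized,
  mean-imputed features (larger linear predictor ⇒ longer survival),
  fitted by penalized maximum likelihood with cross-validated L2 strength,
  and **per-patient influence attribution**: feature *j*'s influence on
  patient *i* is β<sub>j</sub>·x<sub>ij</sub>, ranked to give each
  patient's top-5 survival-improving and survival-worsening features and
  their cohort-level frequencies.
- A **synthetic cohort generator** whose discrimination is analytically
  calibrated: scores are binormal blends of a latent risk, and the latent
  weight hitting a target evaluable-set AUC is obtained by root-finding on
  a closed-form (Gauss–Hermite) expression, so every stage is testable
  without any external data.

## Worked example

```bash
python examples/compare_risk_scores.py
```

```
cohort: 1399 patients, 511 deaths observed
1-year endpoint: 1292 evaluable (107 censored early, excluded), 297 deaths (23%)

eolci_score: C-index 0.670 (535724 comparable pairs), 1-year AUC 0.710
stanford_prob: C-index 0.771 (535724 comparable pairs), 1-year AUC 0.810

high-risk flag, integer score >= 45: 697 flagged, PPV 0.32, sensitivity 0.76, DOR 3.54
matched-count cutoff on probability score: > 0.100 flags 697, PPV 0.36, DOR 6.72
LTFU-as-alive AUC, eolci_score: 0.709 (n=1399)
LTFU-as-alive AUC, stanford_prob: 0.804 (n=1399)
```

The synthetic cohort is drawn at its default study conditions (1,399
patients, target evaluable-set AUCs 0.73/0.82, 23% 1-year mortality, ~8%
lost to follow-up within a year). The probability score dominates the
integer index on every ranking metric; at a matched number of flagged
patients it converts that advantage into a higher PPV and a diagnostic
odds ratio nearly twice as large. The other scripts in `examples/` cover
KM tertiles, influence attribution, and the prevalence dependence of PPV.

The same pipeline runs from the shell on any cohort CSV:

```bash
survbench simulate --n 1399 --seed 1 --out run1
survbench validate --input run1/synthetic_cohort.csv --out run1/report
survbench influence --n 2000 --seed 1 --out run1
```

Column names of an external CSV are adapted through the `column_schema`
mapping of a YAML run configuration (`survbench validate --config
run.yaml`); all thresholds, horizons, bootstrap settings and conventions
live there too.

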