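# Example run configuration for `survbench validate --config run_config.yaml`.
# column_schema maps canonical names to the CSV's actual headers.
input_path: run1/synthetic_cohort.csv
column_schema: null
horizons_days: [180, 365]
primary_horizon_days: 365
cutoff: 45.0
cutoff_inclusive: true
cutoff_score: eolci_score
matched_count: true
subgroup_columns: [age_tertile, sex, race, ethnicity]
convention: exclude_censored   # or censored_as_alive
ci_method: bootstrap           # or analytic (AUC only)
n_boot: 2000
seed: 0
output_dir: run1/report
make_plots: true
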