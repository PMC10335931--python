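# Example end-to-end pipeline configuration for `infantfm run --config`.
# Omit `input_csv` to draw a synthetic cohort instead of reading a file.
visit: "3M"
output_dir: "runs/3m-demo"
seed: 42

generator:
  n: 105                  # study sample size at 3 months
  low_fm_fraction: 0.02   # share of records forced below the 5% FM floor

selection:
  blocks: 100             # 100 blocks x 12 repetitions = 1200 LASSO fits
  reps_per_block: 12
  subsample_fraction: 0.80
  vote_threshold: 500     # nonzero in >= 500/1200 fits to be selected
  lambda_rule: "cv"       # per-repetition 5-fold cross-validated penalty

cv:
  folds: 12
  train_fraction: 0.70

fm_exclusion_pct: 5.0     # drop records with fat mass below 5% of weight
variance_ratio: 1.0       # Deming error-variance ratio (1 = orthogonal)
make_plots: true
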