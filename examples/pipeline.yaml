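# Pipeline configuration for the full synthetic run.
# A single master seed fans out to per-stage seeds (logged to seed_log.json).
master_seed: 20250919
results_dir: results_example

synthetic:
  n_participants: 6000   # default study size is 11914; smaller here for speed

clock:
  n_hidden_layers: 5
  units_per_layer: 256
  dropout_rate: 0.35
  l2_coefficient: 1.0e-5
  n_folds: 5

split:
  train_fraction_healthy: 0.66

attribution:
  train_fraction: 0.7
  n_folds: 10
  n_seeds: 10

en_baseline: true
log_level: INFO
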