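# Minimal end-to-end check: 8 regions, short runs.
synthetic:
  n_roi: 8
  n_rest_samples: 2000
  n_train_trials: 60
  n_test_trials: 60
fit:
  lambda_diag: -0.22
  order: 1
  ridge_alpha: 0.01
  threshold: 0.001
separation:
  framework: acm
seeds:
  master: 0
output_dir: scratch/smoke
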