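# Demonstration of the Active-Cortex-Model separation gain at study scale.
synthetic:
  n_roi: 16
  n_rest_samples: 20000
  n_train_trials: 500
  n_test_trials: 300
fit:
  lambda_diag: -0.22
  order: 1
  ridge_alpha: 0.01
  threshold: 0.001
separation:
  framework: acm
seeds:
  master: 5
output_dir: scratch/acm-demo
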