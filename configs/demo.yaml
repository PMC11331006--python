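# Demo: 200-patient synthetic three-view cohort, 10-fold cross-validation.
synthetic:
  n_patients: 200
  seed: 7
n_select:
  expression: 20
  cnv: 15
resgcn:
  hidden_dim: 32
  fusion_dim: 32
  epochs: 200
  patience: 20
cnn:
  n_filters: 8
  fc_units: 32
  epochs: 40
cv_folds: 10
seed: 7
out_dir: msfn_out
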