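{
 "target_pearson_r": 0.309,
 "calibration": {
  "n_genes": 2000,
  "n_chroms": 4,
  "n_pqs_per_promoter": 2
 },
 "cohort": {
  "n_genes": 10000,
  "n_chroms": 4,
  "n_pqs_per_promoter": 2
 },
 "beta_lo": 0.0,
 "beta_hi": 4.0,
 "tol": 0.005
}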