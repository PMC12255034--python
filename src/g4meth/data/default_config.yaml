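# Default end-to-end run: a small coupled multi-omics simulation.
# All generator and analysis keys can be overridden; seed may also be set
# on the command line (g4m run --seed).
simulation:
  n_genes: 240
  n_chroms: 3
  n_pqs_per_promoter: 2
  seed: 0
analysis:
  flank: 1000
  bin: 10
  top_n: 60
  meth_threshold_pct: 50.0
  p_max: 0.05
  lfc_min: 1.0
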