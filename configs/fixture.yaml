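# Bundled small-scale fixture for end-to-end pipeline runs.
# One seed drives every stochastic stage; rerunning with the same config
# reproduces byte-identical outputs.
seed: 11
simulate:
  n_chroms: 1
  chrom_length: 120000
  te_density: 0.2
  n_circles: 60
  chimeric_rate: 0.05
  length_mean: 2000.0
  length_median: 1800.0
  length_min: 500.0
  length_max: 6000.0
  error_rate: 0.005
  linear_contaminant_rate: 0.1
  min_read_length: 200
call:
  min_length: 200
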