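# small, fast demonstration run of the full simulated pipeline
seed: 7
simulate:
  targets: [klk6_gate, trypsin_gate]
  depth: 5000
  n_cells: 10000
  n_doubles: 30
  error_rate: 0.001
enrich:
  single_threshold: 10
  double_threshold: 3
landscape:
  high_cut: 2.0
  low_cut: 0.5
  min_observed: 8
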