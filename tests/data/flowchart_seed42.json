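{
  "alpha": 0.05,
  "n_hits": 68,
  "n_removed_by_direction": 35,
  "n_removed_by_viability": 0,
  "n_significant": 103,
  "n_tested": 1200,
  "viability_threshold": 0.5
}
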