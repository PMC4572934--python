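# Demo pipeline configuration: a Prestwick-scale synthetic screen
# (4 x 384-well plates, triplicate) followed by hit calling and a
# dose-response fit at the scale of the mometasone furoate IC50.
screen:
  n_library_plates: 4
  n_replicates: 3
  compounds_per_plate: 300
  frac_true_inhibitors: 0.05
  frac_cytotoxic: 0.02
  measurement_cv: 0.1
  seed: 42
hits:
  alpha: 0.05
  null_method: empirical
  viability_threshold: 0.5
dose_response:
  compound_id: MF-like
  orientation: inhibition
  bottom: 0.1
  top: 1.0
  hill: -1.0
  ec50: 1.4e-6
  noise_cv: 0.05
  n_replicates: 3
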