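# End-to-end desk-scale demonstration config for `nichescape run`.
seed: 7
output_dir: nichescape_out
stages: [synth, spectral, stats, gdm, simulate, infer]

landscape:
  width: 20
  height: 20
  n_types: 3
  autocorr_range: 8.0
  cell_size: 100.0

community:
  n_species: 12
  niche_strength: 2.0
  aggregation: 1.0
  pixels_per_cell: 5

cube:
  n_bands: 60
  noise_sd: 0.01
  invalid_fraction: 0.05

spectral:
  k: 12
  min_coverage: 0.25

stats:
  n_boot: 200

gdm:
  predictors: [elevation, tch, tri]

simulate:
  nu: 0.01
  sigma: 3.0
  tau: 8.0
  sample_step: 2
  per_cell: 1

infer:
  sigmas: [1.5, 3.0, 6.0]
  taus: [8.0]
  nus: [0.005, 0.02]
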