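# Desk-scale smoke scenario: 64x64 grid at 30 m, baseline + warmed period.
scenario:
  shape: [64, 64]
  cell_size: 30.0
  elevation_range: [265.0, 2025.0]
  elevation_corr_len: 6.0
  mesoscale_corr_len: 12.0
  micro_corr_len: 2.0
  warming_offsets: {"2010": 0.0, "2050": 2.0}
  seed: 0
species:
  - label: small-bodied
    mass_intercept: 0.25
    mass_slope: 0.0002
    mass_residual_sd: 0.08
    elevation_range: [665.0, 2025.0]
    smr: {b0: -0.10, b1: -0.25, b2: 0.035}
n_presences: 150
background_ratio: 10.0
sdm_k: 5
sdm_cutoff: 0.7
agreement_n_points: 2000
resolutions: [30.0, 60.0, 120.0, 240.0, 480.0]
min_core_area_km2: 0.05
buffer_radius_m: 300.0
seed: 0
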