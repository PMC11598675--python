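# Default instrument/analysis configuration.
geometry:
  rho_short_cm: 1.5
  rho_long_cm: 2.5
tdnirs:
  wavelengths_nm: [685.0, 830.0]
  dt_ps: 9.77
  T_rep_ps: 12500.0
  n_tissue: 1.4
  n_phantom: 1.33
  fit:
    rise_frac: 0.80      # fit starts where the rising edge passes this fraction of peak
    tail_frac: 0.01      # fit stops where the tail falls below this fraction of peak
    t0_bounds_ps: [-100.0, 100.0]
    bg_window_frac: 0.10
dcs:
  wavelength_nm: 785.0
  correlator:
    base_bin_s: 2.0e-7
    m: 16
    octaves: 20
    normalization: symmetric
  fit:
    tail_frac: 0.01
  median_filter_k: 5
protocols:
  gate_width_ps: 500.0
  log_base: e
  stability_band_percent: 1.0
  stability_ref_frac: 0.10
pipeline:
  occlusion_fs_hz: 5.0
  pulsatility_fs_hz: 33.333333
  smoothing_k: 5
  welch_window_s: 20.0
  welch_overlap: 0.5
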