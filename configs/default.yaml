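# Default run configuration — every key is optional; omitted keys fall back
# to these documented defaults, which reproduce the device's published
# operating constants (20 ADU detection threshold, t_on 10 ms, t_delay 3 ms,
# 5 ms exposure, ~130 frames/s, 260 px slice, 730/875/940 nm diode rows).

seed: 1
frames: 1000          # ~7.5 s of free-run video at 130 frames/s
noise_sigma: 0.0      # optional Gaussian read noise [ADU]; 0 = ideal sensor
repeat_count: null    # pattern sweeps; null = enough to cover the recording

geometry:
  rows: 260           # post-binning longitudinal slice height
  cols: 400
  finger_col_stop: 320  # indicator strip occupies columns [320, 400)

timing:
  t_u: 0.017          # controller register update [s] (hardware-determined)
  t_delay: 0.003      # settling delay [s]
  t_on: 0.010         # 7-segment indicator window [s]
  exposure: 0.005     # per-row camera exposure [s]
  frame_rate: 130.0   # free-run frame rate [frames/s]
  seg_lag: 0.0015     # LED-vs-display switching latency [s]

phantom:
  vein_density: 1.0        # 0 disables veins
  vein_width_px: [2.0, 8.0]
  vein_depth_scale: 0.8    # blood path length per px of vein radius
  tissue_depth_max: 2.0    # bulk tissue path at the finger mid-line
  nail_factor: 0.35        # tissue-depth multiplier inside the nail
  texture_contrast: 0.35
  pulse:
    rate_bpm: 90.0
    amplitude: 0.03        # fractional blood-path modulation (<= 0.2)
    phase: 0.0
  absorption: null         # wavelength -> [mu_tissue, mu_blood]; null = defaults

detector:
  threshold: 20       # ADU detection level (saturation is 255)
  sites: null         # 12 [row, col] calibration pixels; null = default layout

roi: null             # pulse ROI {row0, col0, height, width}; null = default
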