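# Small demonstration experiment: 5 noise-free phantom cases, four input
# scenarios, stand-in segmenter with default thresholds. Runs in well under
# a minute on one CPU.
cohort:
  n_cases: 5
  seed: 2024
  grid_shape: [16, 64, 64]
  voxel_spacing: [2.0, 1.0, 1.0]
  n_frames: 30
  frame_interval: 1.5
  noise_sd: 0.0
  radius_scale: [0.85, 1.15]
  center_jitter_mm: 2.0
scenarios:
  - {name: NCCT, input_type: NCCT}
  - {name: mCTA, input_type: mCTA}
  - {name: CTP, input_type: CTP}
  - {name: CTP-equidistant, input_type: CTP, timing_strategy: equidistant}
evaluation:
  tau_report: 0.5
  tau_grid_step: 0.05
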