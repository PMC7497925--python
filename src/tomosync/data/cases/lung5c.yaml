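case: Lung 5c
breathing:
  mean_amplitude_x: 2
  mean_amplitude_y: 10
  mean_amplitude_z: 6
  mean_period: 5
  n: 2
  phase_shift_z: 0.0
  surrogate_mean_amplitude: 3.0
  surrogate_phase_shift: 0.0
  amplitude_rel_sd: 0.1
  smoothing_window: 3
  drift_amplitude: 1.0
delivery:
  treatment_duration: 252
  gantry_period: 12.0
  kv_per_rotation: 4
led_mode: surrogate
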