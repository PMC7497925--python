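case: Lung 3
breathing:
  mean_amplitude_x: 13
  mean_amplitude_y: 7
  mean_amplitude_z: 14
  mean_period: 5
  n: 2
  phase_shift_z: -0.2
  surrogate_mean_amplitude: 5.0
  surrogate_phase_shift: 0.0
  amplitude_rel_sd: 0.1
  smoothing_window: 3
  drift_amplitude: 1.0
delivery:
  treatment_duration: 694
  gantry_period: 12.0
  kv_per_rotation: 4
led_mode: phantom
reference_rms: 7.4
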