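# Desk-scale self-recalibration study: 5 movement classes + rest, 12 channels,
# 6 repetition-sessions with cumulative electrode-shift and gain drift.
seed: 1
synth:
  n_classes: 5
  n_channels: 12
  fs: 2000
  movement_duration: 5.0
  rest_duration: 3.0
  n_repetitions: 6
  noise_sd: 0.4
drift:
  mixing_angle_per_session: 0.15
  gain_drift_per_session: 1.08
  spectral_shift_per_session: 0.0
model:
  n_filters: 8
  fc_neurons: 128
  dropout_rate: 0.5
training:
  epochs: 60
  fine_tune_epochs: 15
  batch_size: 64
  learning_rate: 0.05
correction:
  x: 10
  method: median_prob
scenarios: [none, last_only, all_session]
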