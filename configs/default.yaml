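# Default experiment configuration.
# Sections mirror the configuration dataclasses field-for-field;
# CLI --seed overrides `seed`, which propagates to synth.seed / train.seed
# unless those are set explicitly.

seed: 1
variant: full

synth:
  n_subjects: 20
  n_trials_per_cell: 6
  sampling_rate: 200.0
  trial_length: 2000          # 10 s at 200 Hz
  subject_effect: 1.5
  language_effect: 1.0
  device_effect: 1.0
  noise_sd: 0.4
  noise_color: white
  stimulus_interval_s: 1.0

preprocess:
  channels: [P4, Cz, F8, T7]
  low_hz: 0.5
  high_hz: 45.0
  filter_order: 4
  target_rate: 200.0
  filter_enabled: true

segmentation:
  window: 1000
  stride: 500
  fractions: [0.7, 0.15, 0.15]
  granularity: trial          # 'window' leaks overlap across splits; comparison only
  normalize: true

model:
  in_channels: 4
  conv_kernel: 5
  conv_stride: 2
  conv_channels: [32, 64]
  conv_padding: 2
  d_model: 64
  n_layers: 2
  n_heads: 4
  ffn_dim: 256
  dropout: 0.1
  head_hidden: 64
  n_subjects: 20
  use_positional: true

train:
  lr: 1.0e-4
  weight_decay: 1.0e-4
  gamma: 0.5
  step_size: 5
  epochs: 20
  batch_size: 16
  patience: 5
  monitor: mean_accuracy
  loss_weights: [1.0, 1.0, 1.0]

benchmark:
  variants: [full, stt, sc_sc]
  seeds: [1, 2, 3]
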