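# Desk-scale training configuration (minutes on one CPU core)
learning_rate: 0.001
batch_size: 16
epochs: 10
early_stopping_patience: 15
repetitions: 2
seed: 0
input_size: [64, 64]
contrast_method: clahe
standardize_targets: true
loss: {alpha: 1.0, beta: 1.0, mode: fixed}
model:
  depth: 3
  base_channels: 8
  regression_hidden_units: 32
  eca_conv_layers: 2
  eca_kernel_size: adaptive
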