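# Full-scale protocol: Adam lr 0.001, batch 16, 100 epochs, early stopping,
# 10 repetitions. Expect long runtimes on CPU with the NumPy backend.
learning_rate: 0.001
batch_size: 16
epochs: 100
early_stopping_patience: 15
repetitions: 10
seed: 0
input_size: [96, 96]
contrast_method: clahe
standardize_targets: true
loss: {alpha: 1.0, beta: 1.0, mode: fixed}
model:
  depth: 4
  base_channels: 64
  regression_hidden_units: 64
  eca_conv_layers: 2
  eca_kernel_size: adaptive
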