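# Centralized rhythm-classification baseline: full-depth residual 1-D CNN
# (34 weighted layers), ADAM, batch size 32.
name: ecg_cml
seed: 1
generator: {archetype: ecg4, n_train: 7676, n_test: 852}
partition: {scenario: cml}
model: {family: cnn_ecg}
training: {local_epochs: 1, batch_size: 32, max_rounds: 30, patience: 5}
evaluation: {K: 100}
mini:
  generator: {n_train: 96, n_test: 48, length_range: [120, 240]}
  model: {n_blocks: 2}
  training: {batch_size: 16, max_rounds: 3, patience: null}
  evaluation: {K: 50}
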