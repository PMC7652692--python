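# Imbalanced federated rhythm run: 50% / 30% / 20% split across 3 clients.
name: ecg_imbalanced
seed: 1
generator: {archetype: ecg4, n_train: 7676, n_test: 852}
partition: {scenario: imbalanced_fraction, fractions: [0.5, 0.3, 0.2]}
model: {family: cnn_ecg}
training: {local_epochs: 3, batch_size: 16, max_rounds: 30, patience: 5}
evaluation: {K: 100}
mini:
  generator: {n_train: 96, n_test: 48, length_range: [120, 240]}
  model: {n_blocks: 2}
  training: {max_rounds: 3, patience: null}
  evaluation: {K: 50}
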