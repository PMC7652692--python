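# Basic federated mortality run: three equal clients ("three institutions"),
# 2 local epochs, batch size 4, up to 30 rounds.
name: icu_basic
seed: 1
generator: {archetype: icu_mortality, n_train: 17903, n_test: 3236}
partition: {scenario: basic, n_clients: 3, per_client: 5967}
model: {family: lstm_icu}
training: {local_epochs: 2, batch_size: 4, max_rounds: 30, patience: 5}
evaluation: {K: 10000}
mini:
  generator: {n_train: 240, n_test: 120, length_range: [8, 16]}
  partition: {per_client: 80}
  training: {max_rounds: 4, patience: null}
  evaluation: {K: 50}
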