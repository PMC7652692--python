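# Basic federated run: 10 clients, each a uniform random 600-image shard,
# 5 local epochs, batch size 10, up to 500 rounds.
name: image10_basic
seed: 1
generator: {archetype: image10, n_train: 60000, n_test: 10000}
partition: {scenario: basic, n_clients: 10, per_client: 600}
model: {family: mlp_image}
training: {local_epochs: 5, batch_size: 10, max_rounds: 500, patience: 20}
evaluation: {K: 100}
mini:
  generator: {n_train: 1500, n_test: 400}
  partition: {per_client: 100}
  training: {max_rounds: 15, patience: null}
  evaluation: {K: 50}
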