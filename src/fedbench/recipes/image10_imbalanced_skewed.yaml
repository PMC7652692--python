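# Combined scenario: one class per client AND random shard sizes in 1-600.
name: image10_imbalanced_skewed
seed: 1
generator: {archetype: image10, n_train: 60000, n_test: 10000}
partition: {scenario: imbalanced_skewed, size_min: 1, size_max: 600}
model: {family: mlp_image}
training: {local_epochs: 5, batch_size: 10, max_rounds: 3000, patience: 50}
evaluation: {K: 100}
mini:
  generator: {n_train: 1500, n_test: 400}
  partition: {size_min: 20, size_max: 150}
  training: {max_rounds: 25, patience: null}
  evaluation: {K: 50}
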