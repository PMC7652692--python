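# Label-skewed federated run: one digit class per client, 600 images each,
# up to 3000 rounds (convergence is slower under extreme label skew).
name: image10_skewed
seed: 1
generator: {archetype: image10, n_train: 60000, n_test: 10000}
partition: {scenario: skewed, per_client: 600}
model: {family: mlp_image}
training: {local_epochs: 5, batch_size: 10, max_rounds: 3000, patience: 50}
evaluation: {K: 100}
mini:
  generator: {n_train: 1500, n_test: 400}
  partition: {per_client: 100}
  training: {max_rounds: 25, patience: null}
  evaluation: {K: 50}
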