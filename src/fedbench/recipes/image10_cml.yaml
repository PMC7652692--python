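# Centralized baseline on the 10-class image archetype: one client holds the
# whole training set (batch size 32, early stopping), the control group for
# every federated image run.
name: image10_cml
seed: 1
generator: {archetype: image10, n_train: 60000, n_test: 10000}
partition: {scenario: cml}
model: {family: mlp_image}
training: {local_epochs: 1, batch_size: 32, max_rounds: 1000, patience: 10}
evaluation: {K: 100}
mini:
  generator: {n_train: 1500, n_test: 400}
  training: {max_rounds: 15, patience: 5}
  evaluation: {K: 50}
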