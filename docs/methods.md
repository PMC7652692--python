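# Methods

This note records what fedbench computes, the modelling and numerical
choices behind it, and what the synthetic benchmarks do and do not show.

## Federation procedure

The harness implements synchronous federated averaging over a fixed,
pre-registered client roster. Assumptions, chosen to match the
multi-hospital setting rather than the mobile-device setting:

- clients are always online; there is no eligibility sampling from a large
  pool, and every registered client participates in every round;
- a round aggregates only when *all* expected clients have submitted, so no
  client's update is ever dropped (a fractional participation threshold is
  config-exposed on the server but defaults to full participation);
- aggregation weights are sample counts, `w ← Σ n_k w_k / Σ n_k`. A uniform
  mode (`weighting="uniform"`) is provided for ablation, since quantity
  imbalance makes the two genuinely different.
- each round, local optimizer state (ADAM moments) starts fresh; only
  weights cross the wire.

Per-round evaluation uses the aggregated global weights on the held-out
test split. The monitored metric is accuracy by default; early stopping
fires after `patience` rounds without improvement and the best-so-far model
(not the final one) is what gets reported, with the final model kept
alongside.

Reproducibility: every stream derives from integer seeds via SHA-256
(`derive_seed`), and a client's training stream for round `r` is
`derive_seed(seed, "round", r, client_id)` — independent of thread timing,
transport and submission order. Aggregation sorts updates by client id
before accumulating, so the aggregate is bit-identical under any arrival
order.

### Numerical form of the average

The weighted mean is computed as `w_0 + Σ c_k (w_k − w_0)` with
`c_k = n_k / Σ n_k` in float64. This baseline-shifted form makes three
contracts exact in floating point, not just approximate: a single client's
weights pass through unchanged; identical submissions aggregate to
themselves for any `n_k`; and scaling all `n_k` by a constant changes
nothing. With one full-batch SGD epoch per client the average equals a
centralized full-batch step on the pooled data because each client's
gradient is the *mean* cross-entropy gradient over its shard.

## Wire protocol

Three calls: `GET /round` (current round number), `GET /weight` (global
weights), `PUT /weight` (upload). The upload envelope carries `client_id`,
`round_index` and `n_k` so the server can reject duplicate submissions
("already participated — wait for the next round") and stale-round uploads
idempotently. Weights travel as canonical JSON (sorted keys, no whitespace,
shortest round-trip float repr), so payload equality is byte equality and
the loopback transport — which passes through the identical encoding — is
bit-identical to HTTP. The HTTP side is the standard library's threaded
`http.server` and `urllib` with bounded exponential-backoff retries.

## Task models

All networks are NumPy implementations with analytic gradients (verified
against central finite differences in the suite):

- **mlp_image** — 784 → 128 ReLU → 10 softmax; plain SGD. Default learning
  rate 0.01 (conventional for SGD; config-exposed — the scenario-comparison
  experiment uses 0.1 to approach convergence within its round budget).
- **lstm_icu** — 2 stacked LSTM layers, 16 hidden units, dropout 0.3 on
  each layer's output during training, single sigmoid unit read from the
  last hidden state; ADAM, lr 0.001; binary cross-entropy. Forget-gate
  bias initialized to 1.
- **cnn_ecg** — convolutional stem, then residual blocks of two same-padded
  width-16 convolutions (kernel 7) with identity skips; every other block
  subsamples time by stride 2; global average pooling; 4-way softmax head.
  At the default 16 blocks the network has 34 weighted layers; `n_blocks`
  scales the same architecture down (desk-scale recipes use 2 blocks → 6
  weighted layers) without changing the contract.
- **linear_oracle** — multinomial logistic regression; its single SGD step
  is hand-checkable, which anchors the exact-equivalence tests.

Training is deterministic given the seed: one RNG drives shuffling and
dropout in a fixed consumption order; `local_epochs = 0` is the identity;
the incoming WeightSet is never mutated.

## Synthetic benchmark archetypes

The generators reproduce only the statistical features the benchmark
conclusions rest on; they are not simulators of the underlying physiology.

- **image10**: each class is a fixed unit-norm 784-pixel prototype plus
  i.i.d. Gaussian pixel noise (σ = 0.25 by default). Prototype correlations
  follow a configurable class-similarity matrix (via its Cholesky factor);
  by default pairs {3,5} and {4,9} have correlation 0.85, which places them
  ~1 noise-sd apart while unrelated pairs sit ~3 sd apart — a linear
  classifier then errs mostly between the flagged pairs, emulating the
  visually-similar-digit confusions. Classes are balanced by default.
- **icu_mortality**: per record, a latent severity `z ~ N(0,1)` shifts all
  17 channels through a fixed loading vector; channels evolve as AR(1)
  noise (lag coefficient 0.8) around `baseline + z·loading`; lengths are
  uniform on 16–48 (hourly samples within the first 48 h). The label is a
  logistic function of severity: a latent utility `β·z + logistic noise`
  is thresholded, with `β = 2` by default (true-severity AUROC ≈ 0.85,
  the published regime for this task) and `β = 0` giving a no-signal
  control. Default prevalence 13% is an emulation choice — the source
  experiments never state their split's prevalence.
- **ecg4**: class 0 is a regular quasi-periodic spike train (inter-beat
  interval fixed per record at 55–75 samples ± 1 jitter); class 1 draws
  every inter-beat gap independently (AF-like irregularity); class 2 keeps
  the regular rhythm but swaps in a wide biphasic beat (altered
  morphology); class 3 is pure broadband noise, and is rare — the default
  mix (60/9/28/3%) makes it 3% of records, the rarity that drives its poor
  per-class precision/recall. Lengths are uniform on 300–900 samples.

Label assignment is **stratified** by default (largest-remainder exact
counts, so small fixtures are exact) with an i.i.d. mode for studying
sampling variation. Train and test splits use disjoint seed streams and
record-id namespaces; identical configs are bit-identical.

What passing tests on these archetypes show: that the *harness* — the
partitioning, the aggregation arithmetic, the protocol, the early stopping,
the bootstrap — behaves correctly, and that the qualitative non-IID
phenomena (ordering of scenarios, slow start under label skew) emerge from
federation itself. What they do not show: performance levels transfer to
the real datasets; absolute metric values here are properties of the
synthetic generators at desk scale, not of the published benchmarks.

## Evaluation

Point metrics come from scikit-learn: AUROC (binary, and macro/micro
one-vs-rest for multiclass — macro is the headline since the averaging
convention is not fixed by the source), precision/recall/F1 per class plus
macro and weighted averages, confusion matrix, and AUPRC (average
precision, i.e. step-wise integration over thresholds) for binary tasks.
Binary mortality predictions threshold the sigmoid at 0.5.

The bootstrap is the plain percentile method — the minimal reading of
"resample the test set K times": K same-size with-replacement resamples,
CI = 2.5th/97.5th percentiles of the replicates, point = metric on the
full test set. Degenerate resamples (a class absent, making AUROC/AUPRC
undefined) are redrawn up to 100 times each before the computation fails;
with a ~3% class in a small test set this fires regularly and is the reason
the policy exists. Replicates are retained on the result object so resample
counts are auditable. `K` defaults follow the benchmark protocol (100 for
the image and ECG tasks; 10,000 for mortality; mini recipes use 50).

## Partitioning details

All scenarios sample **disjoint** shards (the multi-hospital reading; the
source states "without duplication" for its clinical splits). Fractional
splits round by largest remainder so e.g. 1000 × (0.5, 0.3, 0.2) is exactly
500/300/200 and thirds of 10 give 4/3/3. Quantity-imbalanced draws redraw
the whole size vector (bounded retries) if a draw oversubscribes the
dataset, then fail with a sizing error. Skewed scenarios build one
single-class shard per class and name the offending class when it is too
small.

## Problem sizes in the suite

The test suite and desk-scale recipes run at deliberately small sizes —
image runs of 150–6,100 records, sequence tasks of tens to hundreds of
records, reduced-depth CNN, bootstrap coverage at 300 repetitions × K=199 —
chosen so the whole suite completes in about a minute while every contract
is still exercised at full fidelity. Full-scale recipes (60,000-image
pools, 17,903-stay mortality splits, 7,676-signal ECG sets, K=10,000) are
bundled and runnable but are not part of the default test run.

## Known limitations

- No asynchronous updates, compression, robust/median aggregation,
  differential privacy or secure aggregation; the protocol is deliberately
  the minimal three-call contract.
- The NumPy sequence models are CPU-bound and loop over records; they are
  meant for correctness and desk-scale experiments, not throughput.
- Percentile (not BCa) bootstrap; intervals on small test sets inherit the
  usual lattice undercoverage of resampling a discrete statistic.
- The ECG generator's morphology classes are schematic waveforms; spectral
  flatness and rhythm regularity are the only physiological contrasts it
  preserves.
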