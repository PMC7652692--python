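"""Synchronous federated-averaging orchestration.

One *round*: every expected client downloads the global weights, trains
locally for E epochs on its shard, and uploads its weights together with its
sample count n_k; the server replaces the global weights with the
sample-count-weighted element-wise mean (FedAVG) once every expected client
has reported — no client is ever dropped. An experiment repeats rounds up to
a budget R, evaluates the global model on the held-out test set after every
round, stops early when the monitored metric stalls, and returns the best
model seen.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._seeds import derive_seed
from .datasets import LabeledDataset
from .models import ModelSpec, TrainingConfig, WeightSet, build, local_train, predict
from .partitioning import PartitionPlan

__all__ = [
    "ClientUpdate",
    "RoundState",
    "ExperimentResult",
    "fedavg",
    "client_seed",
    "run_round",
    "run_experiment",
]


def client_seed(seed: int, round_index: int, client_id: str) -> int:
    """Per-(round, client) training-stream seed; reproducible yet distinct."""
    return derive_seed(seed, "round", round_index, client_id)


@dataclass
class ClientUpdate:
    """One client's uploaded weights for one round; n_k is its shard size."""

    client_id: str
    round_index: int
    weights: WeightSet
    n_k: int

    def __post_init__(self) -> None:
        if self.n_k < 1:
            raise ValueError("n_k must be >= 1")
        if self.round_index < 0:
            raise ValueError("round_index must be >= 0")


@dataclass
class RoundState:
    round_index: int
    global_weights: WeightSet
    expected: frozenset[str]
    participated: frozenset[str] = frozenset()
    history: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.participated <= self.expected:
            raise ValueError("participated must be a subset of expected")


def fedavg(updates: list[ClientUpdate], weighting: str = "samples") -> WeightSet:
    """Element-wise weighted mean of client weights.

    ``weighting='samples'`` uses n_k / sum(n_k) (the FedAVG definition);
    ``weighting='uniform'`` averages clients equally (ablation mode).
    """
    if not updates:
        raise ValueError("fedavg of an empty update list")
    if weighting not in ("samples", "uniform"):
        raise ValueError(f"unknown weighting {weighting!r}")
    rounds = {u.round_index for u in updates}
    if len(rounds) > 1:
        raise ValueError(f"updates span multiple rounds: {sorted(rounds)}")
    # canonical accumulation order: the aggregate is bit-identical no matter
    # in which order clients happened to submit
    updates = sorted(updates, key=lambda u: u.client_id)
    first = updates[0].weights
    for u in updates[1:]:
        if not first.compatible_with(u.weights):
            raise ValueError("incompatible WeightSets in aggregation")
    coef = np.array(
        [u.n_k for u in updates] if weighting == "samples" else [1.0] * len(updates),
        dtype=np.float64,
    )
    coef /= coef.sum()
    # mean computed as w_0 + sum_i c_i (w_i - w_0): when all clients submit
    # identical weights every difference vanishes and the aggregate is
    # bit-identical to the input, for any sample counts
    tensors = {}
    for name in first.names:
        acc = first[name].astype(np.float64, copy=True)
        for c, u in zip(coef[1:], updates[1:]):
            acc += c * (u.weights[name] - first[name])
        tensors[name] = acc
    return WeightSet(first.names, tensors, first.fingerprint)


def run_round(
    state: RoundState,
    ds: LabeledDataset,
    plan: PartitionPlan,
    spec: ModelSpec,
    cfg: TrainingConfig,
    weighting: str = "samples",
) -> RoundState:
    """Execute one full synchronous round and return the advanced state."""
    updates = []
    for shard in plan.shards:
        recs = [ds.records[i] for i in shard.record_indices]
        labs = ds.labels[shard.record_indices]
        w = local_train(
            spec,
            state.global_weights,
            recs,
            labs,
            cfg,
            seed=client_seed(cfg.seed, state.round_index, shard.client_id),
        )
        updates.append(ClientUpdate(shard.client_id, state.round_index, w, shard.n_k))
    new_global = fedavg(updates, weighting=weighting)
    return RoundState(
        round_index=state.round_index + 1,
        global_weights=new_global,
        expected=state.expected,
        participated=frozenset(),
        history=state.history,
    )


@dataclass
class ExperimentResult:
    """History plus the best and final global models of one experiment."""

    history: pd.DataFrame
    best_round: int
    best_weights: WeightSet
    final_weights: WeightSet
    per_client: pd.DataFrame

    def summary(self) -> str:
        last = self.history.iloc[-1] if len(self.history) else None
        lines = [
            "Federated experiment",
            f"  rounds run        : {len(self.history)}",
            f"  best round        : {self.best_round}",
        ]
        if last is not None and self.best_round > 0:
            best = self.history[self.history["round"] == self.best_round].iloc[0]
            lines.append(f"  best accuracy     : {best['accuracy']:.4f}")
            lines.append(f"  final accuracy    : {last['accuracy']:.4f}")
        return "\n".join(lines)


def _evaluate_round(spec, weights, test: LabeledDataset) -> dict:
    probs = predict(spec, weights, test.records)
    pred = probs.argmax(axis=1)
    acc = float((pred == test.labels).mean())
    # macro F1 without importing the evaluation module (no cycle)
    f1s = []
    for c in range(test.n_classes):
        tp = int(((pred == c) & (test.labels == c)).sum())
        fp = int(((pred == c) & (test.labels != c)).sum())
        fn = int(((pred != c) & (test.labels == c)).sum())
        f1s.append(2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0)
    return {"accuracy": acc, "macro_f1": float(np.mean(f1s))}


def run_experiment(
    train: LabeledDataset,
    test: LabeledDataset,
    plan: PartitionPlan,
    spec: ModelSpec,
    cfg: TrainingConfig,
    weighting: str = "samples",
    init_weights: WeightSet | None = None,
) -> ExperimentResult:
    """Run up to ``cfg.max_rounds`` rounds with per-round test evaluation.

    The monitored metric (``cfg.monitor``, default accuracy) is evaluated on
    the test split after every aggregation; if it fails to improve for
    ``cfg.patience`` consecutive rounds the run stops, and the best model by
    the monitored metric is returned alongside the final one.
    """
    missing = [s.client_id for s in plan.shards if not s.record_indices]
    if missing:
        raise ValueError(f"clients without shards: {missing}")
    w = init_weights if init_weights is not None else build(spec, seed=cfg.seed)
    state = RoundState(
        round_index=0,
        global_weights=w,
        expected=frozenset(s.client_id for s in plan.shards),
    )
    rows: list[dict] = []
    best_metric, best_round, best_weights = -np.inf, 0, w.copy()
    stall = 0
    for _ in range(cfg.max_rounds):
        state = run_round(state, train, plan, spec, cfg, weighting=weighting)
        metrics = _evaluate_round(spec, state.global_weights, test)
        rows.append({"round": state.round_index, **metrics})
        current = metrics[cfg.monitor]
        if current > best_metric:
            best_metric, best_round = current, state.round_index
            best_weights = state.global_weights.copy()
            stall = 0
        else:
            stall += 1
            if cfg.patience is not None and stall >= cfg.patience:
                break
    history = pd.DataFrame(rows, columns=["round", "accuracy", "macro_f1"])
    per_client_rows = []
    for shard in plan.shards:
        recs = [train.records[i] for i in shard.record_indices]
        labs = train.labels[shard.record_indices]
        probs = predict(spec, best_weights, recs)
        per_client_rows.append(
            {
                "client_id": shard.client_id,
                "n_k": shard.n_k,
                "local_accuracy": float((probs.argmax(axis=1) == labs).mean()),
            }
        )
    return ExperimentResult(
        history=history,
        best_round=best_round,
        best_weights=best_weights,
        final_weights=state.global_weights,
        per_client=pd.DataFrame(per_client_rows),
    )
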