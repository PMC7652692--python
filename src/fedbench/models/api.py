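"""Uniform build / local-train / predict interface over the model families."""

from __future__ import annotations

import numpy as np

from .._seeds import derive_seed
from ._cnn import cnn
from ._dense import linear, mlp
from ._lstm import lstm
from .specs import ModelSpec, TrainingConfig
from .weights import WeightSet

__all__ = ["build", "local_train", "predict", "mean_loss"]

_FAMILIES = {
    "linear_oracle": linear,
    "mlp_image": mlp,
    "lstm_icu": lstm,
    "cnn_ecg": cnn,
}


def _family(spec: ModelSpec):
    return _FAMILIES[spec.family]


def build(spec: ModelSpec, seed: int = 0) -> WeightSet:
    """Initialize a WeightSet for the spec; deterministic given the seed."""
    rng = np.random.default_rng(derive_seed(seed, "init", spec.fingerprint))
    names, tensors = _family(spec).init(spec, rng)
    return WeightSet(tuple(names), tensors, spec.fingerprint)


def _check_compat(spec: ModelSpec, w: WeightSet) -> None:
    if w.fingerprint != spec.fingerprint:
        raise ValueError(
            f"WeightSet fingerprint {w.fingerprint!r} does not match spec "
            f"{spec.fingerprint!r}"
        )


class _Sgd:
    def __init__(self, lr: float):
        self.lr = lr

    def step(self, params, grads):
        for k, g in grads.items():
            params[k] -= self.lr * g


class _Adam:
    """ADAM with state local to one training call (reset every round)."""

    def __init__(self, lr: float, b1=0.9, b2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.t = 0
        self.m: dict = {}
        self.v: dict = {}

    def step(self, params, grads):
        self.t += 1
        for k, g in grads.items():
            m = self.m.setdefault(k, np.zeros_like(g))
            v = self.v.setdefault(k, np.zeros_like(g))
            m += (1 - self.b1) * (g - m)
            v += (1 - self.b2) * (g * g - v)
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def local_train(
    spec: ModelSpec,
    w0: WeightSet,
    records,
    labels,
    cfg: TrainingConfig,
    seed: int = 0,
) -> WeightSet:
    """Mini-batch training for exactly ``cfg.local_epochs`` epochs from w0.

    The input WeightSet is never modified; the shuffling (and dropout)
    stream is fully determined by ``seed``, so identical calls return
    bit-identical weights. ``local_epochs == 0`` returns a copy of w0.
    """
    _check_compat(spec, w0)
    if len(records) == 0:
        raise ValueError("empty shard: nothing to train on")
    if len(records) != len(labels):
        raise ValueError("records and labels length mismatch")
    out = w0.copy()
    if cfg.local_epochs == 0:
        return out
    params = out.tensors
    fam = _family(spec)
    opt = _Sgd(spec.learning_rate) if spec.optimizer == "sgd" else _Adam(spec.learning_rate)
    labels = np.asarray(labels)
    rng = np.random.default_rng(derive_seed(seed, "local_train"))
    n = len(records)
    for _epoch in range(cfg.local_epochs):
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            batch = [records[i] for i in idx]
            _, grads = fam.loss_and_grads(spec, params, batch, labels[idx], rng, train=True)
            opt.step(params, grads)
    return out


def predict(spec: ModelSpec, w: WeightSet, records) -> np.ndarray:
    """Per-class probability matrix; each row sums to 1."""
    _check_compat(spec, w)
    return _family(spec).predict_proba(spec, w.tensors, records)


def mean_loss(spec: ModelSpec, w: WeightSet, records, labels) -> float:
    """Mean cross-entropy of w on the given records (no dropout)."""
    _check_compat(spec, w)
    rng = np.random.default_rng(0)  # unused when train=False
    loss, _ = _family(spec).loss_and_grads(
        spec, w.tensors, records, np.asarray(labels), rng, train=False
    )
    return loss
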