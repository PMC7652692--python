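"""Multinomial logistic regression and the one-hidden-layer ReLU MLP.

Both operate on flattened fixed-shape records, use mean cross-entropy loss,
and return exact analytic gradients — the linear model is the oracle family
whose single SGD step can be checked by hand.
"""

from __future__ import annotations

import numpy as np

__all__ = ["linear", "mlp"]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def stack_flat(records) -> np.ndarray:
    return np.stack([np.asarray(r, dtype=np.float64).ravel() for r in records])


def cross_entropy(probs: np.ndarray, labels: np.ndarray) -> float:
    n = len(labels)
    return float(-np.log(np.clip(probs[np.arange(n), labels], 1e-12, None)).mean())


class linear:
    @staticmethod
    def init(spec, rng: np.random.Generator):
        d, k = spec.n_features, spec.n_classes
        tensors = {
            "W": rng.normal(0.0, 0.01, (d, k)),
            "b": np.zeros(k),
        }
        return ("W", "b"), tensors

    @staticmethod
    def loss_and_grads(spec, params, records, labels, rng, train=True):
        X = stack_flat(records)
        n = len(labels)
        probs = softmax(X @ params["W"] + params["b"])
        loss = cross_entropy(probs, labels)
        delta = probs.copy()
        delta[np.arange(n), labels] -= 1.0
        delta /= n
        return loss, {"W": X.T @ delta, "b": delta.sum(axis=0)}

    @staticmethod
    def predict_proba(spec, params, records):
        X = stack_flat(records)
        return softmax(X @ params["W"] + params["b"])


class mlp:
    """input -> hidden (ReLU, 128 units by default) -> softmax output."""

    @staticmethod
    def init(spec, rng: np.random.Generator):
        d, h, k = spec.n_features, spec.hidden_units, spec.n_classes
        tensors = {
            "W1": rng.normal(0.0, np.sqrt(2.0 / d), (d, h)),  # He init for ReLU
            "b1": np.zeros(h),
            "W2": rng.normal(0.0, np.sqrt(1.0 / h), (h, k)),
            "b2": np.zeros(k),
        }
        return ("W1", "b1", "W2", "b2"), tensors

    @staticmethod
    def _forward(params, X):
        a = X @ params["W1"] + params["b1"]
        hidden = np.maximum(a, 0.0)
        return a, hidden, softmax(hidden @ params["W2"] + params["b2"])

    @staticmethod
    def loss_and_grads(spec, params, records, labels, rng, train=True):
        X = stack_flat(records)
        n = len(labels)
        a, hidden, probs = mlp._forward(params, X)
        loss = cross_entropy(probs, labels)
        delta = probs.copy()
        delta[np.arange(n), labels] -= 1.0
        delta /= n
        d_hidden = (delta @ params["W2"].T) * (a > 0)
        grads = {
            "W2": hidden.T @ delta,
            "b2": delta.sum(axis=0),
            "W1": X.T @ d_hidden,
            "b1": d_hidden.sum(axis=0),
        }
        return loss, grads

    @staticmethod
    def predict_proba(spec, params, records):
        X = stack_flat(records)
        return mlp._forward(params, X)[2]
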