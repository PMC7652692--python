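"""Residual 1-D convolutional network for variable-length signals.

The full contract is a deep residual network: a convolutional stem, a stack
of residual blocks of two same-padded convolutions each (every other block
subsamples time by stride 2), global average pooling and a softmax head.
At the default 16 blocks that is 34 weighted layers; ``n_blocks`` scales the
same architecture down for desk-size experiments. All convolutions share the
channel width so identity skips need no projection.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from ._dense import softmax, cross_entropy

__all__ = ["cnn"]


def _conv_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray, stride: int):
    """Same-padded 1-D convolution. x: (T, Cin), W: (K, Cin, Cout)."""
    T = x.shape[0]
    K, c_in, c_out = W.shape
    out_len = -(-T // stride)
    left = (K - 1) // 2
    right = max((out_len - 1) * stride + K - 1 - left - (T - 1), 0)
    xp = np.pad(x, ((left, right), (0, 0)))
    win = sliding_window_view(xp, K, axis=0)  # (positions, Cin, K)
    cols = win[::stride][:out_len].transpose(0, 2, 1).reshape(out_len, K * c_in)
    out = cols @ W.reshape(K * c_in, c_out) + b
    return out, (cols, xp.shape[0], left, T, stride)


def _conv_backward(d_out: np.ndarray, W: np.ndarray, cache):
    cols, tp, left, T, stride = cache
    K, c_in, c_out = W.shape
    out_len = d_out.shape[0]
    dW = (cols.T @ d_out).reshape(K, c_in, c_out)
    db = d_out.sum(axis=0)
    dcols = (d_out @ W.reshape(K * c_in, c_out).T).reshape(out_len, K, c_in)
    dxp = np.zeros((tp, c_in))
    pos = stride * np.arange(out_len)
    for j in range(K):  # within one j the target indices are distinct
        dxp[pos + j] += dcols[:, j, :]
    return dW, db, dxp[left : left + T]


def _block_stride(i: int) -> int:
    return 2 if i % 2 == 0 else 1


class cnn:
    @staticmethod
    def init(spec, rng: np.random.Generator):
        K, C = spec.kernel_size, spec.channels
        names, tensors = [], {}

        def conv(name, c_in, c_out):
            fan_in = K * c_in
            tensors[f"{name}_W"] = rng.normal(0.0, np.sqrt(2.0 / fan_in), (K, c_in, c_out))
            tensors[f"{name}_b"] = np.zeros(c_out)
            names.extend([f"{name}_W", f"{name}_b"])

        conv("stem", spec.n_features, C)
        for i in range(spec.n_blocks):
            conv(f"blk{i}a", C, C)
            conv(f"blk{i}b", C, C)
        tensors["head_W"] = rng.normal(0.0, np.sqrt(1.0 / C), (C, spec.n_classes))
        tensors["head_b"] = np.zeros(spec.n_classes)
        names.extend(["head_W", "head_b"])
        return tuple(names), tensors

    @staticmethod
    def _forward_record(spec, params, rec):
        x = np.asarray(rec, dtype=np.float64)
        if x.ndim == 1:
            x = x[:, None]
        caches = []
        h, c0 = _conv_forward(x, params["stem_W"], params["stem_b"], 1)
        stem_pre = h
        h = np.maximum(h, 0.0)
        caches.append(("stem", c0, stem_pre))
        for i in range(spec.n_blocks):
            s = _block_stride(i)
            a, ca = _conv_forward(h, params[f"blk{i}a_W"], params[f"blk{i}a_b"], s)
            a_relu = np.maximum(a, 0.0)
            bpre, cb = _conv_forward(a_relu, params[f"blk{i}b_W"], params[f"blk{i}b_b"], 1)
            skip = h[::s][: bpre.shape[0]]
            pre = bpre + skip
            out = np.maximum(pre, 0.0)
            caches.append((f"blk{i}", s, ca, a, cb, pre, h.shape[0]))
            h = out
        gap = h.mean(axis=0)
        logits = gap @ params["head_W"] + params["head_b"]
        return logits, gap, h.shape[0], caches

    @staticmethod
    def loss_and_grads(spec, params, records, labels, rng, train=True):
        n = len(records)
        grads = {k: np.zeros_like(v) for k, v in params.items()}
        total = 0.0
        for rec, y in zip(records, labels):
            logits, gap, t_out, caches = cnn._forward_record(spec, params, rec)
            probs = softmax(logits[None, :])[0]
            total += -np.log(max(probs[y], 1e-12))
            delta = probs.copy()
            delta[y] -= 1.0
            grads["head_W"] += np.outer(gap, delta)
            grads["head_b"] += delta
            dh = np.repeat((delta @ params["head_W"].T)[None, :] / t_out, t_out, axis=0)
            for entry in reversed(caches[1:]):
                name, s, ca, a, cb, pre, t_in = entry
                d_pre = dh * (pre > 0)
                dWb, dbb, d_arelu = _conv_backward(d_pre, params[f"{name}b_W"], cb)
                grads[f"{name}b_W"] += dWb
                grads[f"{name}b_b"] += dbb
                d_a = d_arelu * (a > 0)
                dWa, dba, dh_conv = _conv_backward(d_a, params[f"{name}a_W"], ca)
                grads[f"{name}a_W"] += dWa
                grads[f"{name}a_b"] += dba
                dh_skip = np.zeros((t_in, d_pre.shape[1]))
                dh_skip[::s][: d_pre.shape[0]] = d_pre
                dh = dh_conv + dh_skip
            _, c0, stem_pre = caches[0]
            d_stem = dh * (stem_pre > 0)
            dW0, db0, _ = _conv_backward(d_stem, params["stem_W"], c0)
            grads["stem_W"] += dW0
            grads["stem_b"] += db0
        for k in grads:
            grads[k] /= n
        return total / n, grads

    @staticmethod
    def predict_proba(spec, params, records):
        out = np.empty((len(records), spec.n_classes))
        for idx, rec in enumerate(records):
            logits, _, _, _ = cnn._forward_record(spec, params, rec)
            out[idx] = softmax(logits[None, :])[0]
        return out
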