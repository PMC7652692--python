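"""Stacked LSTM for variable-length multichannel series, sigmoid output.

Matches the mortality-model contract: default 16 hidden units, depth 2,
dropout 0.3 applied to each layer's output sequence during training, a
single sigmoid unit read from the final hidden state, binary cross-entropy
loss. Sequences are processed one record at a time (records vary in
length); gradients are averaged over the mini-batch.
"""

from __future__ import annotations

import numpy as np

__all__ = ["lstm"]


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


def _layer_params(spec):
    """(name, in_dim) per stacked layer."""
    dims = [spec.n_features] + [spec.hidden_units] * (spec.depth - 1)
    return [(l, dims[l]) for l in range(spec.depth)]


class lstm:
    @staticmethod
    def init(spec, rng: np.random.Generator):
        h = spec.hidden_units
        names, tensors = [], {}
        for l, d_in in _layer_params(spec):
            scale_x = 1.0 / np.sqrt(d_in)
            scale_h = 1.0 / np.sqrt(h)
            tensors[f"Wx{l}"] = rng.uniform(-scale_x, scale_x, (d_in, 4 * h))
            tensors[f"Wh{l}"] = rng.uniform(-scale_h, scale_h, (h, 4 * h))
            b = np.zeros(4 * h)
            b[h : 2 * h] = 1.0  # forget-gate bias: remember by default
            tensors[f"bh{l}"] = b
            names += [f"Wx{l}", f"Wh{l}", f"bh{l}"]
        tensors["w_out"] = rng.uniform(-1.0 / np.sqrt(h), 1.0 / np.sqrt(h), (h,))
        tensors["b_out"] = np.zeros(1)
        names += ["w_out", "b_out"]
        return tuple(names), tensors

    # -- single-layer forward/backward over one sequence ------------------

    @staticmethod
    def _forward_layer(Wx, Wh, b, X):
        T, h = X.shape[0], Wh.shape[0]
        gates = np.empty((T, 4 * h))
        cs = np.empty((T, h))
        hs = np.empty((T, h))
        h_prev = np.zeros(h)
        c_prev = np.zeros(h)
        for t in range(T):
            z = X[t] @ Wx + h_prev @ Wh + b
            i = _sigmoid(z[:h])
            f = _sigmoid(z[h : 2 * h])
            g = np.tanh(z[2 * h : 3 * h])
            o = _sigmoid(z[3 * h :])
            c = f * c_prev + i * g
            hcur = o * np.tanh(c)
            gates[t] = np.concatenate([i, f, g, o])
            cs[t] = c
            hs[t] = hcur
            h_prev, c_prev = hcur, c
        return hs, (X, gates, cs, hs)

    @staticmethod
    def _backward_layer(Wx, Wh, cache, d_hs):
        X, gates, cs, hs = cache
        T, h = cs.shape
        dWx = np.zeros_like(Wx)
        dWh = np.zeros_like(Wh)
        db = np.zeros(4 * h)
        dX = np.zeros_like(X)
        dh_next = np.zeros(h)
        dc_next = np.zeros(h)
        for t in range(T - 1, -1, -1):
            i, f, g, o = (
                gates[t, :h],
                gates[t, h : 2 * h],
                gates[t, 2 * h : 3 * h],
                gates[t, 3 * h :],
            )
            c_prev = cs[t - 1] if t > 0 else np.zeros(h)
            h_prev = hs[t - 1] if t > 0 else np.zeros(h)
            tc = np.tanh(cs[t])
            dh = d_hs[t] + dh_next
            do = dh * tc
            dc = dh * o * (1.0 - tc**2) + dc_next
            di, df, dg = dc * g, dc * c_prev, dc * i
            dz = np.concatenate(
                [
                    di * i * (1 - i),
                    df * f * (1 - f),
                    dg * (1 - g**2),
                    do * o * (1 - o),
                ]
            )
            dWx += np.outer(X[t], dz)
            dWh += np.outer(h_prev, dz)
            db += dz
            dh_next = dz @ Wh.T
            dc_next = dc * f
            dX[t] = dz @ Wx.T
        return dWx, dWh, db, dX

    # -- batch API --------------------------------------------------------

    @staticmethod
    def loss_and_grads(spec, params, records, labels, rng, train=True):
        n = len(records)
        p_drop = spec.dropout if train else 0.0
        grads = {k: np.zeros_like(v) for k, v in params.items()}
        total = 0.0
        for rec, y in zip(records, labels):
            X = np.asarray(rec, dtype=np.float64)
            caches, masks, inp = [], [], X
            for l, _ in _layer_params(spec):
                hs, cache = lstm._forward_layer(
                    params[f"Wx{l}"], params[f"Wh{l}"], params[f"bh{l}"], inp
                )
                if p_drop > 0.0:
                    mask = (rng.random(hs.shape) >= p_drop) / (1.0 - p_drop)
                else:
                    mask = None
                caches.append(cache)
                masks.append(mask)
                inp = hs if mask is None else hs * mask
            h_last = inp[-1]
            u = float(h_last @ params["w_out"] + params["b_out"][0])
            p = _sigmoid(np.array([u]))[0]
            total += -(np.log(max(p, 1e-12)) if y == 1 else np.log(max(1 - p, 1e-12)))
            du = p - float(y == 1)
            grads["w_out"] += du * h_last
            grads["b_out"][0] += du
            d_out = np.zeros_like(inp)
            d_out[-1] = du * params["w_out"]
            for l in range(spec.depth - 1, -1, -1):
                if masks[l] is not None:
                    d_out = d_out * masks[l]
                dWx, dWh, db, d_out = lstm._backward_layer(
                    params[f"Wx{l}"], params[f"Wh{l}"], caches[l], d_out
                )
                grads[f"Wx{l}"] += dWx
                grads[f"Wh{l}"] += dWh
                grads[f"bh{l}"] += db
        for k in grads:
            grads[k] /= n
        return total / n, grads

    @staticmethod
    def predict_proba(spec, params, records):
        out = np.empty((len(records), 2))
        for idx, rec in enumerate(records):
            inp = np.asarray(rec, dtype=np.float64)
            for l, _ in _layer_params(spec):
                inp, _ = lstm._forward_layer(
                    params[f"Wx{l}"], params[f"Wh{l}"], params[f"bh{l}"], inp
                )
            p = _sigmoid(inp[-1] @ params["w_out"] + params["b_out"])[0]
            out[idx] = (1.0 - p, p)
        return out
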