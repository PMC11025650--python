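"""Minimal NumPy neural-network kernel: embedding + one-layer LSTM with
backpropagation through time, tanh/sigmoid/softmax heads, and the Adamax
optimizer.  Everything operates on one sentence at a time; mini-batching is
done by accumulating gradients over sentences before an optimizer step.

Shapes follow the convention (time, features); weights are stored in a flat
name -> array dict so optimizer state and checkpointing stay trivial.
"""

from __future__ import annotations

import numpy as np


def glorot(rng: np.random.Generator, n_in: int, n_out: int) -> np.ndarray:
    lim = np.sqrt(6.0 / (n_in + n_out))
    return rng.uniform(-lim, lim, size=(n_in, n_out))


def sigmoid(x: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


class Adamax(object):
    """Adamax (infinity-norm variant of Adam); lr per the training recipe."""

    def __init__(self, params: dict[str, np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.u = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        bias = 1.0 - self.beta1 ** self.t
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1.0 - self.beta1) * g
            self.u[k] = np.maximum(self.beta2 * self.u[k], np.abs(g))
            self.params[k] -= (self.lr / bias) * self.m[k] / (self.u[k] + self.eps)


class LSTM(object):
    """One-layer LSTM.  Parameters live in ``params`` under a name prefix:
    ``{p}Wx`` (D x 4H), ``{p}Wh`` (H x 4H), ``{p}b`` (4H,).  Gate order in
    the concatenated dimension is input, forget, cell, output.
    """

    def __init__(self, params: dict[str, np.ndarray], prefix: str, hidden: int):
        self.params = params
        self.p = prefix
        self.H = hidden

    @staticmethod
    def init(params: dict[str, np.ndarray], prefix: str, n_in: int, hidden: int,
             rng: np.random.Generator) -> "LSTM":
        params[prefix + "Wx"] = glorot(rng, n_in, 4 * hidden)
        params[prefix + "Wh"] = glorot(rng, hidden, 4 * hidden)
        b = np.zeros(4 * hidden)
        b[hidden:2 * hidden] = 1.0  # forget-gate bias; standard stabilizer
        params[prefix + "b"] = b
        return LSTM(params, prefix, hidden)

    def forward(self, xs: np.ndarray):
        """xs: (T, D) -> hidden states (T, H) and a cache for backward().
        Initial hidden and cell states are zero vectors."""
        T = xs.shape[0]
        H = self.H
        Wx, Wh, b = (self.params[self.p + k] for k in ("Wx", "Wh", "b"))
        hs = np.zeros((T, H))
        cs = np.zeros((T, H))
        gates = np.zeros((T, 4 * H))
        h_prev = np.zeros(H)
        c_prev = np.zeros(H)
        pre = xs @ Wx + b
        for t in range(T):
            z = pre[t] + h_prev @ Wh
            i = sigmoid(z[:H])
            f = sigmoid(z[H:2 * H])
            g = np.tanh(z[2 * H:3 * H])
            o = sigmoid(z[3 * H:])
            c = f * c_prev + i * g
            h = o * np.tanh(c)
            gates[t, :H], gates[t, H:2 * H] = i, f
            gates[t, 2 * H:3 * H], gates[t, 3 * H:] = g, o
            cs[t] = c
            hs[t] = h
            h_prev, c_prev = h, c
        cache = (xs, hs, cs, gates)
        return hs, cache

    def backward(self, dhs: np.ndarray, cache, grads: dict[str, np.ndarray]) -> np.ndarray:
        """dhs: (T, H) upstream gradient on each hidden state.  Accumulates
        parameter gradients into ``grads`` and returns dxs (T, D)."""
        xs, hs, cs, gates = cache
        T = xs.shape[0]
        H = self.H
        Wx, Wh = self.params[self.p + "Wx"], self.params[self.p + "Wh"]
        dWx = grads.setdefault(self.p + "Wx", np.zeros_like(Wx))
        dWh = grads.setdefault(self.p + "Wh", np.zeros_like(Wh))
        db = grads.setdefault(self.p + "b", np.zeros_like(self.params[self.p + "b"]))
        dxs = np.zeros_like(xs)
        dh_next = np.zeros(H)
        dc_next = np.zeros(H)
        dz_all = np.zeros((T, 4 * H))
        for t in range(T - 1, -1, -1):
            i, f = gates[t, :H], gates[t, H:2 * H]
            g, o = gates[t, 2 * H:3 * H], gates[t, 3 * H:]
            c = cs[t]
            c_prev = cs[t - 1] if t > 0 else np.zeros(H)
            h_prev = hs[t - 1] if t > 0 else np.zeros(H)
            dh = dhs[t] + dh_next
            tanh_c = np.tanh(c)
            do = dh * tanh_c
            dc = dh * o * (1.0 - tanh_c ** 2) + dc_next
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate([
                di * i * (1.0 - i),
                df * f * (1.0 - f),
                dg * (1.0 - g ** 2),
                do * o * (1.0 - o),
            ])
            dz_all[t] = dz
            dWh += np.outer(h_prev, dz)
            dh_next = dz @ Wh.T
            dc_next = dc * f
        dWx += xs.T @ dz_all
        db += dz_all.sum(axis=0)
        dxs[:] = dz_all @ Wx.T
        return dxs


def accumulate_embedding_grad(grads: dict[str, np.ndarray], name: str,
                              shape: tuple[int, int], ids: np.ndarray,
                              dxs: np.ndarray) -> None:
    dE = grads.setdefault(name, np.zeros(shape))
    np.add.at(dE, ids, dxs)
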