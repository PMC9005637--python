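"""Minimal LSTM / Bi-LSTM sequence-to-one regression network in numpy.

Implements exactly what the phase estimator needs: a stack of (optionally
bidirectional) LSTM layers over a fixed-length input window, a dense output
layer applied to the last timestep, mean-squared-error loss, analytic
backpropagation through time, and Adam.  Gate order is (input, forget, cell,
output); the forget-gate bias is initialized to 1.  Bidirectional layers run
an independent LSTM over the reversed sequence and concatenate, so an
H-unit bidirectional layer outputs 2H features per timestep.

All math is float64; gradients are validated against finite differences in
the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["SequenceRegressorNet", "Adam"]


def _sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _init_lstm(rng: np.random.Generator, d_in: int, units: int):
    s = 1.0 / np.sqrt(d_in + units)
    Wx = rng.uniform(-s, s, size=(d_in, 4 * units))
    Wh = rng.uniform(-s, s, size=(units, 4 * units))
    b = np.zeros(4 * units)
    b[units:2 * units] = 1.0          # forget-gate bias
    return [Wx, Wh, b]


def _lstm_forward(X, Wx, Wh, b):
    """X: (B, T, D) -> H_seq (B, T, H), plus cache for backprop."""
    B, T, _ = X.shape
    H = Wh.shape[0]
    Zx = X @ Wx + b
    gates = np.empty((B, T, 4 * H))
    Cs = np.empty((B, T, H))
    Hs = np.empty((B, T, H))
    h = np.zeros((B, H))
    c = np.zeros((B, H))
    for t in range(T):
        z = Zx[:, t] + h @ Wh
        i = _sigmoid(z[:, :H])
        f = _sigmoid(z[:, H:2 * H])
        g = np.tanh(z[:, 2 * H:3 * H])
        o = _sigmoid(z[:, 3 * H:])
        c = f * c + i * g
        h = o * np.tanh(c)
        gates[:, t, :H], gates[:, t, H:2 * H] = i, f
        gates[:, t, 2 * H:3 * H], gates[:, t, 3 * H:] = g, o
        Cs[:, t] = c
        Hs[:, t] = h
    return Hs, (X, gates, Cs, Hs)


def _lstm_backward(dHs, cache, Wx, Wh):
    """Gradient of a full-sequence loss wrt inputs and parameters."""
    X, gates, Cs, Hs = cache
    B, T, _ = X.shape
    H = Wh.shape[0]
    dZ = np.empty((B, T, 4 * H))
    dh = np.zeros((B, H))
    dc = np.zeros((B, H))
    for t in range(T - 1, -1, -1):
        dh = dh + dHs[:, t]
        i = gates[:, t, :H]
        f = gates[:, t, H:2 * H]
        g = gates[:, t, 2 * H:3 * H]
        o = gates[:, t, 3 * H:]
        tc = np.tanh(Cs[:, t])
        dc = dc + dh * o * (1.0 - tc * tc)
        c_prev = Cs[:, t - 1] if t > 0 else 0.0
        dz = dZ[:, t]
        dz[:, :H] = dc * g * i * (1.0 - i)
        dz[:, H:2 * H] = dc * c_prev * f * (1.0 - f)
        dz[:, 2 * H:3 * H] = dc * i * (1.0 - g * g)
        dz[:, 3 * H:] = dh * tc * o * (1.0 - o)
        dh = dz @ Wh.T
        dc = dc * f
    dX = dZ @ Wx.T
    Hprev = np.concatenate([np.zeros((B, 1, H)), Hs[:, :-1]], axis=1)
    dWx = np.einsum("btd,bth->dh", X, dZ)
    dWh = np.einsum("btd,bth->dh", Hprev, dZ)
    db = dZ.sum(axis=(0, 1))
    return dX, [dWx, dWh, db]


class SequenceRegressorNet:
    """Stacked (Bi-)LSTM + dense head mapping (B, T, C) -> (B, n_outputs)."""

    def __init__(self, n_channels: int, hidden_units=(128, 64, 64, 32),
                 bidirectional=(True, False, False, False), n_outputs: int = 2,
                 rng: np.random.Generator | None = None):
        if len(hidden_units) != len(bidirectional):
            raise ValueError("hidden_units and bidirectional must align")
        rng = rng if rng is not None else np.random.default_rng(0)
        self.n_channels = n_channels
        self.hidden_units = tuple(int(u) for u in hidden_units)
        self.bidirectional = tuple(bool(b) for b in bidirectional)
        self.n_outputs = int(n_outputs)
        self.params: list[np.ndarray] = []
        self._layout: list[dict] = []
        d = n_channels
        for units, bidir in zip(self.hidden_units, self.bidirectional):
            if bidir:
                if units % 2:
                    raise ValueError("bidirectional layer units must be even "
                                     "(split across directions)")
                per_dir = units // 2
                fwd = _init_lstm(rng, d, per_dir)
                bwd = _init_lstm(rng, d, per_dir)
                self._layout.append({"kind": "bilstm", "i": len(self.params),
                                     "units": per_dir})
                self.params.extend(fwd + bwd)
                d = units
            else:
                self._layout.append({"kind": "lstm", "i": len(self.params),
                                     "units": units})
                self.params.extend(_init_lstm(rng, d, units))
                d = units
        s = 1.0 / np.sqrt(d)
        self._layout.append({"kind": "dense", "i": len(self.params)})
        self.params.extend([rng.uniform(-s, s, size=(d, self.n_outputs)),
                            np.zeros(self.n_outputs)])

    # -- parameter plumbing -------------------------------------------------
    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params]

    def set_weights(self, weights) -> None:
        if len(weights) != len(self.params):
            raise ValueError("weight list length mismatch")
        for p, w in zip(self.params, weights):
            p[...] = w

    # -- forward / backward -------------------------------------------------
    def forward(self, X: np.ndarray, want_cache: bool = False):
        X = np.asarray(X, dtype=float)
        if X.ndim != 3 or X.shape[2] != self.n_channels:
            raise ValueError(
                f"expected input of shape (B, T, {self.n_channels}), got {X.shape}")
        caches = []
        h = X
        for layer in self._layout[:-1]:
            i = layer["i"]
            if layer["kind"] == "lstm":
                h, cache = _lstm_forward(h, *self.params[i:i + 3])
                caches.append((layer, cache))
            else:
                hf, cf = _lstm_forward(h, *self.params[i:i + 3])
                hb, cb = _lstm_forward(h[:, ::-1], *self.params[i + 3:i + 6])
                h = np.concatenate([hf, hb[:, ::-1]], axis=2)
                caches.append((layer, (cf, cb)))
        i = self._layout[-1]["i"]
        W, b = self.params[i], self.params[i + 1]
        last = h[:, -1]
        y = last @ W + b
        if want_cache:
            return y, (caches, last, h.shape)
        return y

    def loss_and_grads(self, X, y_true):
        """Mean-squared-error loss and gradients for one batch."""
        y_true = np.asarray(y_true, dtype=float)
        y, (caches, last, top_shape) = self.forward(X, want_cache=True)
        B = y.shape[0]
        resid = y - y_true
        loss = float(np.mean(resid ** 2))
        grads = [np.zeros_like(p) for p in self.params]
        dY = 2.0 * resid / resid.size
        i = self._layout[-1]["i"]
        W = self.params[i]
        grads[i] = last.T @ dY
        grads[i + 1] = dY.sum(axis=0)
        dH = np.zeros(top_shape)
        dH[:, -1] = dY @ W.T
        for layer, cache in reversed(caches):
            j = layer["i"]
            if layer["kind"] == "lstm":
                dH, g = _lstm_backward(dH, cache, self.params[j], self.params[j + 1])
                grads[j:j + 3] = g
            else:
                per = layer["units"]
                cf, cb = cache
                dHf = dH[:, :, :per]
                dHb = dH[:, ::-1, per:]
                dXf, gf = _lstm_backward(dHf, cf, self.params[j], self.params[j + 1])
                dXb, gb = _lstm_backward(dHb, cb, self.params[j + 3], self.params[j + 4])
                grads[j:j + 3] = gf
                grads[j + 3:j + 6] = gb
                dH = dXf + dXb[:, ::-1]
        return loss, grads

    def predict(self, X, batch_size: int = 256) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        outs = [self.forward(X[s:s + batch_size])
                for s in range(0, X.shape[0], batch_size)]
        return np.concatenate(outs, axis=0) if outs else np.empty((0, self.n_outputs))


class Adam:
    """Adam optimizer over a flat parameter list."""

    def __init__(self, params: list[np.ndarray], learning_rate: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = learning_rate
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        lr_t = self.lr * np.sqrt(1.0 - b2 ** self.t) / (1.0 - b1 ** self.t)
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            p -= lr_t * m / (np.sqrt(v) + self.eps)
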