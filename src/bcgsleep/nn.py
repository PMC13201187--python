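"""Minimal sequence-model building blocks on numpy with manual backprop.

Implements exactly the layers the staging model needs — dense, (bi)LSTM,
causal dilated 1-D convolution, per-channel layer normalization, ReLU,
ordinary and spatial (channel) dropout, residual blocks and a class-weighted
softmax cross-entropy — each with an analytic backward pass (gradient-checked
in the test suite) and an Adam optimizer.

Sequences are 2-D arrays of shape (T, C): one feature vector per 30-s epoch.
All randomness (initialization, dropout) flows from a single
``numpy.random.Generator`` so training is reproducible from one seed.
"""

from __future__ import annotations

import numpy as np


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class Layer:
    """Base: parameters/grads as parallel dicts; stateless between calls
    except the forward cache consumed by backward."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool, rng: np.random.Generator
                ) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def n_params(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    def zero_grad(self) -> None:
        for k, p in self.params.items():
            self.grads[k] = np.zeros_like(p)


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        scale = np.sqrt(2.0 / (d_in + d_out))
        self.params = {"W": rng.normal(0, scale, (d_in, d_out)),
                       "b": np.zeros(d_out)}
        self.zero_grad()

    def forward(self, x, train, rng):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy):
        self.grads["W"] += self._x.T @ dy
        self.grads["b"] += dy.sum(axis=0)
        return dy @ self.params["W"].T


class ReLU(Layer):
    def forward(self, x, train, rng):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy):
        return np.where(self._mask, dy, 0.0)


class Dropout(Layer):
    """Element dropout with inverted scaling; identity in evaluation mode."""

    def __init__(self, p: float) -> None:
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.p = p

    def forward(self, x, train, rng):
        if not train or self.p == 0.0:
            self._mask = None
            return x
        self._mask = (rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class SpatialDropout(Dropout):
    """Drops whole channels (columns) of the (T, C) sequence."""

    def forward(self, x, train, rng):
        if not train or self.p == 0.0:
            self._mask = None
            return x
        self._mask = (rng.random((1, x.shape[1])) >= self.p) / (1.0 - self.p)
        return x * self._mask


class LayerNorm(Layer):
    """Per-time-step normalization over channels, learnable offset+scale."""

    def __init__(self, channels: int, eps: float = 1e-5) -> None:
        super().__init__()
        self.eps = eps
        self.params = {"g": np.ones(channels), "b": np.zeros(channels)}
        self.zero_grad()

    def forward(self, x, train, rng):
        mu = x.mean(axis=1, keepdims=True)
        var = x.var(axis=1, keepdims=True)
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mu) / self._std
        return self._xhat * self.params["g"] + self.params["b"]

    def backward(self, dy):
        g = self.params["g"]
        xhat, std = self._xhat, self._std
        self.grads["g"] += (dy * xhat).sum(axis=0)
        self.grads["b"] += dy.sum(axis=0)
        c = dy.shape[1]
        dxhat = dy * g
        return (dxhat - dxhat.mean(axis=1, keepdims=True)
                - xhat * (dxhat * xhat).mean(axis=1, keepdims=True)) / std


class CausalConv1D(Layer):
    """Causal dilated 1-D convolution on (T, C_in) -> (T, C_out).

    Output at time t sees inputs t, t-d, ..., t-(k-1)d only (left zero
    padding), so the layer is strictly causal.
    """

    def __init__(self, c_in: int, c_out: int, kernel: int, dilation: int,
                 rng: np.random.Generator) -> None:
        super().__init__()
        self.k, self.d, self.c_in = kernel, dilation, c_in
        scale = np.sqrt(2.0 / (c_in * kernel + c_out))
        self.params = {"W": rng.normal(0, scale, (kernel, c_in, c_out)),
                       "b": np.zeros(c_out)}
        self.zero_grad()

    def forward(self, x, train, rng):
        T = x.shape[0]
        pad = (self.k - 1) * self.d
        self._padded = np.concatenate([np.zeros((pad, self.c_in)), x], axis=0)
        y = np.tile(self.params["b"], (T, 1))
        for j in range(self.k):
            y += self._padded[j * self.d: j * self.d + T] @ self.params["W"][j]
        return y

    def backward(self, dy):
        T = dy.shape[0]
        pad = (self.k - 1) * self.d
        dpadded = np.zeros_like(self._padded)
        for j in range(self.k):
            seg = self._padded[j * self.d: j * self.d + T]
            self.grads["W"][j] += seg.T @ dy
            dpadded[j * self.d: j * self.d + T] += dy @ self.params["W"][j].T
        self.grads["b"] += dy.sum(axis=0)
        return dpadded[pad:]


class LSTM(Layer):
    """Single-direction LSTM returning the full hidden sequence.

    Gate order i, f, g, o; parameters W of shape (4H, D+H) and bias (4H),
    i.e. 4(H(D+H) + H) parameters.
    """

    def __init__(self, d_in: int, hidden: int, rng: np.random.Generator,
                 reverse: bool = False) -> None:
        super().__init__()
        self.d_in, self.h, self.reverse = d_in, hidden, reverse
        scale = 1.0 / np.sqrt(d_in + hidden)
        self.params = {"W": rng.normal(0, scale, (4 * hidden, d_in + hidden)),
                       "b": np.zeros(4 * hidden)}
        # forget-gate bias at 1: standard recurrence stabilizer
        self.params["b"][hidden:2 * hidden] = 1.0
        self.zero_grad()

    def forward(self, x, train, rng):
        if self.reverse:
            x = x[::-1]
        T, H = x.shape[0], self.h
        W, b = self.params["W"], self.params["b"]
        h = np.zeros(H)
        c = np.zeros(H)
        self._cache = []
        out = np.empty((T, H))
        for t in range(T):
            xt = x[t]
            zin = np.concatenate([xt, h])
            z = W @ zin + b
            i = _sigmoid(z[:H])
            f = _sigmoid(z[H:2 * H])
            g = np.tanh(z[2 * H:3 * H])
            o = _sigmoid(z[3 * H:])
            c_prev = c
            c = f * c_prev + i * g
            tc = np.tanh(c)
            h = o * tc
            out[t] = h
            self._cache.append((zin, i, f, g, o, c_prev, tc))
        if self.reverse:
            out = out[::-1]
        return out

    def backward(self, dy):
        if self.reverse:
            dy = dy[::-1]
        T, H = dy.shape[0], self.h
        W = self.params["W"]
        dW, db = self.grads["W"], self.grads["b"]
        dh_next = np.zeros(H)
        dc_next = np.zeros(H)
        dx = np.empty((T, self.d_in))
        for t in range(T - 1, -1, -1):
            zin, i, f, g, o, c_prev, tc = self._cache[t]
            dh = dy[t] + dh_next
            do = dh * tc
            dc = dh * o * (1 - tc ** 2) + dc_next
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dc_next = dc * f
            dz = np.concatenate([
                di * i * (1 - i),
                df * f * (1 - f),
                dg * (1 - g ** 2),
                do * o * (1 - o),
            ])
            dW += np.outer(dz, zin)
            db += dz
            dzin = W.T @ dz
            dx[t] = dzin[: self.d_in]
            dh_next = dzin[self.d_in:]
        if self.reverse:
            dx = dx[::-1]
        return dx


class BiLSTM(Layer):
    """Forward and reverse LSTM, outputs concatenated (T, 2H)."""

    def __init__(self, d_in: int, hidden: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.fwd = LSTM(d_in, hidden, rng, reverse=False)
        self.bwd = LSTM(d_in, hidden, rng, reverse=True)
        self.h = hidden

    @property
    def children(self):
        return [self.fwd, self.bwd]

    def forward(self, x, train, rng):
        return np.concatenate([self.fwd.forward(x, train, rng),
                               self.bwd.forward(x, train, rng)], axis=1)

    def backward(self, dy):
        return (self.fwd.backward(dy[:, : self.h])
                + self.bwd.backward(dy[:, self.h:]))

    def n_params(self) -> int:
        return self.fwd.n_params() + self.bwd.n_params()

    def zero_grad(self) -> None:
        self.fwd.zero_grad()
        self.bwd.zero_grad()


class ResidualBlock(Layer):
    """Two causal dilated convolutions (norm/ReLU/spatial-dropout after
    each) plus an identity skip; a 1x1 convolution lifts the skip only when
    input and output channel counts differ."""

    def __init__(self, c_in: int, filters: int, kernel: int, dilation: int,
                 spatial_dropout: float, rng: np.random.Generator) -> None:
        super().__init__()
        self.main: list[Layer] = []
        for conv_idx in range(2):
            cin = c_in if conv_idx == 0 else filters
            self.main += [
                CausalConv1D(cin, filters, kernel, dilation, rng),
                LayerNorm(filters),
                ReLU(),
                SpatialDropout(spatial_dropout),
            ]
        self.skip = (CausalConv1D(c_in, filters, 1, 1, rng)
                     if c_in != filters else None)

    @property
    def children(self):
        return self.main + ([self.skip] if self.skip is not None else [])

    def forward(self, x, train, rng):
        h = x
        for layer in self.main:
            h = layer.forward(h, train, rng)
        s = x if self.skip is None else self.skip.forward(x, train, rng)
        return h + s

    def backward(self, dy):
        dh = dy
        for layer in reversed(self.main):
            dh = layer.backward(dh)
        ds = dy if self.skip is None else self.skip.backward(dy)
        return dh + ds

    def n_params(self) -> int:
        return sum(layer.n_params() for layer in self.children)

    def zero_grad(self) -> None:
        for layer in self.children:
            layer.zero_grad()


class Sequential:
    """Chain of layers with a shared RNG for dropout; eval mode is
    deterministic."""

    def __init__(self, layers: list[Layer], rng: np.random.Generator) -> None:
        self.layers = layers
        self.rng = rng

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train, self.rng)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def _flat_layers(self) -> list[Layer]:
        flat = []
        for layer in self.layers:
            flat.extend(getattr(layer, "children", [layer]))
        return flat

    def parameters(self) -> list[tuple[Layer, str]]:
        return [(l, k) for l in self._flat_layers() for k in l.params]

    def n_params(self) -> int:
        return sum(layer.n_params() for layer in self.layers)

    def zero_grad(self) -> None:
        for layer in self.layers:
            layer.zero_grad()


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def weighted_cross_entropy(logits: np.ndarray, labels: np.ndarray,
                           class_weights: np.ndarray
                           ) -> tuple[float, np.ndarray]:
    """Class-weighted softmax cross-entropy over a sequence.

    Returns (mean weighted loss, gradient w.r.t. logits).
    """
    p = softmax(logits)
    T = logits.shape[0]
    w = class_weights[labels]
    wsum = w.sum()
    eps = 1e-12
    loss = float(-(w * np.log(p[np.arange(T), labels] + eps)).sum() / wsum)
    dlogits = p.copy()
    dlogits[np.arange(T), labels] -= 1.0
    dlogits *= (w / wsum)[:, None]
    return loss, dlogits


class Adam:
    """Adam on a Sequential's parameters."""

    def __init__(self, model: Sequential, lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8) -> None:
        self.model = model
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.t = 0
        self.m = {id(l): {k: np.zeros_like(p) for k, p in l.params.items()}
                  for l in model._flat_layers()}
        self.v = {id(l): {k: np.zeros_like(p) for k, p in l.params.items()}
                  for l in model._flat_layers()}

    def step(self) -> None:
        self.t += 1
        for layer, key in self.model.parameters():
            g = layer.grads[key]
            m = self.m[id(layer)][key]
            v = self.v[id(layer)][key]
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g ** 2
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            layer.params[key] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
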