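"""Minimal deterministic neural-network building blocks (numpy).

Implements exactly what the hybrid window classifier needs: 2-D
convolution (im2col), batch normalization, ReLU, inverted dropout, dense
layers, a softmax cross-entropy head, and Adam with decoupled weight
decay. Everything is float32, seeded, and single-threaded deterministic.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv2D",
    "BatchNorm",
    "ReLU",
    "Dropout",
    "Dense",
    "Flatten",
    "AdamW",
    "softmax",
    "softmax_cross_entropy",
]

DTYPE = np.float32


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits, labels, sample_weight=None):
    """Mean weighted cross-entropy and the gradient w.r.t. the logits."""
    n = logits.shape[0]
    p = softmax(logits.astype(np.float64))
    eps = 1e-12
    ll = -np.log(p[np.arange(n), labels] + eps)
    if sample_weight is None:
        loss = ll.mean()
        g = p
        g[np.arange(n), labels] -= 1.0
        g /= n
    else:
        w = sample_weight / sample_weight.sum()
        loss = float(np.sum(w * ll))
        g = p * w[:, None]
        g[np.arange(n), labels] -= w
    return float(loss), g.astype(DTYPE)


class Layer:
    params: dict
    grads: dict

    def __init__(self):
        self.params, self.grads = {}, {}

    def forward(self, x, train: bool):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout):  # pragma: no cover - interface
        raise NotImplementedError

    def state(self) -> dict:
        return {k: v.copy() for k, v in self.params.items()}

    def load_state(self, state: dict) -> None:
        for k, v in state.items():
            self.params[k] = v.copy()


def _he_normal(rng, shape, fan_in):
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(DTYPE)


class Conv2D(Layer):
    """Same-padded strided convolution via im2col."""

    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int, rng):
        super().__init__()
        self.c_in, self.c_out, self.k, self.stride = c_in, c_out, kernel, stride
        self.pad = kernel // 2
        self.params["W"] = _he_normal(rng, (c_out, c_in * kernel * kernel), c_in * kernel * kernel)
        self.params["b"] = np.zeros(c_out, dtype=DTYPE)

    def _im2col(self, x):
        n, c, h, w = x.shape
        p, k, s = self.pad, self.k, self.stride
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        ho = (h + 2 * p - k) // s + 1
        wo = (w + 2 * p - k) // s + 1
        cols = np.empty((n, c, k, k, ho, wo), dtype=DTYPE)
        for i in range(k):
            for j in range(k):
                cols[:, :, i, j] = xp[:, :, i : i + s * ho : s, j : j + s * wo : s]
        return cols.reshape(n, c * k * k, ho * wo), (ho, wo), xp.shape

    def forward(self, x, train: bool):
        x = x.astype(DTYPE, copy=False)
        cols, (ho, wo), xp_shape = self._im2col(x)
        self._cache = (cols, x.shape, xp_shape, ho, wo)
        out = np.matmul(self.params["W"], cols)  # (n, c_out, ho*wo)
        out += self.params["b"][None, :, None]
        return out.reshape(x.shape[0], self.c_out, ho, wo)

    def backward(self, dout):
        cols, x_shape, xp_shape, ho, wo = self._cache
        n = x_shape[0]
        d = dout.reshape(n, self.c_out, ho * wo)
        self.grads["W"] = np.tensordot(d, cols, axes=([0, 2], [0, 2]))
        self.grads["b"] = d.sum(axis=(0, 2))
        dcols = np.matmul(self.params["W"].T, d)  # (n, c_in*k*k, ho*wo)
        # col2im: scatter-add each kernel offset back onto the padded grid
        dxp = np.zeros(xp_shape, dtype=DTYPE)
        dc = dcols.reshape(n, self.c_in, self.k, self.k, ho, wo)
        s = self.stride
        for i in range(self.k):
            for j in range(self.k):
                dxp[:, :, i : i + s * ho : s, j : j + s * wo : s] += dc[:, :, i, j]
        p = self.pad
        h, w = x_shape[2], x_shape[3]
        return dxp[:, :, p : p + h, p : p + w]

    def out_shape(self, h, w):
        ho = (h + 2 * self.pad - self.k) // self.stride + 1
        wo = (w + 2 * self.pad - self.k) // self.stride + 1
        return ho, wo


class BatchNorm(Layer):
    """Batch normalization over the batch (and spatial dims for 4-D input)."""

    def __init__(self, n_features: int, momentum: float = 0.9, eps: float = 1e-5):
        super().__init__()
        self.params["gamma"] = np.ones(n_features, dtype=DTYPE)
        self.params["beta"] = np.zeros(n_features, dtype=DTYPE)
        self.running_mean = np.zeros(n_features, dtype=np.float64)
        self.running_var = np.ones(n_features, dtype=np.float64)
        self.momentum, self.eps = momentum, eps

    def _axes(self, x):
        return (0, 2, 3) if x.ndim == 4 else (0,)

    def _shape(self, x):
        return (1, -1, 1, 1) if x.ndim == 4 else (1, -1)

    def forward(self, x, train: bool):
        axes, shp = self._axes(x), self._shape(x)
        if train:
            mean = x.mean(axis=axes, dtype=np.float64)
            var = x.var(axis=axes, dtype=np.float64)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = (1.0 / np.sqrt(var + self.eps)).astype(DTYPE)
        xhat = (x - mean.reshape(shp).astype(DTYPE)) * inv.reshape(shp)
        if train:
            self._cache = (xhat, inv, axes, shp, x.shape)
        return self.params["gamma"].reshape(shp) * xhat + self.params["beta"].reshape(shp)

    def backward(self, dout):
        xhat, inv, axes, shp, x_shape = self._cache
        m = np.prod([x_shape[a] for a in axes])
        self.grads["gamma"] = (dout * xhat).sum(axis=axes)
        self.grads["beta"] = dout.sum(axis=axes)
        g = self.params["gamma"].reshape(shp)
        dxhat = dout * g
        dx = (
            dxhat
            - dxhat.mean(axis=axes, keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=axes, keepdims=True)
        ) * inv.reshape(shp)
        return dx.astype(DTYPE)

    def state(self) -> dict:
        s = super().state()
        s["_running_mean"] = self.running_mean.copy()
        s["_running_var"] = self.running_var.copy()
        return s

    def load_state(self, state: dict) -> None:
        self.running_mean = state["_running_mean"].copy()
        self.running_var = state["_running_var"].copy()
        super().load_state({k: v for k, v in state.items() if not k.startswith("_")})


class ReLU(Layer):
    def forward(self, x, train: bool):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float, rng):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate, self.rng = rate, rng

    def forward(self, x, train: bool):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(DTYPE) / keep
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class Dense(Layer):
    def __init__(self, f_in: int, f_out: int, rng):
        super().__init__()
        self.params["W"] = _he_normal(rng, (f_in, f_out), f_in)
        self.params["b"] = np.zeros(f_out, dtype=DTYPE)

    def forward(self, x, train: bool):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout):
        self.grads["W"] = self._x.T @ dout
        self.grads["b"] = dout.sum(axis=0)
        return dout @ self.params["W"].T


class Flatten(Layer):
    def forward(self, x, train: bool):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class AdamW:
    """Adam with decoupled weight decay (decay applied to W matrices only)."""

    def __init__(self, layers, lr=1e-3, weight_decay=0.0, betas=(0.9, 0.999), eps=1e-8):
        self.layers = layers
        self.lr, self.wd = lr, weight_decay
        self.b1, self.b2, self.eps = betas[0], betas[1], eps
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in lay.params.items()} for lay in layers]
        self.v = [{k: np.zeros_like(v) for k, v in lay.params.items()} for lay in layers]

    def step(self):
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for lay, m, v in zip(self.layers, self.m, self.v):
            for k, p in lay.params.items():
                g = lay.grads.get(k)
                if g is None:
                    continue
                m[k] = self.b1 * m[k] + (1 - self.b1) * g
                v[k] = self.b2 * v[k] + (1 - self.b2) * g * g
                update = (m[k] / bc1) / (np.sqrt(v[k] / bc2) + self.eps)
                if self.wd and k == "W":
                    update = update + self.wd * p
                lay.params[k] = (p - self.lr * update).astype(DTYPE)
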