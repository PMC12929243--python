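"""Minimal NumPy neural-network engine used by the reference detector and
pose regressor.

The two stage networks of this package are deliberately small (a few conv
blocks and a linear head) so that they train from scratch on a single CPU in
minutes; this module provides exactly the pieces they need — strided 2-D
convolution via im2col, ReLU, linear layers, stable binary cross-entropy,
and SGD(momentum)+cosine / Adam optimizers — with fully deterministic
seeded initialization.  Everything is float32, NCHW.

The backward pass is hand-derived per layer; `Sequential` chains layers and
exposes a flat parameter list for the optimizers.  Checkpoints are plain
``.npz`` files.
"""

from __future__ import annotations

import math
from typing import List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "Conv2d",
    "ReLU",
    "Flatten",
    "Linear",
    "Sequential",
    "SGD",
    "Adam",
    "cosine_lr",
    "sigmoid",
    "bce_with_logits",
    "avg_pool",
]


def _as_f32(x) -> np.ndarray:
    return np.ascontiguousarray(x, dtype=np.float32)


class Layer:
    def params(self) -> List[Tuple[str, np.ndarray, np.ndarray]]:
        """(name, parameter, gradient) triples; empty for stateless layers."""
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2d(Layer):
    """2-D convolution (cross-correlation), stride >= 1, symmetric zero pad."""

    def __init__(self, in_ch: int, out_ch: int, k: int = 3, stride: int = 1,
                 pad: Optional[int] = None, rng: Optional[np.random.Generator] = None):
        self.in_ch, self.out_ch, self.k, self.stride = in_ch, out_ch, k, stride
        self.pad = (k // 2) if pad is None else pad
        rng = rng or np.random.default_rng(0)
        fan_in = in_ch * k * k
        # He initialization for ReLU nets
        self.W = _as_f32(rng.normal(0.0, math.sqrt(2.0 / fan_in), (out_ch, in_ch, k, k)))
        self.b = np.zeros(out_ch, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cache = None

    def params(self):
        return [("W", self.W, self.dW), ("b", self.b, self.db)]

    def _im2col(self, xp: np.ndarray, ho: int, wo: int) -> np.ndarray:
        n, c, _, _ = xp.shape
        k, s = self.k, self.stride
        cols = np.empty((n, c, k, k, ho, wo), dtype=np.float32)
        for i in range(k):
            for j in range(k):
                cols[:, :, i, j] = xp[:, :, i : i + ho * s : s, j : j + wo * s : s]
        return cols

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        k, s, p = self.k, self.stride, self.pad
        ho = (h + 2 * p - k) // s + 1
        wo = (w + 2 * p - k) // s + 1
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        cols = self._im2col(xp, ho, wo)  # (n, c, k, k, ho, wo)
        cols2 = cols.reshape(n, c * k * k, ho * wo)
        Wm = self.W.reshape(self.out_ch, c * k * k)
        out = np.matmul(Wm, cols2)  # (n, out_ch, ho*wo), BLAS per batch item
        out += self.b[None, :, None]
        self._cache = (xp.shape, cols2, (n, ho, wo))
        return out.reshape(n, self.out_ch, ho, wo)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xp_shape, cols2, (n, ho, wo) = self._cache
        k, s, p = self.k, self.stride, self.pad
        c = self.in_ch
        g = grad.reshape(n, self.out_ch, ho * wo)
        Wm = self.W.reshape(self.out_ch, c * k * k)
        self.dW[...] = np.matmul(g, cols2.transpose(0, 2, 1)).sum(axis=0).reshape(self.W.shape)
        self.db[...] = g.sum(axis=(0, 2))
        dcols = np.matmul(Wm.T, g)
        dcols = dcols.reshape(n, c, k, k, ho, wo)
        dxp = np.zeros(xp_shape, dtype=np.float32)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + ho * s : s, j : j + wo * s : s] += dcols[:, :, i, j]
        if p:
            return dxp[:, :, p:-p, p:-p]
        return dxp


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(np.float32, copy=False)

    def backward(self, grad):
        return np.where(self._mask, grad, 0.0).astype(np.float32, copy=False)


class Flatten(Layer):
    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Linear(Layer):
    def __init__(self, n_in: int, n_out: int, rng: Optional[np.random.Generator] = None):
        rng = rng or np.random.default_rng(0)
        self.W = _as_f32(rng.normal(0.0, math.sqrt(2.0 / n_in), (n_out, n_in)))
        self.b = np.zeros(n_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [("W", self.W, self.dW), ("b", self.b, self.db)]

    def forward(self, x):
        self._x = x
        return x @ self.W.T + self.b

    def backward(self, grad):
        self.dW[...] = grad.T @ self._x
        self.db[...] = grad.sum(axis=0)
        return (grad @ self.W).astype(np.float32, copy=False)


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self):
        out = []
        for i, layer in enumerate(self.layers):
            for name, p, g in layer.params():
                out.append((f"{i}.{name}", p, g))
        return out

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    # -- checkpointing -----------------------------------------------------
    def state_dict(self) -> dict:
        return {name: p.copy() for name, p, _ in self.params()}

    def load_state_dict(self, state: dict) -> None:
        for name, p, _ in self.params():
            p[...] = state[name]

    def save(self, path) -> None:
        np.savez(path, **self.state_dict())

    def load(self, path) -> None:
        with np.load(path) as data:
            self.load_state_dict({k: data[k] for k in data.files})


# ---------------------------------------------------------------------------
# functional pieces


def avg_pool(x: np.ndarray, factor: int) -> np.ndarray:
    """Non-learned average pooling by an integer factor (used to downsample
    frames before the detector backbone)."""
    n, c, h, w = x.shape
    f = factor
    return x.reshape(n, c, h // f, f, w // f, f).mean(axis=(3, 5))


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def bce_with_logits(logits: np.ndarray, targets: np.ndarray,
                    weights: Optional[np.ndarray] = None) -> Tuple[float, np.ndarray]:
    """Numerically stable binary cross-entropy on logits.

    Returns (mean loss, gradient w.r.t. logits).  ``weights`` rescales each
    element's contribution (still normalized by the element count).
    """
    z = np.asarray(logits, dtype=np.float64)
    t = np.asarray(targets, dtype=np.float64)
    # log(1 + e^z) computed stably
    loss_el = np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))
    p = sigmoid(z)
    grad = p - t
    if weights is not None:
        loss_el = loss_el * weights
        grad = grad * weights
    n = z.size
    return float(loss_el.sum() / n), (grad / n).astype(np.float32)


# ---------------------------------------------------------------------------
# optimizers


def cosine_lr(lr0: float, step: int, total_steps: int, lr_min: float = 0.0) -> float:
    """Cosine annealing from ``lr0`` down to ``lr_min`` over ``total_steps``."""
    if total_steps <= 1:
        return lr0
    t = min(step, total_steps - 1) / (total_steps - 1)
    return lr_min + 0.5 * (lr0 - lr_min) * (1.0 + math.cos(math.pi * t))


class SGD:
    """SGD with Nesterov-free momentum and optional weight decay."""

    def __init__(self, params: Sequence[Tuple[str, np.ndarray, np.ndarray]],
                 lr: float = 1e-2, momentum: float = 0.9, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.v = [np.zeros_like(p) for _, p, _ in self.params]

    def step(self, lr: Optional[float] = None) -> None:
        lr = self.lr if lr is None else lr
        for (name, p, g), v in zip(self.params, self.v):
            grad = g
            if self.weight_decay and p.ndim > 1:
                grad = grad + self.weight_decay * p
            v *= self.momentum
            v += grad
            p -= lr * v


class Adam:
    """Adam, optionally with decoupled weight decay on matrix/conv weights."""

    def __init__(self, params: Sequence[Tuple[str, np.ndarray, np.ndarray]],
                 lr: float = 1e-4, betas: Tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.m = [np.zeros_like(p) for _, p, _ in self.params]
        self.v = [np.zeros_like(p) for _, p, _ in self.params]
        self.t = 0

    def step(self, lr: Optional[float] = None) -> None:
        lr = self.lr if lr is None else lr
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for (name, p, g), m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * (g * g)
            p -= lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            if self.weight_decay and p.ndim > 1:
                p -= lr * self.weight_decay * p
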