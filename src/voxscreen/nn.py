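"""Minimal 3D convolutional network machinery in numpy.

Implements exactly what the pose rescorer and binder classifier need:
strided 3D convolutions (im2col over BLAS matmul), ReLU, global average
pooling, dense layers, softmax cross-entropy and sigmoid binary
cross-entropy losses, and the rectified Adam optimizer.  Gradients are
hand-derived and checked numerically in the test suite.  Everything is
deterministic given the seed and single-threaded execution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .errors import ConfigurationError, InputError

__all__ = [
    "Conv3d",
    "ReLU",
    "GlobalAvgPool",
    "Dense",
    "Sequential",
    "softmax",
    "softmax_cross_entropy",
    "sigmoid",
    "sigmoid_bce",
    "RAdam",
]


class Layer:
    """Base layer: ``params()`` exposes (name, value, grad) triples."""

    def params(self) -> List[Tuple[str, np.ndarray, np.ndarray]]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv3d(Layer):
    """3D convolution with cubic kernel, symmetric zero padding and stride."""

    def __init__(self, c_in: int, c_out: int, kernel: int = 3, stride: int = 1,
                 pad: Optional[int] = None, rng: Optional[np.random.Generator] = None):
        if rng is None:
            rng = np.random.default_rng(0)
        self.c_in, self.c_out, self.k, self.stride = c_in, c_out, kernel, stride
        self.pad = kernel // 2 if pad is None else pad
        fan_in = c_in * kernel**3
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, fan_in)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cache = None

    def params(self):
        return [("W", self.W, self.dW), ("b", self.b, self.db)]

    def _im2col(self, xp: np.ndarray, d_out: int) -> np.ndarray:
        B = xp.shape[0]
        win = np.lib.stride_tricks.sliding_window_view(xp, (self.k, self.k, self.k), axis=(2, 3, 4))
        win = win[:, :, ::self.stride, ::self.stride, ::self.stride]
        win = win[:, :, :d_out, :d_out, :d_out]
        # (B, C, D', H', W', k, k, k) -> (B, P, C*k^3)
        cols = win.transpose(0, 2, 3, 4, 1, 5, 6, 7).reshape(B, d_out**3, -1)
        return np.ascontiguousarray(cols)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if x.ndim != 5 or x.shape[1] != self.c_in:
            raise InputError(f"Conv3d expects (B,{self.c_in},D,D,D), got {x.shape}")
        B, _, D = x.shape[0], x.shape[1], x.shape[2]
        d_out = (D + 2 * self.pad - self.k) // self.stride + 1
        xp = np.pad(x, ((0, 0), (0, 0)) + ((self.pad, self.pad),) * 3)
        cols = self._im2col(xp, d_out)
        y = cols @ self.W.T + self.b  # (B, P, c_out)
        if train:
            self._cache = (cols, xp.shape, D, d_out)
        return y.transpose(0, 2, 1).reshape(B, self.c_out, d_out, d_out, d_out)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols, xp_shape, D, d_out = self._cache
        B = dy.shape[0]
        dyf = dy.reshape(B, self.c_out, -1).transpose(0, 2, 1)  # (B, P, c_out)
        self.dW[...] = np.einsum("bpo,bpi->oi", dyf, cols)
        self.db[...] = dyf.sum(axis=(0, 1))
        dcols = dyf @ self.W  # (B, P, C*k^3)
        dcols = dcols.reshape(B, d_out, d_out, d_out, self.c_in, self.k, self.k, self.k)
        dxp = np.zeros(xp_shape, dtype=np.float32)
        s = self.stride
        for i in range(self.k):
            for j in range(self.k):
                for l in range(self.k):
                    dxp[:, :,
                        i:i + s * d_out:s,
                        j:j + s * d_out:s,
                        l:l + s * d_out:s] += dcols[:, :, :, :, :, i, j, l].transpose(0, 4, 1, 2, 3)
        p = self.pad
        if p:
            return dxp[:, :, p:p + D, p:p + D, p:p + D]
        return dxp


class ReLU(Layer):
    def forward(self, x, train: bool = False):
        if train:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, dy):
        return dy * self._mask


class GlobalAvgPool(Layer):
    """(B, C, D, H, W) -> (B, C) mean over the spatial dimensions."""

    def forward(self, x, train: bool = False):
        self._shape = x.shape
        return x.mean(axis=(2, 3, 4))

    def backward(self, dy):
        B, C, D, H, W = self._shape
        return np.broadcast_to(
            dy[:, :, None, None, None], self._shape
        ) / (D * H * W)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: Optional[np.random.Generator] = None):
        if rng is None:
            rng = np.random.default_rng(0)
        self.W = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_out, n_in)).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [("W", self.W, self.dW), ("b", self.b, self.db)]

    def forward(self, x, train: bool = False):
        if train:
            self._x = x
        return x @ self.W.T + self.b

    def backward(self, dy):
        self.dW[...] = dy.T @ self._x
        self.db[...] = dy.sum(axis=0)
        return dy @ self.W


class Sequential(Layer):
    def __init__(self, layers: Sequence[Layer]):
        self.layers = list(layers)

    def params(self):
        out = []
        for i, layer in enumerate(self.layers):
            for name, v, g in layer.params():
                out.append((f"{i}.{name}", v, g))
        return out

    def forward(self, x, train: bool = False):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def state_dict(self) -> Dict[str, np.ndarray]:
        return {name: v.copy() for name, v, _ in self.params()}

    def load_state_dict(self, state: Dict[str, np.ndarray]) -> None:
        for name, v, _ in self.params():
            if name not in state:
                raise ConfigurationError(f"missing parameter {name} in state dict")
            if state[name].shape != v.shape:
                raise ConfigurationError(f"shape mismatch for {name}")
            v[...] = state[name]


# ---------------------------------------------------------------------------
# Losses


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean categorical cross-entropy; ``labels`` are integer class ids.

    Returns (loss, dlogits) with dlogits already averaged over the batch.
    """
    B = logits.shape[0]
    p = softmax(logits)
    eps = 1e-12
    loss = -np.mean(np.log(p[np.arange(B), labels] + eps))
    d = p.copy()
    d[np.arange(B), labels] -= 1.0
    return loss, d / B


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def sigmoid_bce(logits: np.ndarray, targets: np.ndarray):
    """Mean binary cross-entropy on logits; returns (loss, dlogits)."""
    B = logits.shape[0]
    p = sigmoid(logits)
    loss = float(np.mean(
        np.maximum(logits, 0) - logits * targets + np.log1p(np.exp(-np.abs(logits)))
    ))
    return loss, (p - targets) / B


# ---------------------------------------------------------------------------
# Optimizer


class RAdam:
    """Rectified Adam (variance-rectified adaptive learning rate).

    Falls back to un-adapted momentum SGD while the variance estimate is
    untrustworthy (rho_t <= 4), then switches to rectified Adam updates.
    """

    def __init__(self, net: Sequential, lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.net = net
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {name: np.zeros_like(v) for name, v, _ in net.params()}
        self.v = {name: np.zeros_like(v) for name, v, _ in net.params()}
        self.rho_inf = 2.0 / (1.0 - beta2) - 1.0

    def step(self) -> None:
        self.t += 1
        t, b1, b2 = self.t, self.b1, self.b2
        rho_t = self.rho_inf - 2.0 * t * b2**t / (1.0 - b2**t)
        for name, value, grad in self.net.params():
            m = self.m[name]
            v = self.v[name]
            m[...] = b1 * m + (1 - b1) * grad
            v[...] = b2 * v + (1 - b2) * grad**2
            m_hat = m / (1.0 - b1**t)
            if rho_t > 4.0:
                r = np.sqrt(
                    ((rho_t - 4.0) * (rho_t - 2.0) * self.rho_inf)
                    / ((self.rho_inf - 4.0) * (self.rho_inf - 2.0) * rho_t)
                )
                v_hat = np.sqrt(v / (1.0 - b2**t)) + self.eps
                value -= self.lr * r * m_hat / v_hat
            else:
                value -= self.lr * m_hat
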