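"""Minimal CPU neural-network stack used by the CNN feature extractors.

Implements exactly the layers the two extractor architectures need —
2-D/1-D convolution ("same" padding, stride 1) via im2col, 2x2 max
pooling, global max pooling, dense layers, ReLU — plus softmax
cross-entropy and the Adam optimizer. Everything is plain numpy: forward
and backward passes are deterministic given the initialisation seed, so
two identically seeded trainings produce bit-identical weights.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Conv2D",
    "Conv1D",
    "MaxPool2D",
    "GlobalMaxPool1D",
    "Dense",
    "ReLU",
    "Flatten",
    "Sequential",
    "softmax_cross_entropy",
    "Adam",
]


class Layer:
    """Base layer: forward caches what backward needs; params() exposes
    (value, gradient) pairs for the optimizer."""

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def params(self) -> list[tuple[np.ndarray, np.ndarray]]:
        return []


def _he_normal(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Conv2D(Layer):
    """2-D convolution, stride 1, "same" zero padding, odd kernel size."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int, rng: np.random.Generator):
        if kernel % 2 != 1:
            raise ValueError("kernel size must be odd for 'same' padding")
        self.k = kernel
        self.in_channels = in_channels
        self.out_channels = out_channels
        fan_in = in_channels * kernel * kernel
        self.W = _he_normal(rng, (out_channels, fan_in), fan_in)
        self.b = np.zeros(out_channels)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        N, C, H, W = x.shape
        if C != self.in_channels:
            raise ValueError(f"expected {self.in_channels} input channels, got {C}")
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = sliding_window_view(xp, (self.k, self.k), axis=(2, 3))  # N,C,H,W,k,k
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(N * H * W, -1)  # N*H*W x C*k*k
        self._cols = cols
        self._shape = (N, C, H, W)
        out = cols @ self.W.T + self.b
        return out.reshape(N, H, W, self.out_channels).transpose(0, 3, 1, 2)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        N, C, H, W = self._shape
        g = grad.transpose(0, 2, 3, 1).reshape(N * H * W, self.out_channels)
        self.dW[...] = g.T @ self._cols
        self.db[...] = g.sum(axis=0)
        dcols = (g @ self.W).reshape(N, H, W, C, self.k, self.k)
        p = self.k // 2
        dxp = np.zeros((N, C, H + 2 * p, W + 2 * p))
        for i in range(self.k):
            for j in range(self.k):
                dxp[:, :, i : i + H, j : j + W] += dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        return dxp[:, :, p : p + H, p : p + W]

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]


class Conv1D(Layer):
    """1-D convolution, stride 1, "same" zero padding, odd kernel size."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int, rng: np.random.Generator):
        if kernel % 2 != 1:
            raise ValueError("kernel size must be odd for 'same' padding")
        self.k = kernel
        self.in_channels = in_channels
        self.out_channels = out_channels
        fan_in = in_channels * kernel
        self.W = _he_normal(rng, (out_channels, fan_in), fan_in)
        self.b = np.zeros(out_channels)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        N, C, L = x.shape
        if C != self.in_channels:
            raise ValueError(f"expected {self.in_channels} input channels, got {C}")
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p)))
        win = sliding_window_view(xp, self.k, axis=2)  # N,C,L,k
        cols = win.transpose(0, 2, 1, 3).reshape(N * L, -1)
        self._cols = cols
        self._shape = (N, C, L)
        out = cols @ self.W.T + self.b
        return out.reshape(N, L, self.out_channels).transpose(0, 2, 1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        N, C, L = self._shape
        g = grad.transpose(0, 2, 1).reshape(N * L, self.out_channels)
        self.dW[...] = g.T @ self._cols
        self.db[...] = g.sum(axis=0)
        dcols = (g @ self.W).reshape(N, L, C, self.k)
        p = self.k // 2
        dxp = np.zeros((N, C, L + 2 * p))
        for i in range(self.k):
            dxp[:, :, i : i + L] += dcols[:, :, :, i].transpose(0, 2, 1)
        return dxp[:, :, p : p + L]

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]


class MaxPool2D(Layer):
    """Non-overlapping max pooling (stride = pool size). Trailing rows or
    columns that do not fill a window are cropped."""

    def __init__(self, size: int = 2):
        self.size = size

    def forward(self, x: np.ndarray) -> np.ndarray:
        s = self.size
        N, C, H, W = x.shape
        Ho, Wo = H // s, W // s
        if Ho < 1 or Wo < 1:
            raise ValueError(f"spatial size {(H, W)} too small for pool size {s}")
        xc = x[:, :, : Ho * s, : Wo * s]
        blocks = xc.reshape(N, C, Ho, s, Wo, s).transpose(0, 1, 2, 4, 3, 5).reshape(
            N, C, Ho, Wo, s * s
        )
        self._argmax = blocks.argmax(axis=-1)
        self._shape = (N, C, H, W)
        return blocks.max(axis=-1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        s = self.size
        N, C, H, W = self._shape
        Ho, Wo = H // s, W // s
        dblocks = np.zeros((N, C, Ho, Wo, s * s))
        np.put_along_axis(dblocks, self._argmax[..., None], grad[..., None], axis=-1)
        dx = np.zeros((N, C, H, W))
        dx[:, :, : Ho * s, : Wo * s] = dblocks.reshape(N, C, Ho, Wo, s, s).transpose(
            0, 1, 2, 4, 3, 5
        ).reshape(N, C, Ho * s, Wo * s)
        return dx


class GlobalMaxPool1D(Layer):
    """Max over the length axis: (N, C, L) -> (N, C)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._argmax = x.argmax(axis=2)
        self._shape = x.shape
        return x.max(axis=2)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        dx = np.zeros(self._shape)
        N, C, _ = self._shape
        n_idx, c_idx = np.meshgrid(np.arange(N), np.arange(C), indexing="ij")
        dx[n_idx, c_idx, self._argmax] = grad
        return dx


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        self.W = _he_normal(rng, (in_features, out_features), in_features)
        self.b = np.zeros(out_features)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.dW[...] = self._x.T @ grad
        self.db[...] = grad.sum(axis=0)
        return grad @ self.W.T

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return np.where(self._mask, grad, 0.0)


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = list(layers)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def params(self):
        return [p for layer in self.layers for p in layer.params()]


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy of softmax(logits) against integer labels.

    Returns (loss, gradient w.r.t. logits).
    """
    z = logits - logits.max(axis=1, keepdims=True)
    expz = np.exp(z)
    probs = expz / expz.sum(axis=1, keepdims=True)
    n = logits.shape[0]
    loss = float(-np.mean(np.log(probs[np.arange(n), labels] + 1e-300)))
    grad = probs
    grad[np.arange(n), labels] -= 1.0
    return loss, grad / n


class Adam:
    """Adam optimizer over a fixed list of (param, grad) pairs."""

    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in self.params]
        self.v = [np.zeros_like(p) for p, _ in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, (p, g) in enumerate(self.params):
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
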