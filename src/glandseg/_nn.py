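"""Minimal CNN engine (numpy, CPU).

Implements exactly the building blocks the pixel classifiers need: valid
2-D convolution, 2x2 max-pooling with floor semantics, ReLU, fully connected
layers, inverted dropout, and a softmax / cross-entropy head.  Forward and
backward passes use im2col so the heavy lifting is BLAS matrix products.

Arrays are float32 throughout; layouts are (N, C, H, W).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Conv2D",
    "MaxPool2",
    "ReLU",
    "Flatten",
    "Dense",
    "Dropout",
    "softmax",
    "softmax_cross_entropy",
    "SGDMomentum",
]


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N, C, H, W) -> (N*Ho*Wo, C*k*k) patch matrix for a valid k x k conv."""
    n, c, h, w = x.shape
    ho, wo = h - k + 1, w - k + 1
    win = sliding_window_view(x, (k, k), axis=(2, 3))  # (N, C, Ho, Wo, k, k)
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * k * k)
    return np.ascontiguousarray(cols, dtype=np.float32)


class Layer:
    params: list[np.ndarray] = []
    grads: list[np.ndarray] = []

    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2D(Layer):
    """Valid (unpadded) convolution followed by nothing; pair with ReLU."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 rng: np.random.Generator, needs_input_grad: bool = True):
        fan_in = in_channels * kernel * kernel
        limit = np.sqrt(3.0 / fan_in)  # variance-preserving (LeCun) uniform
        self.w = rng.uniform(-limit, limit,
                             (out_channels, in_channels, kernel, kernel)
                             ).astype(np.float32)
        self.b = np.zeros(out_channels, dtype=np.float32)
        self.kernel = kernel
        self.needs_input_grad = needs_input_grad
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]
        self._x_shape: tuple | None = None
        self._cols: np.ndarray | None = None

    def forward(self, x, train=False, rng=None):
        n, c, h, w = x.shape
        k = self.kernel
        if h < k or w < k:
            raise ValueError(f"input {h}x{w} smaller than kernel {k}")
        ho, wo = h - k + 1, w - k + 1
        cols = _im2col(x, k)
        self._x_shape = x.shape
        self._cols = cols if train else None
        wr = self.w.reshape(self.w.shape[0], -1)
        out = cols @ wr.T + self.b
        return out.reshape(n, ho, wo, -1).transpose(0, 3, 1, 2)

    def backward(self, dout):
        n, f, ho, wo = dout.shape
        k = self.kernel
        c = self._x_shape[1]
        dflat = np.ascontiguousarray(
            dout.transpose(0, 2, 3, 1).reshape(-1, f), dtype=np.float32
        )
        self.grads[0][...] = (dflat.T @ self._cols).reshape(self.w.shape)
        self.grads[1][...] = dflat.sum(axis=0)
        self._cols = None
        if not self.needs_input_grad:
            return None
        # accumulate the input gradient channel-last so every scatter-add is
        # a contiguous view; one small matmul per kernel offset
        h, w = self._x_shape[2], self._x_shape[3]
        dx_nhwc = np.zeros((n, h, w, c), dtype=np.float32)
        for i in range(k):
            for j in range(k):
                contrib = dflat @ self.w[:, :, i, j]  # (N*Ho*Wo, C)
                dx_nhwc[:, i:i + ho, j:j + wo, :] += contrib.reshape(n, ho, wo, c)
        return np.ascontiguousarray(dx_nhwc.transpose(0, 3, 1, 2))


class MaxPool2(Layer):
    """2x2 max-pooling, stride 2; odd trailing rows/cols are dropped (floor)."""

    def forward(self, x, train=False, rng=None):
        n, c, h, w = x.shape
        h2, w2 = h // 2, w // 2
        xc = x[:, :, : 2 * h2, : 2 * w2].reshape(n, c, h2, 2, w2, 2)
        windows = xc.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h2, w2, 4)
        self._argmax = windows.argmax(axis=-1)
        self._in_shape = x.shape
        return windows.max(axis=-1)

    def backward(self, dout):
        n, c, h2, w2 = dout.shape
        dwin = np.zeros((n, c, h2, w2, 4), dtype=np.float32)
        np.put_along_axis(dwin, self._argmax[..., None], dout[..., None], axis=-1)
        dx = np.zeros(self._in_shape, dtype=np.float32)
        dxc = dwin.reshape(n, c, h2, w2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        dx[:, :, : 2 * h2, : 2 * w2] = dxc.reshape(n, c, 2 * h2, 2 * w2)
        return dx


class ReLU(Layer):
    def forward(self, x, train=False, rng=None):
        self._mask = x > 0
        return np.where(self._mask, x, 0)

    def backward(self, dout):
        return np.where(self._mask, dout, 0)


class Flatten(Layer):
    def forward(self, x, train=False, rng=None):
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._in_shape)


class Dense(Layer):
    def __init__(self, in_units: int, out_units: int, rng: np.random.Generator):
        limit = np.sqrt(3.0 / in_units)
        self.w = rng.uniform(-limit, limit, (out_units, in_units)).astype(np.float32)
        self.b = np.zeros(out_units, dtype=np.float32)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x, train=False, rng=None):
        self._x = x if train else None
        return x @ self.w.T + self.b

    def backward(self, dout):
        self.grads[0][...] = dout.T @ self._x
        self.grads[1][...] = dout.sum(axis=0)
        dx = dout @ self.w
        self._x = None
        return dx


class Dropout(Layer):
    """Inverted dropout: active only in training mode."""

    def __init__(self, rate: float):
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate

    def forward(self, x, train=False, rng=None):
        if not train or self.rate == 0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("training-mode dropout needs a random generator")
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, dout):
        if self._mask is None:
            return dout
        return dout * self._mask


def softmax(logits: np.ndarray) -> np.ndarray:
    """Row-wise softmax computed in float64 for tight normalization."""
    z = np.asarray(logits, dtype=np.float64)
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, targets: np.ndarray
                          ) -> tuple[float, np.ndarray]:
    """Mean cross-entropy loss and its gradient w.r.t. the logits."""
    p = softmax(logits)
    n = len(targets)
    loss = float(-np.log(np.maximum(p[np.arange(n), targets], 1e-300)).mean())
    dlogits = p.astype(np.float32)
    dlogits[np.arange(n), targets] -= 1.0
    return loss, dlogits / n


class SGDMomentum:
    """SGD with classical momentum and decoupled-in-gradient weight decay."""

    def __init__(self, params: list[np.ndarray], weight_decay: float = 0.0):
        self.params = params
        self.weight_decay = weight_decay
        self.velocity = [np.zeros_like(p) for p in params]

    def step(self, grads: list[np.ndarray], lr: float, momentum: float) -> None:
        for p, g, v in zip(self.params, grads, self.velocity):
            gg = g + self.weight_decay * p if p.ndim > 1 else g  # no decay on biases
            v *= momentum
            v -= lr * gg
            p += v
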