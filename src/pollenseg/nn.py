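"""Minimal CPU neural-network layers with explicit backpropagation.

The segmentation and classification networks used here are tiny (desk-scale
profiles stay under 1e5 parameters), so a small, fully deterministic numpy
layer library is sufficient and keeps every activation and gradient openly
inspectable — which the class-activation mapping stage needs anyway.

Conventions: tensors are ``float64`` arrays shaped ``(N, C, H, W)`` for images
and ``(N, F)`` for features.  Each layer caches what its backward pass needs;
``backward`` consumes the gradient w.r.t. its output and returns the gradient
w.r.t. its input, accumulating parameter gradients into ``Param.grad``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Conv2d",
    "ReLU",
    "MaxPool2d",
    "UpsampleNearest2d",
    "GlobalAvgPool",
    "Linear",
    "Sequential",
    "Adam",
    "softmax",
    "cross_entropy",
    "pixel_cross_entropy",
]


class Param:
    """A trainable array with its accumulated gradient."""

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=float)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError


class Conv2d(Layer):
    """3x3 (or kxk) same-padding convolution, stride 1, via im2col."""

    def __init__(self, in_ch: int, out_ch: int, k: int = 3, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / (in_ch * k * k))  # He initialization
        self.W = Param(rng.normal(0.0, scale, (out_ch, in_ch, k, k)))
        self.b = Param(np.zeros(out_ch))
        self.k = k

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        k, p = self.k, self.k // 2
        n, c, h, w = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        # (N, C, H, W, k, k) -> (N*H*W, C*k*k)
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * k * k)
        out_ch = self.W.value.shape[0]
        y = cols @ self.W.value.reshape(out_ch, -1).T + self.b.value
        self._cache = (cols, x.shape)
        return y.reshape(n, h, w, out_ch).transpose(0, 3, 1, 2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols, xshape = self._cache
        n, c, h, w = xshape
        k, p = self.k, self.k // 2
        out_ch = dy.shape[1]
        dyf = dy.transpose(0, 2, 3, 1).reshape(-1, out_ch)
        self.W.grad += (dyf.T @ cols).reshape(self.W.value.shape)
        self.b.grad += dyf.sum(axis=0)
        dcols = (dyf @ self.W.value.reshape(out_ch, -1)).reshape(n, h, w, c, k, k)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p))
        for di in range(k):
            for dj in range(k):
                dxp[:, :, di : di + h, dj : dj + w] += dcols[:, :, :, :, di, dj].transpose(0, 3, 1, 2)
        return dxp[:, :, p : p + h, p : p + w]


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class MaxPool2d(Layer):
    """2x2 max pooling; ties share the gradient equally (subgradient choice)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
        y = xr.max(axis=(3, 5))
        mask = xr == y[:, :, :, None, :, None]
        self._cache = (mask, mask.sum(axis=(3, 5)), x.shape)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        mask, counts, xshape = self._cache
        g = (dy / counts)[:, :, :, None, :, None] * mask
        return g.reshape(xshape)


class UpsampleNearest2d(Layer):
    """Nearest-neighbour 2x upsampling."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = dy.shape
        return dy.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class GlobalAvgPool(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        return np.broadcast_to(dy[:, :, None, None], self._shape) / (h * w)


class Linear(Layer):
    def __init__(self, in_f: int, out_f: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.W = Param(rng.normal(0.0, np.sqrt(2.0 / in_f), (out_f, in_f)))
        self.b = Param(np.zeros(out_f))

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.value.T + self.b.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.W.grad += dy.T @ self._x
        self.b.grad += dy.sum(axis=0)
        return dy @ self.W.value


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self) -> list[Param]:
        return [p for l in self.layers for p in l.params()]

    def forward(self, x: np.ndarray) -> np.ndarray:
        for l in self.layers:
            x = l.forward(x)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for l in reversed(self.layers):
            dy = l.backward(dy)
        return dy


class Adam:
    """Adam optimizer over a list of :class:`Param`."""

    def __init__(self, params: list[Param], lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * p.grad
            v[...] = self.b2 * v + (1 - self.b2) * p.grad**2
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def softmax(logits: np.ndarray, axis: int = 1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean softmax cross-entropy over ``(N, C)`` logits; returns (loss, dlogits)."""
    n = logits.shape[0]
    p = softmax(logits, axis=1)
    loss = -np.log(p[np.arange(n), labels] + 1e-12).mean()
    d = p.copy()
    d[np.arange(n), labels] -= 1.0
    return float(loss), d / n


def pixel_cross_entropy(logits: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean per-pixel cross-entropy; logits ``(N, C, H, W)``, target ``(N, H, W)`` int."""
    n, c, h, w = logits.shape
    p = softmax(logits, axis=1)
    pt = np.take_along_axis(p, target[:, None], axis=1)[:, 0]
    loss = -np.log(pt + 1e-12).mean()
    onehot = np.arange(c).reshape(1, c, 1, 1) == target[:, None]
    d = (p - onehot) / (n * h * w)
    return float(loss), d
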