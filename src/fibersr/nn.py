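"""Minimal CPU neural-network engine for the restoration autoencoders.

Implements exactly the layers the encoder-decoder needs — 3x3 "same" padded
convolution, ReLU, 2x2 max pooling, 2x nearest-neighbour up-sampling and a
sigmoid output head — with hand-written backpropagation and an Adam
optimizer, all in numpy.  Convolution is evaluated as an im2col matrix
product so the heavy lifting lands in BLAS.

Tensors are ``(N, C, H, W)`` float32 throughout.  Everything is seeded and
deterministic: identical seeds and data give bit-identical parameters.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv2D", "ReLU", "MaxPool2", "Upsample2", "Sigmoid", "Sequential", "Adam"]


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N, C, H, W) -> (N, H*W, C*k*k) patches with 'same' zero padding."""
    n, c, h, w = x.shape
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    # win: (N, C, H, W, k, k) -> (N, H*W, C*k*k)
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n, h * w, c * k * k)
    return np.ascontiguousarray(cols)


def _col2im(dcols: np.ndarray, shape: tuple[int, int, int, int], k: int) -> np.ndarray:
    """Adjoint of :func:`_im2col`: scatter-add patches back to an image."""
    n, c, h, w = shape
    p = k // 2
    d6 = dcols.reshape(n, h, w, c, k, k)
    dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=dcols.dtype)
    for di in range(k):
        for dj in range(k):
            dxp[:, :, di : di + h, dj : dj + w] += d6[..., di, dj].transpose(0, 3, 1, 2)
    return dxp[:, :, p : p + h, p : p + w]


class Layer:
    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def parameters(self) -> list[dict]:
        return []


class Conv2D(Layer):
    """3x3 (or k x k) convolution with 'same' zero padding, He-initialized."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, k: int = 3):
        self.c_in, self.c_out, self.k = c_in, c_out, k
        scale = np.sqrt(2.0 / (c_in * k * k))
        self.W = rng.normal(0.0, scale, size=(c_in * k * k, c_out)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cols: np.ndarray | None = None
        self._xshape: tuple[int, int, int, int] | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        if c != self.c_in:
            raise ValueError(f"expected {self.c_in} input channels, got {c}")
        cols = _im2col(x, self.k)
        self._cols, self._xshape = cols, x.shape
        y = cols @ self.W + self.b
        return y.reshape(n, h, w, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, _, h, w = grad.shape
        g2 = grad.transpose(0, 2, 3, 1).reshape(n, h * w, self.c_out)
        cols = self._cols
        self.dW = np.tensordot(cols, g2, axes=([0, 1], [0, 1])).astype(np.float32)
        self.db = g2.sum(axis=(0, 1)).astype(np.float32)
        dcols = g2 @ self.W.T
        return _col2im(dcols, self._xshape, self.k)

    def parameters(self) -> list[dict]:
        return [
            {"value": self.W, "grad": lambda: self.dW, "name": "W"},
            {"value": self.b, "grad": lambda: self.db, "name": "b"},
        ]


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(np.float32)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return np.where(self._mask, grad, 0.0)


class MaxPool2(Layer):
    """2x2 max pooling; gradient routes to the per-window argmax."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError("spatial size must be divisible by the pool size")
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        xr = xr.reshape(n, c, h // 2, w // 2, 4)
        self._arg = xr.argmax(axis=-1)
        self._inshape = x.shape
        return np.take_along_axis(xr, self._arg[..., None], axis=-1)[..., 0]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, h, w = self._inshape
        d4 = np.zeros((n, c, h // 2, w // 2, 4), dtype=grad.dtype)
        np.put_along_axis(d4, self._arg[..., None], grad[..., None], axis=-1)
        d = d4.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return d.reshape(n, c, h, w)


class Upsample2(Layer):
    """2x nearest-neighbour up-sampling; gradient sums over each 2x2 block."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, h, w = grad.shape
        return grad.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class Sigmoid(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._out = 1.0 / (1.0 + np.exp(-x))
        return self._out.astype(np.float32)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._out * (1.0 - self._out)


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def parameters(self) -> list[dict]:
        return [p for layer in self.layers for p in layer.parameters()]

    def state_arrays(self) -> list[np.ndarray]:
        return [p["value"] for p in self.parameters()]

    def get_state(self) -> list[np.ndarray]:
        return [a.copy() for a in self.state_arrays()]

    def set_state(self, state: list[np.ndarray]) -> None:
        for a, s in zip(self.state_arrays(), state, strict=True):
            a[...] = s


class Adam:
    """Adam with conventional moment defaults (beta1 0.9, beta2 0.999)."""

    def __init__(
        self,
        params: list[dict],
        lr: float = 1e-4,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p["value"]) for p in params]
        self.v = [np.zeros_like(p["value"]) for p in params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p["grad"]()
            m[...] = self.b1 * m + (1.0 - self.b1) * g
            v[...] = self.b2 * v + (1.0 - self.b2) * g * g
            update = self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
            p["value"][...] = p["value"] - update
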