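"""Layers and optimizer for the NumPy U-Net.

Tensors are NCHW arrays (float32 by default; float64 available for
gradient verification).  Each layer keeps its forward cache on the
instance, so a layer object serves one forward/backward pair at a time
(single-threaded training loop).
"""
from __future__ import annotations

from typing import List, Optional

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from ..errors import ShapeError


class Param:
    """A learnable array with gradient, trainability flag and Adam state."""

    __slots__ = ("name", "value", "grad", "trainable", "m", "v")

    def __init__(self, name: str, value: np.ndarray, trainable: bool = True,
                 dtype=np.float32):
        self.name = name
        self.value = np.asarray(value, dtype=dtype)
        self.grad = np.zeros_like(self.value)
        self.trainable = trainable
        self.m = np.zeros_like(self.value)
        self.v = np.zeros_like(self.value)


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def relu_grad(x: np.ndarray, dy: np.ndarray) -> np.ndarray:
    return dy * (x > 0.0)


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Conv2d:
    """3x3 (or kxk) same-padding convolution via im2col."""

    def __init__(self, cin: int, cout: int, name: str, rng: np.random.Generator,
                 k: int = 3, dtype=np.float32):
        if k % 2 != 1:
            raise ValueError("kernel size must be odd for same padding")
        self.cin, self.cout, self.k = cin, cout, k
        self.dtype = dtype
        scale = np.sqrt(2.0 / (cin * k * k))  # He initialization for ReLU stacks
        self.W = Param(f"{name}.W", rng.normal(0.0, scale, size=(cout, cin * k * k)),
                       dtype=dtype)
        self.b = Param(f"{name}.b", np.zeros(cout), dtype=dtype)
        self._cols: Optional[np.ndarray] = None
        self._xshape = None

    def params(self) -> List[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        if c != self.cin:
            raise ShapeError(f"{self.W.name}: expected {self.cin} channels, got {c}")
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = sliding_window_view(xp, (self.k, self.k), axis=(2, 3))  # n,c,h,w,k,k
        ckk = c * self.k * self.k
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, ckk)
        self._cols, self._xshape = cols, x.shape
        y = cols @ self.W.value.T + self.b.value  # (n*hw, cout) via BLAS
        return y.reshape(n, h, w, self.cout).transpose(0, 3, 1, 2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._xshape
        k, p = self.k, self.k // 2
        dyf = dy.transpose(0, 2, 3, 1).reshape(n * h * w, self.cout)
        cols = self._cols
        self.W.grad += dyf.T @ cols
        self.b.grad += dyf.sum(axis=0)
        # dx of a stride-1 same conv = correlation of dy with the spatially
        # flipped kernels, input/output channels swapped — one more matmul
        Wk = self.W.value.reshape(self.cout, c, k, k)
        M = Wk[:, :, ::-1, ::-1].transpose(0, 2, 3, 1).reshape(self.cout * k * k, c)
        dyp = np.pad(
            dy, ((0, 0), (0, 0), (p, p), (p, p))
        )
        win = sliding_window_view(dyp, (k, k), axis=(2, 3))
        dycols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, self.cout * k * k)
        dx = (dycols @ M).reshape(n, h, w, c).transpose(0, 3, 1, 2)
        self._cols = None
        return dx


class MaxPool2:
    """2x2 stride-2 max pooling; gradient routed to the first argmax."""

    def __init__(self):
        self._am = None
        self._shape = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ShapeError(f"max-pool needs even spatial dims, got {h}x{w}")
        xr = (
            x.reshape(n, c, h // 2, 2, w // 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, h // 2, w // 2, 4)
        )
        self._am = xr.argmax(axis=-1)
        self._shape = x.shape
        return np.take_along_axis(xr, self._am[..., None], axis=-1)[..., 0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        dxr = np.zeros((n, c, h // 2, w // 2, 4), dtype=dy.dtype)
        np.put_along_axis(dxr, self._am[..., None], dy[..., None], axis=-1)
        return (
            dxr.reshape(n, c, h // 2, w // 2, 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, h, w)
        )


class ConvTranspose2d:
    """2x2 stride-2 transposed convolution (learned x2 upsampling)."""

    def __init__(self, cin: int, cout: int, name: str, rng: np.random.Generator,
                 dtype=np.float32):
        self.cin, self.cout = cin, cout
        self.dtype = dtype
        scale = np.sqrt(2.0 / cin)
        self.W = Param(f"{name}.W", rng.normal(0.0, scale, size=(cin, cout, 2, 2)),
                       dtype=dtype)
        self.b = Param(f"{name}.b", np.zeros(cout), dtype=dtype)
        self._x = None

    def params(self) -> List[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.shape[1] != self.cin:
            raise ShapeError(f"{self.W.name}: expected {self.cin} channels, got {x.shape[1]}")
        self._x = x
        n, c, h, w = x.shape
        xf = x.transpose(0, 2, 3, 1).reshape(n * h * w, c)
        y = xf @ self.W.value.reshape(c, self.cout * 4)  # BLAS
        # (n, h, w, cout, 2, 2) -> (n, cout, h, 2, w, 2) -> (n, cout, 2h, 2w)
        y = (
            y.reshape(n, h, w, self.cout, 2, 2)
            .transpose(0, 3, 1, 4, 2, 5)
            .reshape(n, self.cout, 2 * h, 2 * w)
        )
        return y + self.b.value[None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._x
        n, c, h, w = x.shape
        dyf = (
            dy.reshape(n, self.cout, h, 2, w, 2)
            .transpose(0, 2, 4, 1, 3, 5)
            .reshape(n * h * w, self.cout * 4)
        )
        xf = x.transpose(0, 2, 3, 1).reshape(n * h * w, c)
        self.W.grad += (xf.T @ dyf).reshape(c, self.cout, 2, 2)
        self.b.grad += dy.sum(axis=(0, 2, 3))
        dx = (dyf @ self.W.value.reshape(c, self.cout * 4).T).reshape(
            n, h, w, c
        ).transpose(0, 3, 1, 2)
        self._x = None
        return dx


class Adam:
    """Adaptive-moment optimizer; skips non-trainable (frozen) parameters."""

    def __init__(self, params: List[Param], lr: float = 5e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p in self.params:
            if not p.trainable:
                continue
            p.m = self.beta1 * p.m + (1.0 - self.beta1) * p.grad
            p.v = self.beta2 * p.v + (1.0 - self.beta2) * p.grad**2
            p.value -= self.lr * (p.m / b1t) / (np.sqrt(p.v / b2t) + self.eps)
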