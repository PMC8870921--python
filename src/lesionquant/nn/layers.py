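"""Minimal 2D CNN layer kit with explicit backpropagation.

Tensors are float32 in NHWC layout (batch, rows, cols, channels): with
channels innermost, im2col patch extraction and the col2im scatter touch
contiguous memory, which is what keeps slice-wise training practical on a
single CPU core. Each layer exposes ``forward(x, train)`` and
``backward(grad)``; trainable arrays live in :class:`Param` objects so the
optimiser can walk them generically.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import as_strided

__all__ = ["Param", "Conv2d", "BatchNorm2d", "ReLU", "MaxPool2x2", "Upsample2x", "Adam"]


class Param:
    """A trainable array and its accumulated gradient."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = "") -> None:
        self.value = np.asarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)
        self.name = name


def _im2col(xp: np.ndarray, k: int, h: int, w: int) -> np.ndarray:
    """(N, H+2p, W+2p, C) -> (N*H*W, k*k*C) patch matrix."""
    n, _, _, c = xp.shape
    s0, s1, s2, s3 = xp.strides
    view = as_strided(xp, shape=(n, h, w, k, k, c),
                      strides=(s0, s1, s2, s1, s2, s3))
    return view.reshape(n * h * w, k * k * c)


class Conv2d:
    """3x3 (or 1x1) convolution with 'same' zero padding, stride 1."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator,
                 name: str = "conv", bias_init: float = 0.0) -> None:
        fan_in = c_in * kernel * kernel
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                       size=(kernel * kernel * c_in, c_out))
        self.W = Param(w, f"{name}.W")
        self.b = Param(np.full(c_out, bias_init), f"{name}.b")
        self.c_in = c_in
        self.c_out = c_out
        self.kernel = kernel
        self.pad = kernel // 2
        self._cols: np.ndarray | None = None
        self._xshape: tuple | None = None

    @property
    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, h, w, c = x.shape
        k, p = self.kernel, self.pad
        if p:
            xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
            cols = _im2col(xp, k, h, w)
        else:
            cols = x.reshape(n * h * w, c)
        out = cols @ self.W.value + self.b.value
        if train:
            # materialise the patch matrix only when gradients are needed
            self._cols = np.ascontiguousarray(cols)
            self._xshape = x.shape
        return out.reshape(n, h, w, self.c_out)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, h, w, c = self._xshape
        k, p = self.kernel, self.pad
        gmat = np.ascontiguousarray(grad).reshape(n * h * w, self.c_out)
        self.W.grad += self._cols.T @ gmat
        self.b.grad += gmat.sum(axis=0)
        self._cols = None
        if not p:
            return (gmat @ self.W.value.T).reshape(n, h, w, c)
        # input gradient as a correlation of the output gradient with the
        # spatially flipped kernel (transposed convolution), done as one gemm
        gp = np.pad(grad, ((0, 0), (p, p), (p, p), (0, 0)))
        cols_g = _im2col(gp, k, h, w)
        w_flip = self.W.value.reshape(k, k, self.c_in, self.c_out)[::-1, ::-1]
        w_flip = np.ascontiguousarray(w_flip.transpose(0, 1, 3, 2)
                                      ).reshape(k * k * self.c_out, self.c_in)
        return (cols_g @ w_flip).reshape(n, h, w, c)


class BatchNorm2d:
    """Per-channel batch normalisation with running statistics for eval mode."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5,
                 name: str = "bn") -> None:
        self.gamma = Param(np.ones(channels), f"{name}.gamma")
        self.beta = Param(np.zeros(channels), f"{name}.beta")
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    @property
    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 1, 2))
            var = x.var(axis=(0, 1, 2))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
            inv = (1.0 / np.sqrt(var + self.eps)).astype(np.float32)
            xhat = (x - mean) * inv
            self._cache = (xhat, inv)
            return self.gamma.value * xhat + self.beta.value
        inv = 1.0 / np.sqrt(self.running_var + self.eps)
        return (self.gamma.value * inv) * (x - self.running_mean) + self.beta.value

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        self._cache = None
        m = grad.shape[0] * grad.shape[1] * grad.shape[2]
        self.gamma.grad += (grad * xhat).sum(axis=(0, 1, 2))
        self.beta.grad += grad.sum(axis=(0, 1, 2))
        dxhat = grad * self.gamma.value
        s1 = dxhat.sum(axis=(0, 1, 2))
        s2 = (dxhat * xhat).sum(axis=(0, 1, 2))
        return inv * (dxhat - s1 / m - xhat * (s2 / m))


class ReLU:
    params: list[Param] = []

    def __init__(self) -> None:
        self._mask = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        out = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        out = grad * self._mask
        self._mask = None
        return out


class MaxPool2x2:
    """2x2 max pooling, stride 2; spatial dims must be even."""

    params: list[Param] = []

    def __init__(self) -> None:
        self._idx = None
        self._shape = None

    @staticmethod
    def _windows(x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        r = x.reshape(n, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 2, 4, 5)
        return r.reshape(n, h // 2, w // 2, 4, c)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        r = self._windows(x)
        idx = r.argmax(axis=3)
        out = np.take_along_axis(r, idx[:, :, :, None, :], axis=3)[:, :, :, 0, :]
        if train:
            self._idx = idx
            self._shape = x.shape
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, h, w, c = self._shape
        dr = np.zeros((n, h // 2, w // 2, 4, c), dtype=np.float32)
        np.put_along_axis(dr, self._idx[:, :, :, None, :], grad[:, :, :, None, :], axis=3)
        dr = dr.reshape(n, h // 2, w // 2, 2, 2, c).transpose(0, 1, 3, 2, 4, 5)
        self._idx = None
        return dr.reshape(n, h, w, c)


class Upsample2x:
    """Non-learned 2x nearest-neighbour up-sampling."""

    params: list[Param] = []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return x.repeat(2, axis=1).repeat(2, axis=2)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, h, w, c = grad.shape
        return grad.reshape(n, h // 2, 2, w // 2, 2, c).sum(axis=(2, 4))


class Adam:
    """Adam optimiser over a flat list of :class:`Param`."""

    def __init__(self, params: list[Param], lr: float = 0.001,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.value) for p in params]
        self._v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1c = 1.0 - self.beta1 ** self.t
        b2c = 1.0 - self.beta2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            m += (1.0 - self.beta1) * (p.grad - m)
            v += (1.0 - self.beta2) * (p.grad * p.grad - v)
            p.value -= self.lr * (m / b1c) / (np.sqrt(v / b2c) + self.eps)
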