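"""A small, self-contained neural-network layer library on numpy.

Implements exactly the pieces the species-distribution models need —
linear, ReLU, dropout, 3x3/1x1 convolution (im2col), batch normalization,
global average pooling, residual blocks, and Adam — with hand-written
backward passes.  Every backward pass is verified against finite
differences in the test suite.

Conventions
-----------
* Layers expose ``forward(x, train)`` and ``backward(dy)``; ``backward``
  accumulates parameter gradients and returns the input gradient.
* Initialization draws from a ``numpy.random.Generator`` passed at
  construction, so a model seed reproduces parameters bit-for-bit.
* Convolution weights use Kaiming (He) normal initialization; batch-norm
  scales start at 1 except where a residual branch is deliberately
  zero-initialized so each block starts as the identity around its
  shortcut.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Param:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=float)
        self.grad = np.zeros_like(self.value)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Linear(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.W = Param(rng.normal(0.0, scale, size=(n_in, n_out)))
        self.b = Param(np.zeros(n_out))
        self._x: np.ndarray | None = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=False):
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dy):
        self.W.grad += self._x.T @ dy
        self.b.grad += dy.sum(axis=0)
        return dy @ self.W.value.T


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class Dropout(Layer):
    """Inverted dropout; identity in evaluation mode."""

    def __init__(self, p: float, rng: np.random.Generator):
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.p = p
        self.rng = rng
        self._mask: np.ndarray | float = 1.0

    def forward(self, x, train=False):
        if not train or self.p == 0.0:
            self._mask = 1.0
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class Conv2d(Layer):
    """2-D convolution via im2col.  Input/output are (N, C, H, W)."""

    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int,
                 pad: int, rng: np.random.Generator):
        fan_in = c_in * kernel * kernel
        self.W = Param(rng.normal(0.0, np.sqrt(2.0 / fan_in),
                                  size=(c_out, c_in, kernel, kernel)))
        self.kernel, self.stride, self.pad = kernel, stride, pad
        self._cols: np.ndarray | None = None
        self._x_shape: tuple | None = None

    def params(self):
        return [self.W]

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        k, s, p = self.kernel, self.stride, self.pad
        if p:
            x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        hp, wp = x.shape[2], x.shape[3]
        ho = (hp - k) // s + 1
        wo = (wp - k) // s + 1
        if ho < 1 or wo < 1:
            raise ValueError(f"input {h}x{w} too small for kernel {k} stride {s}")
        win = sliding_window_view(x, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * k * k)
        self._cols = cols
        self._x_shape = (n, c, h, w, hp, wp, ho, wo)
        y = cols @ self.W.value.reshape(self.W.value.shape[0], -1).T
        return y.reshape(n, ho, wo, -1).transpose(0, 3, 1, 2)

    def backward(self, dy):
        n, c, h, w, hp, wp, ho, wo = self._x_shape
        k, s, p = self.kernel, self.stride, self.pad
        c_out = self.W.value.shape[0]
        dyc = dy.transpose(0, 2, 3, 1).reshape(n * ho * wo, c_out)
        self.W.grad += (dyc.T @ self._cols).reshape(self.W.value.shape)
        dcols = dyc @ self.W.value.reshape(c_out, -1)
        dwin = dcols.reshape(n, ho, wo, c, k, k).transpose(0, 3, 1, 2, 4, 5)
        dxp = np.zeros((n, c, hp, wp))
        for i in range(k):
            for j in range(k):
                dxp[:, :, i:i + s * ho:s, j:j + s * wo:s] += dwin[:, :, :, :, i, j]
        return dxp[:, :, p:p + h, p:p + w] if p else dxp


class BatchNorm(Layer):
    """Batch normalization over all axes but the channel axis.

    Works for both (N, C) and (N, C, H, W) inputs.  Running statistics use
    momentum 0.1 and are applied in evaluation mode.
    """

    def __init__(self, channels: int, zero_init: bool = False,
                 eps: float = 1e-5, momentum: float = 0.1):
        self.gamma = Param(np.zeros(channels) if zero_init else np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self.eps, self.momentum = eps, momentum
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def params(self):
        return [self.gamma, self.beta]

    def _axes(self, x):
        return (0,) if x.ndim == 2 else (0, 2, 3)

    def _shape(self, x, v):
        return v if x.ndim == 2 else v.reshape(1, -1, 1, 1)

    def forward(self, x, train=False):
        axes = self._axes(x)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (1 - self.momentum) * self.running_mean \
                + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var \
                + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - self._shape(x, mean)) * self._shape(x, invstd)
        self._xhat, self._invstd, self._train = xhat, invstd, train
        return self._shape(x, self.gamma.value) * xhat + self._shape(x, self.beta.value)

    def backward(self, dy):
        axes = self._axes(dy)
        xhat, invstd = self._xhat, self._invstd
        self.gamma.grad += (dy * xhat).sum(axis=axes)
        self.beta.grad += dy.sum(axis=axes)
        dxhat = dy * self._shape(dy, self.gamma.value)
        if not self._train:
            return dxhat * self._shape(dy, invstd)
        m = dy.size // dy.shape[1]
        s1 = dxhat.sum(axis=axes)
        s2 = (dxhat * xhat).sum(axis=axes)
        return (self._shape(dy, invstd) / m) * (
            m * dxhat - self._shape(dy, s1) - xhat * self._shape(dy, s2))


class GlobalAvgPool(Layer):
    """(N, C, H, W) -> (N, C) spatial mean."""

    def forward(self, x, train=False):
        self._hw = x.shape[2:]
        return x.mean(axis=(2, 3))

    def backward(self, dy):
        h, w = self._hw
        return np.broadcast_to(dy[:, :, None, None],
                               dy.shape + (h, w)).copy() / (h * w)


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


class ResidualBlock(Layer):
    """conv-bn-relu-conv-bn around a (possibly projected) shortcut.

    The second batch norm's scale is zero-initialized, so at initialization
    the block output equals ReLU(shortcut) — the residual branch starts
    silent and is learned.
    """

    def __init__(self, c_in: int, c_out: int, stride: int,
                 rng: np.random.Generator):
        self.conv1 = Conv2d(c_in, c_out, 3, stride, 1, rng)
        self.bn1 = BatchNorm(c_out)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(c_out, c_out, 3, 1, 1, rng)
        self.bn2 = BatchNorm(c_out, zero_init=True)
        if stride != 1 or c_in != c_out:
            self.shortcut: Sequential | None = Sequential(
                Conv2d(c_in, c_out, 1, stride, 0, rng), BatchNorm(c_out))
        else:
            self.shortcut = None
        self.relu_out = ReLU()

    def params(self):
        out = (self.conv1.params() + self.bn1.params() + self.conv2.params()
               + self.bn2.params())
        if self.shortcut is not None:
            out += self.shortcut.params()
        return out

    def forward(self, x, train=False):
        h = self.conv1.forward(x, train)
        h = self.bn1.forward(h, train)
        h = self.relu1.forward(h, train)
        h = self.conv2.forward(h, train)
        h = self.bn2.forward(h, train)
        s = x if self.shortcut is None else self.shortcut.forward(x, train)
        return self.relu_out.forward(h + s, train)

    def backward(self, dy):
        d = self.relu_out.backward(dy)
        ds = d if self.shortcut is None else self.shortcut.backward(d)
        dh = self.bn2.backward(d)
        dh = self.conv2.backward(dh)
        dh = self.relu1.backward(dh)
        dh = self.bn1.backward(dh)
        dh = self.conv1.backward(dh)
        return dh + ds


class Adam:
    """Adaptive-moment estimation over a parameter list."""

    def __init__(self, params: Sequence[Param], lr: float,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        if lr < 0:
            raise ValueError("learning rate must be non-negative")
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        for p, m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad**2
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def snapshot(params: Sequence[Param]) -> list[np.ndarray]:
    """Deep copy of parameter values (for best-epoch checkpoints)."""
    return [p.value.copy() for p in params]


def restore(params: Sequence[Param], values: Sequence[np.ndarray]) -> None:
    for p, v in zip(params, values):
        p.value[...] = v


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def softplus(z: np.ndarray) -> np.ndarray:
    """log(1 + e^z), numerically stable."""
    return np.logaddexp(0.0, z)
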