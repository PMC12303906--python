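"""Minimal NumPy neural-network layers with explicit forward/backward passes.

Every layer caches what its backward pass needs during ``forward`` and
releases gradients into :class:`Param` objects, which an optimizer
(:mod:`plaquenet.nn.optim`) updates in place.  Shapes follow the NCHW
convention used by the model builder.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import as_strided

__all__ = [
    "Param",
    "Layer",
    "Conv2d",
    "ConvTranspose2d",
    "BatchNorm2d",
    "ReLU",
    "MaxPool2d",
    "Linear",
    "ChannelConv1d",
    "sigmoid",
]


class Param:
    """A trainable tensor together with its accumulated gradient."""

    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = np.ascontiguousarray(data)
        self.grad = np.zeros_like(self.data)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Layer:
    """Base class; concrete layers override forward/backward."""

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, gout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _he_normal(rng: np.random.Generator, shape, fan_in: int, dtype) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(dtype)


def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    """Unfold k x k stride-1 patches of NCHW ``x`` into (N, C*k*k, H*W)."""
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    s = x.strides
    win = as_strided(x, (n, c, k, k, h, w), (s[0], s[1], s[2], s[3], s[2], s[3]))
    return win.reshape(n, c * k * k, h * w)


def _col2im(dcols: np.ndarray, shape, k: int, pad: int) -> np.ndarray:
    """Adjoint of :func:`_im2col` (scatter-add overlapping patches)."""
    n, c, h, w = shape
    d = dcols.reshape(n, c, k, k, h, w)
    dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=dcols.dtype)
    for di in range(k):
        for dj in range(k):
            dxp[:, :, di : di + h, dj : dj + w] += d[:, :, di, dj]
    if pad:
        return dxp[:, :, pad : pad + h, pad : pad + w]
    return dxp


class Conv2d(Layer):
    """Stride-1 2-D convolution with 'same' zero padding (odd kernels)."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator,
                 dtype=np.float32):
        if kernel % 2 == 0:
            raise ValueError("Conv2d requires an odd kernel size")
        self.in_ch, self.out_ch, self.k = in_ch, out_ch, kernel
        self.pad = kernel // 2
        fan_in = in_ch * kernel * kernel
        self.weight = Param(_he_normal(rng, (out_ch, fan_in), fan_in, dtype))
        self.bias = Param(np.zeros(out_ch, dtype=dtype))
        self._cols = None
        self._xshape = None

    def params(self):
        return [self.weight, self.bias]

    def forward(self, x, train=True):
        n, c, h, w = x.shape
        cols = _im2col(x, self.k, self.pad)
        y = np.matmul(self.weight.data, cols)  # (n, out, h*w)
        y += self.bias.data[None, :, None]
        if train:
            self._cols, self._xshape = cols, x.shape
        return y.reshape(n, self.out_ch, h, w)

    def backward(self, gout):
        n, _, h, w = gout.shape
        g2 = gout.reshape(n, self.out_ch, h * w)
        self.weight.grad += np.einsum("noh,nch->oc", g2, self._cols, optimize=True)
        self.bias.grad += g2.sum(axis=(0, 2))
        dcols = np.matmul(self.weight.data.T, g2)
        gin = _col2im(dcols, self._xshape, self.k, self.pad)
        self._cols = None
        return gin


class ConvTranspose2d(Layer):
    """2x2 stride-2 transposed convolution (learned upsampling)."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator, dtype=np.float32):
        self.in_ch, self.out_ch = in_ch, out_ch
        self.weight = Param(_he_normal(rng, (in_ch, out_ch, 2, 2), in_ch * 4, dtype))
        self.bias = Param(np.zeros(out_ch, dtype=dtype))
        self._x = None

    def params(self):
        return [self.weight, self.bias]

    def forward(self, x, train=True):
        n, c, h, w = x.shape
        y = np.einsum("nihw,iokl->nohkwl", x, self.weight.data, optimize=True)
        y = y.reshape(n, self.out_ch, 2 * h, 2 * w)
        y += self.bias.data[None, :, None, None]
        if train:
            self._x = x
        return y

    def backward(self, gout):
        n, o, h2, w2 = gout.shape
        h, w = h2 // 2, w2 // 2
        g6 = gout.reshape(n, o, h, 2, w, 2)
        self.weight.grad += np.einsum("nihw,nohkwl->iokl", self._x, g6, optimize=True)
        self.bias.grad += gout.sum(axis=(0, 2, 3))
        gin = np.einsum("nohkwl,iokl->nihw", g6, self.weight.data, optimize=True)
        self._x = None
        return gin


class BatchNorm2d(Layer):
    """Per-channel batch normalization with running statistics."""

    def __init__(self, ch: int, dtype=np.float32, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(ch, dtype=dtype))
        self.beta = Param(np.zeros(ch, dtype=dtype))
        self.running_mean = np.zeros(ch, dtype=dtype)
        self.running_var = np.ones(ch, dtype=dtype)
        self.momentum, self.eps = momentum, eps
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train=True):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mean
            self.running_var = (1 - m) * self.running_var + m * var
        else:
            mean, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * invstd[None, :, None, None]
        if train:
            self._cache = (xhat, invstd)
        return self.gamma.data[None, :, None, None] * xhat + self.beta.data[None, :, None, None]

    def backward(self, gout):
        xhat, invstd = self._cache
        self._cache = None
        m = gout.shape[0] * gout.shape[2] * gout.shape[3]
        self.gamma.grad += (gout * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += gout.sum(axis=(0, 2, 3))
        g = gout * self.gamma.data[None, :, None, None]
        gsum = g.sum(axis=(0, 2, 3)).reshape(1, -1, 1, 1)
        gxhat = (g * xhat).sum(axis=(0, 2, 3)).reshape(1, -1, 1, 1)
        gin = invstd[None, :, None, None] * (g - gsum / m - xhat * gxhat / m)
        return gin


class ReLU(Layer):
    def __init__(self):
        self._mask = None

    def forward(self, x, train=True):
        y = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return y

    def backward(self, gout):
        gin = gout * self._mask
        self._mask = None
        return gin


class MaxPool2d(Layer):
    """2x2 stride-2 max pooling; backward routes to the argmax element."""

    def __init__(self):
        self._idx = None
        self._shape = None

    def forward(self, x, train=True):
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        flat = xr.reshape(n, c, h // 2, w // 2, 4)
        idx = flat.argmax(axis=-1)
        y = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
        if train:
            self._idx, self._shape = idx, x.shape
        return y

    def backward(self, gout):
        n, c, h, w = self._shape
        flat = np.zeros((n, c, h // 2, w // 2, 4), dtype=gout.dtype)
        np.put_along_axis(flat, self._idx[..., None], gout[..., None], axis=-1)
        gin = (flat.reshape(n, c, h // 2, w // 2, 2, 2)
                   .transpose(0, 1, 2, 4, 3, 5)
                   .reshape(n, c, h, w))
        self._idx = None
        return gin


class Linear(Layer):
    def __init__(self, in_f: int, out_f: int, rng: np.random.Generator, dtype=np.float32):
        self.weight = Param(_he_normal(rng, (out_f, in_f), in_f, dtype))
        self.bias = Param(np.zeros(out_f, dtype=dtype))
        self._x = None

    def params(self):
        return [self.weight, self.bias]

    def forward(self, x, train=True):
        if train:
            self._x = x
        return x @ self.weight.data.T + self.bias.data

    def backward(self, gout):
        self.weight.grad += gout.T @ self._x
        self.bias.grad += gout.sum(axis=0)
        gin = gout @ self.weight.data
        self._x = None
        return gin


class ChannelConv1d(Layer):
    """1-D convolution along the channel axis of a (N, C) descriptor.

    Single input/output channel, odd kernel, zero padding that preserves C —
    the local cross-channel interaction used by efficient channel attention.
    """

    def __init__(self, kernel: int, rng: np.random.Generator, dtype=np.float32):
        if kernel % 2 == 0 or kernel < 1:
            raise ValueError("ChannelConv1d requires an odd positive kernel size")
        self.k = kernel
        self.pad = kernel // 2
        self.weight = Param(_he_normal(rng, (kernel,), kernel, dtype))
        self.bias = Param(np.zeros(1, dtype=dtype))
        self._zp = None

    def params(self):
        return [self.weight, self.bias]

    def forward(self, z, train=True):
        n, c = z.shape
        zp = np.pad(z, ((0, 0), (self.pad, self.pad)))
        s = zp.strides
        win = as_strided(zp, (n, c, self.k), (s[0], s[1], s[1]))
        y = win @ self.weight.data + self.bias.data[0]
        if train:
            self._zp = zp
        return y

    def backward(self, gout):
        n, c = gout.shape
        zp = self._zp
        self._zp = None
        s = zp.strides
        win = as_strided(zp, (n, c, self.k), (s[0], s[1], s[1]))
        self.weight.grad += np.einsum("nc,nck->k", gout, win, optimize=True)
        self.bias.grad += gout.sum(keepdims=True).reshape(1)
        dzp = np.zeros_like(zp)
        for j in range(self.k):
            dzp[:, j : j + c] += self.weight.data[j] * gout
        return dzp[:, self.pad : self.pad + c]
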