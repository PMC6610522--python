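"""Minimal CNN layer zoo on NumPy arrays (NCHW), with exact backprop.

Every layer exposes ``forward(x, training)`` and ``backward(dy)``; learnable
tensors are :class:`Param` objects collected via ``params()``.  Convolutions
are stride-1, zero "same"-padded, odd-kernel, with optional dilation, and use
cross-correlation orientation (no kernel flip) as is conventional in deep
learning.  The backward pass of the convolution is itself expressed as a
convolution with the spatially flipped, channel-transposed kernel, which is
exact for symmetric same padding.
"""
from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from ..errors import ParameterError

__all__ = ["Param", "Conv2d", "BatchNorm2d", "ReLU", "MaxPool2d", "Upsample2d"]


class Param:
    """A learnable tensor and its gradient accumulator."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)
        self.name = name


def _dilated_cols(x: np.ndarray, k: int, dilation: int) -> np.ndarray:
    """im2col view for same-padded dilated correlation: (N,C,H,W,k,k)."""
    pad = dilation * (k - 1) // 2
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    ext = dilation * (k - 1) + 1
    win = sliding_window_view(xp, (ext, ext), axis=(2, 3))
    return win[..., ::dilation, ::dilation]


def _corr2d(x: np.ndarray, w: np.ndarray, dilation: int) -> np.ndarray:
    cols = _dilated_cols(x, w.shape[-1], dilation)
    return np.einsum("nchwij,ocij->nohw", cols, w, optimize=True)


class Conv2d:
    """Stride-1 same-padded 2-D convolution with dilation; He-normal init."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, dilation: int = 1,
                 rng: np.random.Generator | None = None, name: str = "conv"):
        if kernel % 2 == 0:
            raise ParameterError("even filter sides are not supported (same padding)")
        if dilation < 1:
            raise ParameterError("dilation factor must be >= 1")
        rng = rng if rng is not None else np.random.default_rng(0)
        fan_in = in_ch * kernel * kernel
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_ch, in_ch, kernel, kernel))
        self.weight = Param(w, f"{name}.weight")
        self.bias = Param(np.zeros(out_ch), f"{name}.bias")
        self.in_ch, self.out_ch, self.kernel, self.dilation = in_ch, out_ch, kernel, dilation
        self._x = None

    def params(self):
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        if x.shape[1] != self.in_ch:
            raise ParameterError(
                f"{self.weight.name}: expected {self.in_ch} input channels, got {x.shape[1]}"
            )
        self._x = x
        return _corr2d(x, self.weight.value, self.dilation) + self.bias.value[:, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._x
        cols = _dilated_cols(x, self.kernel, self.dilation)
        self.weight.grad += np.einsum("nchwij,nohw->ocij", cols, dy, optimize=True)
        self.bias.grad += dy.sum(axis=(0, 2, 3))
        w_t = self.weight.value[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
        return _corr2d(dy, w_t, self.dilation)


class BatchNorm2d:
    """Per-channel batch normalisation with running statistics."""

    def __init__(self, ch: int, momentum: float = 0.9, eps: float = 1e-5, name: str = "bn"):
        self.gamma = Param(np.ones(ch), f"{name}.gamma")
        self.beta = Param(np.zeros(ch), f"{name}.beta")
        self.running_mean = np.zeros(ch)
        self.running_var = np.ones(ch)
        self.momentum, self.eps, self.ch = momentum, eps, ch
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        if training:
            mu = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mu
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mu, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps)
        xhat = (x - mu[:, None, None]) / std[:, None, None]
        self._cache = (xhat, std, training)
        return self.gamma.value[:, None, None] * xhat + self.beta.value[:, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, std, training = self._cache
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dy.sum(axis=(0, 2, 3))
        g = self.gamma.value[:, None, None]
        if not training:
            return dy * g / std[:, None, None]
        m = dy.shape[0] * dy.shape[2] * dy.shape[3]
        dxhat = dy * g
        mean_d = dxhat.mean(axis=(0, 2, 3))[:, None, None]
        mean_dx = (dxhat * xhat).mean(axis=(0, 2, 3))[:, None, None]
        return (dxhat - mean_d - xhat * mean_dx) / std[:, None, None]


class ReLU:
    def params(self):
        return []

    def forward(self, x, training: bool = True):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class MaxPool2d:
    """2 x 2, stride-2 max pooling; spatial dims must be even."""

    def params(self):
        return []

    def forward(self, x, training: bool = True):
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ParameterError("MaxPool2d needs even spatial dimensions")
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        flat = xr.reshape(n, c, h // 2, w // 2, 4)
        self._idx = flat.argmax(axis=-1)
        self._shape = x.shape
        return np.take_along_axis(flat, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dy):
        n, c, h, w = self._shape
        flat = np.zeros((n, c, h // 2, w // 2, 4))
        np.put_along_axis(flat, self._idx[..., None], dy[..., None], axis=-1)
        return (
            flat.reshape(n, c, h // 2, w // 2, 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, h, w)
        )


class Upsample2d:
    """Nearest-neighbour 2x up-sampling (parameter-free)."""

    def params(self):
        return []

    def forward(self, x, training: bool = True):
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dy):
        n, c, h, w = dy.shape
        return dy.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))
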