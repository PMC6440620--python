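"""Minimal NumPy layer library with manual backpropagation.

Feature maps are arrays of shape (N, C, H, W) in float64 (tests) or
float32 (training). Each layer implements ``forward(x, training)`` and
``backward(grad)``; parameters are :class:`Param` objects carrying their
gradient, and each carries a ``category`` tag so networks can be audited
per parameter family (conv / shortcut / se / norm / classifier).

Convolutions use "same" zero padding: the output spatial size is
``ceil(in / stride)``, with total padding ``max((out-1)*stride + k - in, 0)``
split as evenly as possible (extra pixel at the bottom/right).
"""

from __future__ import annotations

import math
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "Param",
    "Layer",
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "Linear",
    "GlobalAvgPool",
    "MaxPool2d",
    "SEGate",
    "Sequential",
    "he_normal",
]


def he_normal(rng: np.random.Generator, shape: Tuple[int, ...], fan_in: int) -> np.ndarray:
    """He-style initialization: N(0, sqrt(2 / fan_in))."""
    return rng.normal(0.0, math.sqrt(2.0 / fan_in), size=shape)


class Param:
    __slots__ = ("name", "value", "grad", "category")

    def __init__(self, name: str, value: np.ndarray, category: str) -> None:
        self.name = name
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)
        self.category = category

    @property
    def size(self) -> int:
        return int(self.value.size)

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"Param({self.name}, shape={self.value.shape}, category={self.category})"


class Layer:
    def params(self) -> List[Param]:
        return []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def __call__(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        return self.forward(x, training=training)


def _same_pad(in_size: int, k: int, stride: int) -> Tuple[int, int, int]:
    out = -(-in_size // stride)  # ceil division
    total = max((out - 1) * stride + k - in_size, 0)
    before = total // 2
    return out, before, total - before


class Conv2d(Layer):
    """2-D convolution (cross-correlation), no bias, "same" zero padding.

    Implemented as a sum over kernel offsets with einsum contractions,
    which is efficient for the small (1x3, 3x1, 3x3, 1x1) kernels used
    throughout.
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: Tuple[int, int],
        stride: int = 1,
        rng: Optional[np.random.Generator] = None,
        category: str = "conv",
        name: str = "conv",
    ) -> None:
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = tuple(kernel_size)
        self.stride = stride
        kh, kw = self.kernel_size
        fan_in = in_channels * kh * kw
        rng = rng or np.random.default_rng()
        self.weight = Param(
            f"{name}.weight",
            he_normal(rng, (out_channels, in_channels, kh, kw), fan_in),
            category,
        )
        self._cache = None

    def params(self) -> List[Param]:
        return [self.weight]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        if c != self.in_channels:
            raise ValueError(f"expected {self.in_channels} input channels, got {c}")
        kh, kw = self.kernel_size
        s = self.stride
        ho, pt, pb = _same_pad(h, kh, s)
        wo, pl, pr = _same_pad(w, kw, s)
        xp = np.pad(x, ((0, 0), (0, 0), (pt, pb), (pl, pr)))
        out = np.zeros((n, self.out_channels, ho, wo), dtype=x.dtype)
        wgt = self.weight.value
        for dy in range(kh):
            for dx in range(kw):
                patch = xp[:, :, dy : dy + ho * s : s, dx : dx + wo * s : s]
                out += np.einsum("ncij,kc->nkij", patch, wgt[:, :, dy, dx], optimize=True)
        self._cache = (xp, x.shape, (ho, wo, pt, pl))
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xp, x_shape, (ho, wo, pt, pl) = self._cache
        kh, kw = self.kernel_size
        s = self.stride
        wgt = self.weight.value
        dxp = np.zeros_like(xp)
        for dy in range(kh):
            for dx in range(kw):
                patch = xp[:, :, dy : dy + ho * s : s, dx : dx + wo * s : s]
                self.weight.grad[:, :, dy, dx] += np.einsum(
                    "nkij,ncij->kc", grad, patch, optimize=True
                )
                dxp[:, :, dy : dy + ho * s : s, dx : dx + wo * s : s] += np.einsum(
                    "nkij,kc->ncij", grad, wgt[:, :, dy, dx], optimize=True
                )
        _, _, h, w = x_shape
        return dxp[:, :, pt : pt + h, pl : pl + w]


class BatchNorm2d(Layer):
    """Per-channel batch normalization with learnable scale and shift."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1,
                 name: str = "bn") -> None:
        self.channels = channels
        self.eps = eps
        self.momentum = momentum
        self.gamma = Param(f"{name}.gamma", np.ones(channels), "norm")
        self.beta = Param(f"{name}.beta", np.zeros(channels), "norm")
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self._cache = None

    def params(self) -> List[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv_std[None, :, None, None]
        out = self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]
        self._cache = (xhat, inv_std, training)
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv_std, training = self._cache
        self.gamma.grad += np.einsum("ncij,ncij->c", grad, xhat, optimize=True)
        self.beta.grad += grad.sum(axis=(0, 2, 3))
        g = self.gamma.value[None, :, None, None] * inv_std[None, :, None, None]
        if not training:
            return grad * g
        m = grad.shape[0] * grad.shape[2] * grad.shape[3]
        mean_dy = grad.mean(axis=(0, 2, 3))[None, :, None, None]
        mean_dy_xhat = (grad * xhat).mean(axis=(0, 2, 3))[None, :, None, None]
        return g * (grad - mean_dy - xhat * mean_dy_xhat)


class ReLU(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class Linear(Layer):
    def __init__(self, in_features: int, out_features: int, bias: bool = True,
                 rng: Optional[np.random.Generator] = None,
                 category: str = "classifier", name: str = "fc") -> None:
        rng = rng or np.random.default_rng()
        self.weight = Param(
            f"{name}.weight", he_normal(rng, (out_features, in_features), in_features), category
        )
        self.bias = Param(f"{name}.bias", np.zeros(out_features), category) if bias else None

    def params(self) -> List[Param]:
        return [self.weight] + ([self.bias] if self.bias is not None else [])

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._x = x
        out = x @ self.weight.value.T
        if self.bias is not None:
            out = out + self.bias.value
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.weight.grad += grad.T @ self._x
        if self.bias is not None:
            self.bias.grad += grad.sum(axis=0)
        return grad @ self.weight.value


class GlobalAvgPool(Layer):
    """(N, C, H, W) -> (N, C) spatial mean."""

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        return np.broadcast_to(grad[:, :, None, None], self._shape) / (h * w)


class MaxPool2d(Layer):
    """Max pooling with "same" padding (padded with -inf)."""

    def __init__(self, kernel_size: int = 3, stride: int = 2) -> None:
        self.kernel_size = kernel_size
        self.stride = stride

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        k, s = self.kernel_size, self.stride
        ho, pt, pb = _same_pad(h, k, s)
        wo, pl, pr = _same_pad(w, k, s)
        xp = np.pad(x, ((0, 0), (0, 0), (pt, pb), (pl, pr)), constant_values=-np.inf)
        out = np.full((n, c, ho, wo), -np.inf, dtype=x.dtype)
        argmax = np.zeros((n, c, ho, wo), dtype=np.int64)
        for dy in range(k):
            for dx in range(k):
                patch = xp[:, :, dy : dy + ho * s : s, dx : dx + wo * s : s]
                better = patch > out
                out = np.where(better, patch, out)
                argmax = np.where(better, dy * k + dx, argmax)
        self._cache = (xp.shape, argmax, (ho, wo, pt, pl), x.shape)
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xp_shape, argmax, (ho, wo, pt, pl), x_shape = self._cache
        k, s = self.kernel_size, self.stride
        dxp = np.zeros(xp_shape, dtype=grad.dtype)
        for dy in range(k):
            for dx in range(k):
                mask = argmax == dy * k + dx
                dxp[:, :, dy : dy + ho * s : s, dx : dx + wo * s : s] += grad * mask
        _, _, h, w = x_shape
        return dxp[:, :, pt : pt + h, pl : pl + w]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class SEGate(Layer):
    """Channel attention: squeeze (global average pool), two bias-free
    fully connected layers with ReLU then sigmoid, and channel-wise
    rescaling of the input map.

    The bottleneck width is ``max(1, floor(C / r))`` with reduction ratio
    ``r`` (default 16).
    """

    def __init__(self, channels: int, r: int = 16,
                 rng: Optional[np.random.Generator] = None, name: str = "se") -> None:
        self.channels = channels
        self.r = r
        self.hidden = max(1, channels // r)
        rng = rng or np.random.default_rng()
        self.w1 = Param(f"{name}.w1", he_normal(rng, (self.hidden, channels), channels), "se")
        self.w2 = Param(f"{name}.w2", he_normal(rng, (channels, self.hidden), self.hidden), "se")

    def params(self) -> List[Param]:
        return [self.w1, self.w2]

    def gates(self, s: np.ndarray) -> np.ndarray:
        """Excitation path alone: (N, C) channel statistics -> (N, C) gates."""
        h = np.maximum(s @ self.w1.value.T, 0.0)
        return _sigmoid(h @ self.w2.value.T)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        n, c, hh, ww = x.shape
        s = x.mean(axis=(2, 3))  # squeeze
        pre1 = s @ self.w1.value.T
        h = np.maximum(pre1, 0.0)
        g = _sigmoid(h @ self.w2.value.T)
        self._cache = (x, s, pre1, h, g)
        return x * g[:, :, None, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x, s, pre1, h, g = self._cache
        n, c, hh, ww = x.shape
        dg = np.einsum("ncij,ncij->nc", grad, x, optimize=True)
        dx_direct = grad * g[:, :, None, None]
        dpre2 = dg * g * (1.0 - g)
        self.w2.grad += dpre2.T @ h
        dh = dpre2 @ self.w2.value
        dpre1 = dh * (pre1 > 0)
        self.w1.grad += dpre1.T @ s
        ds = dpre1 @ self.w1.value
        dx_squeeze = np.broadcast_to(ds[:, :, None, None], x.shape) / (hh * ww)
        return dx_direct + dx_squeeze


class Sequential(Layer):
    def __init__(self, *layers: Layer) -> None:
        self.layers = list(layers)

    def params(self) -> List[Param]:
        out: List[Param] = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad
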