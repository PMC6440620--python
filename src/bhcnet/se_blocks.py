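"""Squeeze-and-excitation residual modules.

This module has two faces:

* Pure array functions (:func:`squeeze`, :func:`excitation`,
  :func:`recalibrate`, :func:`residual_combine`) expressing the SE block
  pipeline on explicit arrays — global average pooling of a feature map
  to per-channel statistics, a two-layer bias-free gating network with
  ReLU/sigmoid nonlinearities, channel-wise rescaling, and the residual
  sum with the module input.

* :func:`build_module`, which assembles one of three trainable residual
  module variants around that pipeline:

  - ``basic``      : conv3x3 - conv3x3 - SE
  - ``bottleneck`` : conv1x1(C) - conv3x3(C) - conv1x1(4C) - SE
  - ``small``      : conv1x3 - conv3x1 - conv1x3 - conv3x1 - SE

  Every convolution is preceded by batch normalization and ReLU
  (pre-activation ordering); convolutions carry no bias. Downsampling
  stride is applied at the first convolution; when the shortcut shape
  changes, a 1x1 stride-matched projection convolution with
  normalization replaces the identity.

:func:`reference_forward` is an explicit-loop re-implementation of the
whole forward map (eval mode) kept deliberately free of vectorized
shortcuts; it exists solely as a test oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Literal, Optional, Sequence, Tuple

import numpy as np

from .nn import BatchNorm2d, Conv2d, Layer, Param, ReLU, SEGate, he_normal

__all__ = [
    "ModuleKind",
    "ModuleSpec",
    "ExcitationWeights",
    "squeeze",
    "excitation",
    "recalibrate",
    "residual_combine",
    "build_module",
    "SEResNetModule",
    "reference_forward",
    "module_conv_layout",
]

ModuleKind = Literal["basic", "bottleneck", "small"]

KINDS: Tuple[str, ...] = ("basic", "bottleneck", "small")
BOTTLENECK_EXPANSION = 4


def module_conv_layout(kind: str, in_channels: int, width: int) -> List[Tuple[int, int, int, int]]:
    """Convolution shapes (in, kh, kw, out) for one module, in order."""
    c = width
    if kind == "basic":
        return [(in_channels, 3, 3, c), (c, 3, 3, c)]
    if kind == "bottleneck":
        return [(in_channels, 1, 1, c), (c, 3, 3, c), (c, 1, 1, BOTTLENECK_EXPANSION * c)]
    if kind == "small":
        return [(in_channels, 1, 3, c), (c, 3, 1, c), (c, 1, 3, c), (c, 3, 1, c)]
    raise ValueError(f"unknown module kind {kind!r}; expected one of {KINDS}")


@dataclass(frozen=True)
class ModuleSpec:
    """Declarative description of one SE residual module."""

    kind: str
    in_channels: int
    width: int
    stride: int = 1
    r: int = 16
    shortcut: str = "auto"  # auto | identity | projection

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown module kind {self.kind!r}; expected one of {KINDS}")
        if self.in_channels < 1 or self.width < 1:
            raise ValueError("channel counts must be >= 1")
        if self.stride not in (1, 2):
            raise ValueError(f"stride must be 1 or 2, got {self.stride}")
        if self.r < 1:
            raise ValueError("reduction ratio must be >= 1")
        if self.shortcut not in ("auto", "identity", "projection"):
            raise ValueError(f"invalid shortcut policy {self.shortcut!r}")
        if self.shortcut == "identity" and self.needs_projection:
            raise ValueError(
                "identity shortcut is incompatible with a shape change "
                f"(in={self.in_channels}, out={self.out_channels}, stride={self.stride})"
            )

    @property
    def out_channels(self) -> int:
        return BOTTLENECK_EXPANSION * self.width if self.kind == "bottleneck" else self.width

    @property
    def needs_projection(self) -> bool:
        return self.in_channels != self.out_channels or self.stride == 2

    @property
    def use_projection(self) -> bool:
        if self.shortcut == "projection":
            return True
        if self.shortcut == "identity":
            return False
        return self.needs_projection

    def conv_layout(self) -> List[Tuple[int, int, int, int]]:
        return module_conv_layout(self.kind, self.in_channels, self.width)


# ---------------------------------------------------------------------------
# Functional SE-block pipeline on explicit arrays.
# ---------------------------------------------------------------------------


def squeeze(O: np.ndarray) -> np.ndarray:
    """Spatial mean per channel: (..., C, H, W) -> (..., C)."""
    O = np.asarray(O, dtype=float)
    if O.ndim < 3:
        raise ValueError("feature map must have at least (C, H, W) axes")
    if O.shape[-1] == 0 or O.shape[-2] == 0:
        raise ValueError("feature map has empty spatial extent")
    if not np.all(np.isfinite(O)):
        raise ValueError("feature map contains non-finite entries")
    return O.mean(axis=(-2, -1))


@dataclass(frozen=True)
class ExcitationWeights:
    """Weights of the two bias-free gating layers.

    ``w1`` has shape (C_hidden, C) and ``w2`` shape (C, C_hidden) where
    C_hidden = max(1, floor(C / r)).
    """

    w1: np.ndarray
    w2: np.ndarray
    r: int = 16

    def __post_init__(self) -> None:
        w1 = np.asarray(self.w1, dtype=float)
        w2 = np.asarray(self.w2, dtype=float)
        object.__setattr__(self, "w1", w1)
        object.__setattr__(self, "w2", w2)
        if w1.ndim != 2 or w2.ndim != 2:
            raise ValueError("w1 and w2 must be matrices")
        hidden, c = w1.shape
        if w2.shape != (c, hidden):
            raise ValueError(f"inconsistent shapes: w1 {w1.shape}, w2 {w2.shape}")
        if hidden < 1:
            raise ValueError("bottleneck width must be >= 1")

    @property
    def channels(self) -> int:
        return self.w1.shape[1]

    @property
    def hidden(self) -> int:
        return self.w1.shape[0]

    @classmethod
    def random(cls, channels: int, r: int = 16,
               rng: Optional[np.random.Generator] = None) -> "ExcitationWeights":
        rng = rng or np.random.default_rng()
        hidden = max(1, channels // r)
        return cls(
            w1=he_normal(rng, (hidden, channels), channels),
            w2=he_normal(rng, (channels, hidden), hidden),
            r=r,
        )


def excitation(S: np.ndarray, w: ExcitationWeights) -> np.ndarray:
    """Gates sigma(W2 . relu(W1 . S)); every component strictly in (0, 1)."""
    S = np.asarray(S, dtype=float)
    if S.shape[-1] != w.channels:
        raise ValueError(f"expected {w.channels} channels, got {S.shape[-1]}")
    h = np.maximum(S @ w.w1.T, 0.0)
    z = h @ w.w2.T
    with np.errstate(over="ignore"):
        g = np.where(z >= 0, 1.0 / (1.0 + np.exp(-z)), np.exp(z) / (1.0 + np.exp(z)))
    # keep the open-interval contract under float64 saturation
    return np.clip(g, np.nextafter(0.0, 1.0), np.nextafter(1.0, 0.0))


def recalibrate(O: np.ndarray, gates: np.ndarray) -> np.ndarray:
    """Channel-wise rescaling: o_c(i, j) * gate_c."""
    O = np.asarray(O, dtype=float)
    gates = np.asarray(gates, dtype=float)
    if gates.shape[-1] != O.shape[-3]:
        raise ValueError(f"gate length {gates.shape[-1]} != channel count {O.shape[-3]}")
    return O * gates[..., :, None, None]


def residual_combine(X0: np.ndarray, O_tilde: np.ndarray) -> np.ndarray:
    """Elementwise residual sum; shapes must already agree."""
    X0 = np.asarray(X0, dtype=float)
    O_tilde = np.asarray(O_tilde, dtype=float)
    if X0.shape != O_tilde.shape:
        raise ValueError(
            f"identity shortcut requires equal shapes, got {X0.shape} vs {O_tilde.shape}; "
            "pass the input through the projection path first"
        )
    return X0 + O_tilde


# ---------------------------------------------------------------------------
# Trainable module.
# ---------------------------------------------------------------------------


class SEResNetModule(Layer):
    """One residual module: pre-activation conv branch, SE gate, shortcut.

    ``forward`` computes shortcut(x) + SE(branch(x)).
    """

    def __init__(self, spec: ModuleSpec, rng: Optional[np.random.Generator] = None) -> None:
        rng = rng or np.random.default_rng()
        self.spec = spec
        self.branch: List[Layer] = []
        for i, (cin, kh, kw, cout) in enumerate(spec.conv_layout()):
            self.branch.append(BatchNorm2d(cin, name=f"{spec.kind}.bn{i}"))
            self.branch.append(ReLU())
            self.branch.append(Conv2d(
                cin, cout, (kh, kw), stride=spec.stride if i == 0 else 1,
                rng=rng, category="conv", name=f"{spec.kind}.conv{i}",
            ))
        self.se = SEGate(spec.out_channels, r=spec.r, rng=rng, name=f"{spec.kind}.se")
        if spec.use_projection:
            self.proj_conv: Optional[Conv2d] = Conv2d(
                spec.in_channels, spec.out_channels, (1, 1), stride=spec.stride,
                rng=rng, category="shortcut", name=f"{spec.kind}.proj",
            )
            self.proj_bn: Optional[BatchNorm2d] = BatchNorm2d(
                spec.out_channels, name=f"{spec.kind}.proj_bn"
            )
            # audit the projection BN alongside the shortcut conv
            for p in self.proj_bn.params():
                p.category = "shortcut"
        else:
            self.proj_conv = None
            self.proj_bn = None

    def params(self) -> List[Param]:
        out: List[Param] = []
        for layer in self.branch:
            out.extend(layer.params())
        out.extend(self.se.params())
        if self.proj_conv is not None:
            out.extend(self.proj_conv.params())
            out.extend(self.proj_bn.params())
        return out

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        o = x
        for layer in self.branch:
            o = layer.forward(o, training=training)
        o_tilde = self.se.forward(o, training=training)
        if self.proj_conv is not None:
            sc = self.proj_conv.forward(x, training=training)
            sc = self.proj_bn.forward(sc, training=training)
        else:
            if x.shape != o_tilde.shape:
                raise ValueError(
                    f"identity shortcut shape mismatch: {x.shape} vs {o_tilde.shape}"
                )
            sc = x
        return sc + o_tilde

    def backward(self, grad: np.ndarray) -> np.ndarray:
        g = self.se.backward(grad)
        for layer in reversed(self.branch):
            g = layer.backward(g)
        if self.proj_conv is not None:
            gp = self.proj_bn.backward(grad)
            gp = self.proj_conv.backward(gp)
            return g + gp
        return g + grad


def build_module(spec: ModuleSpec, rng: Optional[np.random.Generator] = None) -> SEResNetModule:
    """Construct a trainable module from its spec (seeded via ``rng``)."""
    return SEResNetModule(spec, rng=rng)


# ---------------------------------------------------------------------------
# Explicit-loop oracle (eval mode). Intentionally naive: scalar loops only.
# ---------------------------------------------------------------------------


def _loop_conv(x: np.ndarray, w: np.ndarray, stride: int) -> np.ndarray:
    cout, cin, kh, kw = w.shape
    _, h, wdt = x.shape
    ho = -(-h // stride)
    wo = -(-wdt // stride)
    pt = max((ho - 1) * stride + kh - h, 0) // 2
    pl = max((wo - 1) * stride + kw - wdt, 0) // 2
    out = np.zeros((cout, ho, wo))
    for k in range(cout):
        for i in range(ho):
            for j in range(wo):
                acc = 0.0
                for c in range(cin):
                    for dy in range(kh):
                        for dx in range(kw):
                            yy = i * stride + dy - pt
                            xx = j * stride + dx - pl
                            if 0 <= yy < h and 0 <= xx < wdt:
                                acc += w[k, c, dy, dx] * x[c, yy, xx]
                out[k, i, j] = acc
    return out


def _loop_bn_eval(x: np.ndarray, bn: BatchNorm2d) -> np.ndarray:
    out = np.zeros_like(x)
    for c in range(x.shape[0]):
        scale = bn.gamma.value[c] / math.sqrt(bn.running_var[c] + bn.eps)
        for i in range(x.shape[1]):
            for j in range(x.shape[2]):
                out[c, i, j] = scale * (x[c, i, j] - bn.running_mean[c]) + bn.beta.value[c]
    return out


def reference_forward(module: SEResNetModule, X0: np.ndarray) -> np.ndarray:
    """From-scratch evaluation of a built module on one image (C, H, W).

    Replays normalization, rectification, convolution, squeeze,
    excitation, recalibration and the residual sum with explicit Python
    loops, using the module's weights in eval mode. Only intended for
    tiny inputs.
    """
    x = np.asarray(X0, dtype=float)
    if x.ndim != 3:
        raise ValueError("oracle operates on a single (C, H, W) image")
    o = x
    layers = module.branch
    for layer in layers:
        if isinstance(layer, BatchNorm2d):
            o = _loop_bn_eval(o, layer)
        elif isinstance(layer, ReLU):
            o = np.array([[[max(v, 0.0) for v in row] for row in ch] for ch in o])
        elif isinstance(layer, Conv2d):
            o = _loop_conv(o, layer.weight.value, layer.stride)
        else:  # pragma: no cover - defensive
            raise TypeError(f"unexpected layer {layer!r}")
    # SE pipeline with loops
    c, h, w = o.shape
    s = np.zeros(c)
    for ci in range(c):
        acc = 0.0
        for i in range(h):
            for j in range(w):
                acc += o[ci, i, j]
        s[ci] = acc / (h * w)
    hid = module.se.w1.value.shape[0]
    hvec = np.zeros(hid)
    for a in range(hid):
        acc = 0.0
        for ci in range(c):
            acc += module.se.w1.value[a, ci] * s[ci]
        hvec[a] = max(acc, 0.0)
    gates = np.zeros(c)
    for ci in range(c):
        acc = 0.0
        for a in range(hid):
            acc += module.se.w2.value[ci, a] * hvec[a]
        gates[ci] = 1.0 / (1.0 + math.exp(-acc))
    o_tilde = np.zeros_like(o)
    for ci in range(c):
        for i in range(h):
            for j in range(w):
                o_tilde[ci, i, j] = gates[ci] * o[ci, i, j]
    # shortcut
    if module.proj_conv is not None:
        sc = _loop_conv(x, module.proj_conv.weight.value, module.proj_conv.stride)
        sc = _loop_bn_eval(sc, module.proj_bn)
    else:
        sc = x
    out = np.zeros_like(o_tilde)
    for ci in range(out.shape[0]):
        for i in range(out.shape[1]):
            for j in range(out.shape[2]):
                out[ci, i, j] = sc[ci, i, j] + o_tilde[ci, i, j]
    return out
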