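"""Analytic parameter accounting for convolution layers and module variants.

The closed forms for the convolution-weight total of one module at width C
(steady state, input channels equal to the module's natural input width):

* basic      : 2 * (C*3*3*C)                  = 18 C^2
* bottleneck : 4C*1*1*C + C*3*3*C + C*1*1*4C  = 17 C^2
* small      : 2 * (C*1*3*C) + 2 * (C*3*1*C)  = 12 C^2

``audit_network`` itemizes a built network's trainable parameters by
category and cross-checks the module convolution subtotal against the
analytic sum over the architecture's module list.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

from .se_blocks import BOTTLENECK_EXPANSION, KINDS, module_conv_layout

__all__ = [
    "ConvShape",
    "conv_param_count",
    "module_conv_params",
    "reduction_percent",
    "audit_network",
    "AuditReport",
]


@dataclass(frozen=True)
class ConvShape:
    """One convolution layer: C input channels, H x W kernel, K filters."""

    in_channels: int
    kernel_height: int
    kernel_width: int
    out_channels: int

    def __post_init__(self) -> None:
        for v in (self.in_channels, self.kernel_height, self.kernel_width, self.out_channels):
            if v < 1:
                raise ValueError(f"all ConvShape fields must be >= 1, got {self}")


def conv_param_count(s: ConvShape) -> int:
    """Weight count of one bias-free convolution: C * H * W * K."""
    return s.in_channels * s.kernel_height * s.kernel_width * s.out_channels


def module_conv_params(kind: str, width: int, in_channels: Optional[int] = None) -> int:
    """Convolution-weight total for one module of the given kind and width.

    With the default (steady-state) input channels this equals 18 C^2,
    17 C^2 or 12 C^2 for basic / bottleneck / small respectively. Pass
    ``in_channels`` explicitly for width-transition modules.
    """
    if kind not in KINDS:
        raise ValueError(f"unknown module kind {kind!r}; expected one of {KINDS}")
    if width < 1:
        raise ValueError("width must be >= 1")
    if in_channels is None:
        in_channels = BOTTLENECK_EXPANSION * width if kind == "bottleneck" else width
    return sum(
        conv_param_count(ConvShape(cin, kh, kw, cout))
        for cin, kh, kw, cout in module_conv_layout(kind, in_channels, width)
    )


def reduction_percent(kind_from: str, kind_to: str, width: int = 64) -> float:
    """Percent parameter reduction going from one module kind to another,
    at equal width, rounded to one decimal. Independent of the width."""
    p_from = module_conv_params(kind_from, width)
    p_to = module_conv_params(kind_to, width)
    return round(100.0 * (1.0 - p_to / p_from), 1)


@dataclass
class AuditReport:
    """Itemized trainable-parameter census of a built network."""

    by_category: Dict[str, int]
    per_layer: List[Tuple[str, Tuple[int, ...], int, str]]  # (name, shape, count, category)
    module_conv_expected: int

    @property
    def module_conv_subtotal(self) -> int:
        return self.by_category.get("conv", 0)

    @property
    def total(self) -> int:
        return sum(self.by_category.values())

    def consistent(self) -> bool:
        return self.module_conv_subtotal == self.module_conv_expected

    def to_rows(self) -> List[Dict[str, object]]:
        return [
            {"name": n, "shape": "x".join(map(str, s)), "count": c, "category": cat}
            for n, s, c, cat in self.per_layer
        ]


class AuditError(RuntimeError):
    pass


def audit_network(model) -> AuditReport:
    """Audit a network built by :mod:`bhcnet.architectures`.

    Sums trainable parameters per category and verifies that the
    module-convolution subtotal (category ``"conv"``, excluding the stem
    and shortcut projections) equals the analytic per-module sums implied
    by the architecture spec. A mismatch raises :class:`AuditError`.
    """
    by_category: Dict[str, int] = {}
    per_layer: List[Tuple[str, Tuple[int, ...], int, str]] = []
    for p in model.params():
        by_category[p.category] = by_category.get(p.category, 0) + p.size
        per_layer.append((p.name, tuple(p.value.shape), p.size, p.category))
    expected = 0
    for mspec in model.module_specs():
        expected += module_conv_params(mspec.kind, mspec.width, in_channels=mspec.in_channels)
    report = AuditReport(by_category=by_category, per_layer=per_layer,
                         module_conv_expected=expected)
    if not report.consistent():
        raise AuditError(
            f"module conv subtotal {report.module_conv_subtotal} != analytic {expected}"
        )
    return report
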