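"""Declarative network specs and builders.

Two families:

* ``se_resnet-{18,26,34,50,66}`` — four-stage residual networks for
  32x32 inputs (3x3 stride-1 stem, no initial max-pool), stage widths
  64/128/256/512, module counts (2,2,2,2) for 18/26/34 and (3,4,6,3)
  for 50/66, module kinds basic / bottleneck / small / bottleneck /
  small respectively.

* ``bhcnet-N`` — one plain stem convolution, three blocks of N small SE
  residual modules at widths 16/32/64 (stride 2 entering blocks 2 and
  3), global average pooling and a single fully connected softmax head.
  For large inputs (>= 96 px) the stem uses stride 2 plus a stride-2
  max-pool so activation maps stay tractable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .nn import (
    BatchNorm2d,
    Conv2d,
    GlobalAvgPool,
    Layer,
    Linear,
    MaxPool2d,
    Param,
    ReLU,
)
from .se_blocks import ModuleSpec, SEResNetModule

__all__ = [
    "StageSpec",
    "ArchitectureSpec",
    "se_resnet_spec",
    "bhcnet_spec",
    "build_network",
    "Network",
    "REGISTRY",
    "spec_from_name",
]


@dataclass(frozen=True)
class StageSpec:
    kind: str
    width: int
    count: int
    stride: int = 1  # entry stride of the first module in the stage

    def __post_init__(self) -> None:
        if self.width < 1 or self.count < 1:
            raise ValueError("stage width and count must be >= 1")
        if self.stride not in (1, 2):
            raise ValueError("stage entry stride must be 1 or 2")


@dataclass(frozen=True)
class ArchitectureSpec:
    name: str
    stem_width: int
    stages: Tuple[StageSpec, ...]
    num_classes: int
    stem_kernel: Tuple[int, int] = (3, 3)
    stem_stride: int = 1
    stem_pool: bool = False
    r: int = 16

    def __post_init__(self) -> None:
        if self.num_classes < 2:
            raise ValueError("num_classes must be >= 2")
        if not self.stages:
            raise ValueError("at least one stage is required")
        object.__setattr__(self, "stages", tuple(self.stages))

    def module_specs(self) -> List[ModuleSpec]:
        """Flattened per-module specs with resolved input channels."""
        specs: List[ModuleSpec] = []
        in_ch = self.stem_width
        for stage in self.stages:
            for i in range(stage.count):
                m = ModuleSpec(
                    kind=stage.kind,
                    in_channels=in_ch,
                    width=stage.width,
                    stride=stage.stride if i == 0 else 1,
                    r=self.r,
                )
                specs.append(m)
                in_ch = m.out_channels
        return specs

    def to_dict(self) -> dict:
        d = asdict(self)
        d["stages"] = [asdict(s) for s in self.stages]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ArchitectureSpec":
        d = dict(d)
        d["stages"] = tuple(StageSpec(**s) for s in d["stages"])
        d["stem_kernel"] = tuple(d.get("stem_kernel", (3, 3)))
        return cls(**d)


_SE_RESNET_KINDS = {18: "basic", 26: "bottleneck", 34: "small", 50: "bottleneck", 66: "small"}
_SE_RESNET_COUNTS = {18: (2, 2, 2, 2), 26: (2, 2, 2, 2), 34: (2, 2, 2, 2),
                     50: (3, 4, 6, 3), 66: (3, 4, 6, 3)}
_SE_RESNET_WIDTHS = (64, 128, 256, 512)


def se_resnet_spec(variant: int, num_classes: int = 10) -> ArchitectureSpec:
    """Spec for the 32x32-input residual family (variants 18/26/34/50/66)."""
    if variant not in _SE_RESNET_KINDS:
        raise ValueError(f"unknown variant {variant}; expected one of {sorted(_SE_RESNET_KINDS)}")
    kind = _SE_RESNET_KINDS[variant]
    counts = _SE_RESNET_COUNTS[variant]
    stages = tuple(
        StageSpec(kind=kind, width=w, count=c, stride=1 if i == 0 else 2)
        for i, (w, c) in enumerate(zip(_SE_RESNET_WIDTHS, counts))
    )
    return ArchitectureSpec(
        name=f"se_resnet-{variant}",
        stem_width=64,
        stages=stages,
        num_classes=num_classes,
    )


def bhcnet_spec(
    N: int,
    num_classes: int = 2,
    input_size: int = 32,
    widths: Sequence[int] = (16, 32, 64),
) -> ArchitectureSpec:
    """Spec for the small-module network with N modules per block."""
    if N < 1:
        raise ValueError(f"N must be >= 1, got {N}")
    if len(widths) != 3:
        raise ValueError("exactly three block widths are required")
    big = input_size >= 96
    stages = tuple(
        StageSpec(kind="small", width=w, count=N, stride=1 if i == 0 else 2)
        for i, w in enumerate(widths)
    )
    return ArchitectureSpec(
        name=f"bhcnet-{N}",
        stem_width=widths[0],
        stages=stages,
        num_classes=num_classes,
        stem_stride=2 if big else 1,
        stem_pool=big,
    )


REGISTRY = {
    **{f"se_resnet-{v}": (lambda v=v, **kw: se_resnet_spec(v, **kw)) for v in _SE_RESNET_KINDS},
    "bhcnet-3": lambda **kw: bhcnet_spec(3, **kw),
    "bhcnet-6": lambda **kw: bhcnet_spec(6, **kw),
}


def spec_from_name(name: str, **kwargs) -> ArchitectureSpec:
    if name in REGISTRY:
        return REGISTRY[name](**kwargs)
    if name.startswith("bhcnet-"):
        return bhcnet_spec(int(name.split("-", 1)[1]), **kwargs)
    raise ValueError(f"unknown architecture {name!r}; known: {sorted(REGISTRY)}")


class Network(Layer):
    """A built, trainable network: stem, residual modules, pooled softmax head."""

    def __init__(self, spec: ArchitectureSpec, seed: int = 0) -> None:
        rng = np.random.default_rng(seed)
        self.spec = spec
        self._module_specs = spec.module_specs()
        self.layers: List[Layer] = []
        stem = Conv2d(3, spec.stem_width, spec.stem_kernel, stride=spec.stem_stride,
                      rng=rng, category="stem", name="stem")
        self.layers.append(stem)
        if spec.stem_pool:
            self.layers.append(MaxPool2d(kernel_size=3, stride=2))
        for i, mspec in enumerate(self._module_specs):
            self.layers.append(SEResNetModule(mspec, rng=rng))
        out_ch = self._module_specs[-1].out_channels
        self.layers.append(BatchNorm2d(out_ch, name="final_bn"))
        self.layers.append(ReLU())
        self.layers.append(GlobalAvgPool())
        self.layers.append(Linear(out_ch, spec.num_classes, rng=rng,
                                  category="classifier", name="fc"))

    def module_specs(self) -> List[ModuleSpec]:
        return list(self._module_specs)

    def params(self) -> List[Param]:
        out: List[Param] = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def num_params(self) -> int:
        return sum(p.size for p in self.params())

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x  # logits (N, num_classes)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def predict_proba(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Class probabilities for a batch of images (N, 3, H, W)."""
        outs = []
        for i in range(0, x.shape[0], batch_size):
            logits = self.forward(x[i : i + batch_size], training=False)
            outs.append(softmax(logits))
        return np.concatenate(outs, axis=0)

    def state_dict(self) -> Dict[str, np.ndarray]:
        state = {p.name + f"#{i}": p.value for i, p in enumerate(self.params())}
        for i, layer in enumerate(self._batchnorms()):
            state[f"bn_running_mean#{i}"] = layer.running_mean
            state[f"bn_running_var#{i}"] = layer.running_var
        return state

    def load_state_dict(self, state: Dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.params()):
            p.value[...] = state[p.name + f"#{i}"]
        for i, layer in enumerate(self._batchnorms()):
            layer.running_mean = np.asarray(state[f"bn_running_mean#{i}"])
            layer.running_var = np.asarray(state[f"bn_running_var#{i}"])

    def save(self, path) -> None:
        np.savez(path, **self.state_dict())

    def load(self, path) -> None:
        with np.load(path) as data:
            self.load_state_dict({k: data[k] for k in data.files})

    def _batchnorms(self) -> List[BatchNorm2d]:
        out: List[BatchNorm2d] = []

        def walk(layer: Layer) -> None:
            if isinstance(layer, BatchNorm2d):
                out.append(layer)
            elif isinstance(layer, SEResNetModule):
                for sub in layer.branch:
                    walk(sub)
                if layer.proj_bn is not None:
                    out.append(layer.proj_bn)

        for layer in self.layers:
            walk(layer)
        return out


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def build_network(spec: ArchitectureSpec, seed: int = 0) -> Network:
    """Instantiate a trainable network from a spec, deterministically."""
    return Network(spec, seed=seed)
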