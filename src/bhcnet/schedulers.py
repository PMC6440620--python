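"""Closed-form per-epoch learning-rate schedules.

Four families are provided:

* :class:`ErfSchedule` — a sigmoid-shaped schedule built on the Gaussian
  error function, parameterized by integer shape parameters ``alpha < 0``
  and ``beta > 0`` that control how long training dwells at ``lr_max``
  and ``lr_min`` respectively.
* :class:`StepSchedule` — piecewise-constant decay, either with explicit
  changepoints or derived from a single ratio ``R`` via
  :func:`step_r_breakpoints`.
* :class:`CosineSchedule` — half-cosine decay from ``lr_max`` to ``lr_min``.
* :class:`ExponentialSchedule` — geometric decay ``lr0 * lambda**e``.

All schedules are per-epoch: epochs are 1-based and the rate for epoch
``e`` is constant throughout that epoch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, List, Sequence, Tuple

from scipy import special

__all__ = [
    "erf_value",
    "erf_rate",
    "step_r_breakpoints",
    "step_rate",
    "cosine_rate",
    "exponential_rate",
    "tabulate_schedule",
    "ErfScheduleParams",
    "StepScheduleSpec",
    "CosineScheduleParams",
    "ExponentialScheduleParams",
    "ErfSchedule",
    "StepSchedule",
    "CosineSchedule",
    "ExponentialSchedule",
    "make_scheduler",
]


def erf_value(x: float) -> float:
    """Gaussian error function ``(2/sqrt(pi)) * int_0^x exp(-t^2) dt``.

    Thin validated wrapper over :func:`scipy.special.erf`; odd, strictly
    increasing, with open range (-1, 1).
    """
    x = float(x)
    if not math.isfinite(x):
        raise ValueError(f"erf_value requires a finite argument, got {x!r}")
    return float(special.erf(x))


@dataclass(frozen=True)
class ErfScheduleParams:
    """Parameters of the erf-shaped schedule.

    ``alpha`` must be a negative integer and ``beta`` a positive integer;
    ``lr_min`` must be strictly positive so the late-training rate never
    collapses to zero.
    """

    lr_max: float
    lr_min: float
    alpha: int
    beta: int
    total_epochs: int

    def __post_init__(self) -> None:
        if not (0 < self.lr_min < self.lr_max):
            raise ValueError(
                f"require 0 < lr_min < lr_max, got lr_min={self.lr_min}, lr_max={self.lr_max}"
            )
        if not (self.alpha < 0 < self.beta):
            raise ValueError(f"require alpha < 0 < beta, got alpha={self.alpha}, beta={self.beta}")
        if int(self.alpha) != self.alpha or int(self.beta) != self.beta:
            raise ValueError("alpha and beta must be integers")
        if self.total_epochs < 1:
            raise ValueError(f"total_epochs must be >= 1, got {self.total_epochs}")


def erf_rate(e: int, p: ErfScheduleParams) -> float:
    """Learning rate for 1-based epoch ``e`` under the erf schedule.

    rate(e) = lr_min + (lr_max - lr_min)/2 * (1 - erf(e*(beta-alpha)/E + alpha))

    The value lies strictly inside (lr_min, lr_max) and is non-increasing
    in ``e``.
    """
    _check_epoch(e, p.total_epochs)
    x = e * (p.beta - p.alpha) / p.total_epochs + p.alpha
    return p.lr_min + (p.lr_max - p.lr_min) / 2.0 * (1.0 - erf_value(x))


def step_r_breakpoints(R: float, E_total: int) -> Tuple[int, int]:
    """Derive the two decay epochs (E1, E2) from a single ratio R in (0, 1).

    E2 = floor(E_total / (1 + R)) and E1 = floor(R * E2), so that
    E1 / E2 ~= R and E1 + E2 ~= E_total.
    """
    if not (0.0 < R < 1.0):
        raise ValueError(f"R must lie in (0, 1), got {R}")
    if E_total < 2:
        raise ValueError(f"E_total must be >= 2, got {E_total}")
    E2 = math.floor(E_total / (1.0 + R))
    E1 = math.floor(R * E2)
    return E1, E2


@dataclass(frozen=True)
class StepScheduleSpec:
    """Piecewise-constant schedule: ``initial_rate`` until the first
    changepoint; the rate attached to a changepoint epoch applies from the
    following epoch onward ("after the 60th epoch" = from epoch 61).
    """

    initial_rate: float
    changepoints: Tuple[Tuple[int, float], ...] = ()

    def __post_init__(self) -> None:
        if self.initial_rate <= 0:
            raise ValueError("initial_rate must be positive")
        object.__setattr__(self, "changepoints", tuple(
            (int(ep), float(r)) for ep, r in self.changepoints
        ))
        prev_epoch = 0
        prev_rate = self.initial_rate
        for ep, r in self.changepoints:
            if ep <= prev_epoch:
                raise ValueError("changepoint epochs must be strictly increasing and positive")
            if r >= prev_rate:
                raise ValueError("changepoint rates must be strictly decreasing")
            prev_epoch, prev_rate = ep, r

    @classmethod
    def from_r(
        cls,
        R: float,
        E_total: int,
        initial_rate: float = 0.1,
        divisor: float = 10.0,
    ) -> "StepScheduleSpec":
        """Two-drop schedule with breakpoints from :func:`step_r_breakpoints`,
        dividing the rate by ``divisor`` at each drop."""
        E1, E2 = step_r_breakpoints(R, E_total)
        return cls(
            initial_rate=initial_rate,
            changepoints=((E1, initial_rate / divisor), (E2, initial_rate / divisor**2)),
        )


def step_rate(e: int, s: StepScheduleSpec) -> float:
    """Rate at 1-based epoch ``e`` under a step schedule."""
    if e < 1:
        raise ValueError(f"epoch must be >= 1, got {e}")
    rate = s.initial_rate
    for ep, r in s.changepoints:
        if e > ep:
            rate = r
        else:
            break
    return rate


@dataclass(frozen=True)
class CosineScheduleParams:
    lr_max: float
    lr_min: float = 0.0
    total_epochs: int = 300
    # The printed amplitude is (lr_max + lr_min)/2; the conventional
    # cosine-annealing amplitude is (lr_max - lr_min)/2. They coincide for
    # lr_min = 0, the default configuration.
    conventional_amplitude: bool = False

    def __post_init__(self) -> None:
        if self.lr_min < 0:
            raise ValueError("lr_min must be >= 0 for the cosine schedule")
        if self.lr_max <= self.lr_min:
            raise ValueError("require lr_max > lr_min")
        if self.total_epochs < 1:
            raise ValueError("total_epochs must be >= 1")


def cosine_rate(e: int, p: CosineScheduleParams) -> float:
    """Half-cosine decay evaluated at 1-based epoch ``e``."""
    _check_epoch(e, p.total_epochs)
    amp = (p.lr_max - p.lr_min) if p.conventional_amplitude else (p.lr_max + p.lr_min)
    return p.lr_min + amp / 2.0 * (1.0 + math.cos(math.pi * e / p.total_epochs))


@dataclass(frozen=True)
class ExponentialScheduleParams:
    lr0: float
    decay: float  # discount factor lambda in [0, 1]

    def __post_init__(self) -> None:
        if self.lr0 <= 0:
            raise ValueError("lr0 must be positive")
        if not (0.0 <= self.decay <= 1.0):
            raise ValueError(f"decay factor must lie in [0, 1], got {self.decay}")


def exponential_rate(e: int, p: ExponentialScheduleParams) -> float:
    if e < 1:
        raise ValueError(f"epoch must be >= 1, got {e}")
    return p.lr0 * p.decay**e


def _check_epoch(e: int, total: int) -> None:
    if not (1 <= e <= total):
        raise ValueError(f"epoch must satisfy 1 <= e <= {total}, got {e}")


# ---------------------------------------------------------------------------
# Scheduler objects: a uniform rate(e) interface for the training loop / CLI.
# ---------------------------------------------------------------------------


class Scheduler:
    """Base class: callable mapping a 1-based epoch to a learning rate."""

    total_epochs: int

    def rate(self, e: int) -> float:  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, e: int) -> float:
        return self.rate(e)


@dataclass
class ErfSchedule(Scheduler):
    params: ErfScheduleParams

    @property
    def total_epochs(self) -> int:
        return self.params.total_epochs

    def rate(self, e: int) -> float:
        return erf_rate(e, self.params)


@dataclass
class StepSchedule(Scheduler):
    spec: StepScheduleSpec
    total_epochs: int = 300

    def rate(self, e: int) -> float:
        return step_rate(e, self.spec)


@dataclass
class CosineSchedule(Scheduler):
    params: CosineScheduleParams

    @property
    def total_epochs(self) -> int:
        return self.params.total_epochs

    def rate(self, e: int) -> float:
        return cosine_rate(e, self.params)


@dataclass
class ExponentialSchedule(Scheduler):
    params: ExponentialScheduleParams
    total_epochs: int = 300

    def rate(self, e: int) -> float:
        return exponential_rate(e, self.params)


def tabulate_schedule(scheduler: Callable[[int], float], E: int) -> List[Tuple[int, float]]:
    """Per-epoch rate table [(1, rate), ..., (E, rate)] for plotting / CSV."""
    if E < 1:
        raise ValueError(f"E must be >= 1, got {E}")
    return [(e, float(scheduler(e))) for e in range(1, E + 1)]


def make_scheduler(config: dict) -> Scheduler:
    """Build a scheduler from a flat config mapping.

    Recognized keys: ``type`` in {erf, step, step_r, cosine, exponential};
    ``lr_max``, ``lr_min``, ``alpha``, ``beta``, ``epochs``, ``R``,
    ``lambda`` (or ``decay``), ``initial_rate``, ``changepoints``.
    """
    kind = str(config.get("type", "erf")).lower().replace("-", "_")
    epochs = int(config.get("epochs", 300))
    if kind == "erf":
        return ErfSchedule(ErfScheduleParams(
            lr_max=float(config.get("lr_max", 0.1)),
            lr_min=float(config.get("lr_min", 0.0001)),
            alpha=int(config.get("alpha", -3)),
            beta=int(config.get("beta", 3)),
            total_epochs=epochs,
        ))
    if kind == "step_r":
        spec = StepScheduleSpec.from_r(
            R=float(config["R"]),
            E_total=epochs,
            initial_rate=float(config.get("initial_rate", 0.1)),
        )
        return StepSchedule(spec, total_epochs=epochs)
    if kind == "step":
        spec = StepScheduleSpec(
            initial_rate=float(config.get("initial_rate", 0.1)),
            changepoints=tuple(
                (int(ep), float(r)) for ep, r in config.get("changepoints", [])
            ),
        )
        return StepSchedule(spec, total_epochs=epochs)
    if kind == "cosine":
        return CosineSchedule(CosineScheduleParams(
            lr_max=float(config.get("lr_max", 0.1)),
            lr_min=float(config.get("lr_min", 0.0)),
            total_epochs=epochs,
            conventional_amplitude=bool(config.get("conventional_amplitude", False)),
        ))
    if kind == "exponential":
        return ExponentialSchedule(
            ExponentialScheduleParams(
                lr0=float(config.get("lr0", config.get("initial_rate", 0.1))),
                decay=float(config.get("lambda", config.get("decay", 0.98))),
            ),
            total_epochs=epochs,
        )
    raise ValueError(f"unknown scheduler type {kind!r}")
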