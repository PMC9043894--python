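"""Exponential decay models for soil protein-residue time courses.

Two nested models describe the residue concentration ``Y`` (ng per g dry
soil) as a function of elapsed time ``t`` (days):

* **first-order** — ``Y(t) = a * exp(-b * t)``: single-exponential decay
  to zero, the conventional degradation-kinetics model.
* **plateau** — ``Y(t) = y0 + a * exp(-b * t)``: decay to a non-zero
  asymptote ``y0``, interpreted as a residual fraction that is not
  degraded on the time scale of the experiment.

Setting ``y0 = 0`` reduces the plateau model to the first-order model, so
the two are nested.  The half-life functionals below are closed forms of
the decay rate ``b``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "LN2",
    "FirstOrderParams",
    "PlateauParams",
    "eval_first_order",
    "eval_plateau",
    "dt50_first_order",
    "half_life_degradable_fraction",
]

LN2 = math.log(2.0)


def _check_finite(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value!r}")
    return value


@dataclass(frozen=True)
class FirstOrderParams:
    """Parameters of the first-order model ``Y(t) = a * exp(-b * t)``.

    Attributes
    ----------
    a : float
        Initial concentration (ng per g dry soil); strictly positive.
    b : float
        Decay rate (1/day); strictly positive.
    """

    a: float
    b: float

    def __post_init__(self) -> None:
        a = _check_finite("a", self.a)
        b = _check_finite("b", self.b)
        if a <= 0:
            raise ValueError(f"amplitude a must be > 0, got {a}")
        if b <= 0:
            raise ValueError(f"decay rate b must be > 0, got {b}")


@dataclass(frozen=True)
class PlateauParams:
    """Parameters of the plateau model ``Y(t) = y0 + a * exp(-b * t)``.

    Attributes
    ----------
    y0 : float
        Non-degradable residual plateau (ng per g dry soil); non-negative.
    a : float
        Degradable amplitude (ng per g dry soil); strictly positive.
    b : float
        Decay rate (1/day); strictly positive.
    """

    y0: float
    a: float
    b: float

    def __post_init__(self) -> None:
        y0 = _check_finite("y0", self.y0)
        a = _check_finite("a", self.a)
        b = _check_finite("b", self.b)
        if y0 < 0:
            raise ValueError(f"plateau y0 must be >= 0, got {y0}")
        if a <= 0:
            raise ValueError(f"amplitude a must be > 0, got {a}")
        if b <= 0:
            raise ValueError(f"decay rate b must be > 0, got {b}")


def _check_times(t):
    arr = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("time values must be finite")
    if np.any(arr < 0):
        raise ValueError("time values must be non-negative")
    return arr


def eval_first_order(p: FirstOrderParams, t):
    """Evaluate ``a * exp(-b * t)`` at time(s) ``t`` (days).

    Accepts a scalar or an array of non-negative times; returns a float for
    scalar input and an ndarray otherwise.
    """
    arr = _check_times(t)
    out = p.a * np.exp(-p.b * arr)
    return float(out) if arr.ndim == 0 else out


def eval_plateau(p: PlateauParams, t):
    """Evaluate ``y0 + a * exp(-b * t)`` at time(s) ``t`` (days)."""
    arr = _check_times(t)
    out = p.y0 + p.a * np.exp(-p.b * arr)
    return float(out) if arr.ndim == 0 else out


def dt50_first_order(b: float) -> float:
    """Half-life ``ln(2) / b`` (days) of the first-order model.

    This is the time at which ``a * exp(-b * t)`` reaches half of its
    ``t = 0`` value.  Raises ``ValueError`` for ``b <= 0`` or non-finite b.
    """
    b = _check_finite("b", b)
    if b <= 0:
        raise ValueError(f"decay rate b must be > 0, got {b}")
    return LN2 / b


def half_life_degradable_fraction(p: PlateauParams) -> float:
    """Half-life ``ln(2) / b`` (days) of the degradable component.

    For the plateau model the quantity ``Y(t) - y0 = a * exp(-b * t)``
    halves every ``ln(2) / b`` days; the plateau itself never halves, so
    this is the only well-defined half-life of that model.
    """
    return dt50_first_order(p.b)
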