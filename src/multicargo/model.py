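"""Shared domain types: shape factors, domains, the cargo model, units.

A cargo is a body of half-width ``L`` carrying ``N`` legs.  Legs bind at
positions drawn within the cargo footprint (the shape factor), unbind from
their bound positions, and the cargo centre is the arithmetic mean of the
bound leg positions.  A third event type displaces all bound legs by
``k3_step`` at rate ``k3_rate``, encoding deterministic substrate motion
such as the co-moving frame of a growing microtubule tip.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Optional

import numpy as np

from .profiles import RateProfile, make_rate_profile

__all__ = [
    "ShapeFactor",
    "shape_factor",
    "Domain",
    "CargoModel",
    "DimensionlessConvention",
]


@dataclasses.dataclass(frozen=True)
class ShapeFactor:
    """Uniform density of allowed binding positions around the cargo centre.

    1D: 1/(2L) on [x_a - L, x_a + L].  2D: 1/(pi L^2) on the disk |x - x_a| <= L.
    """

    half_width: float
    dim: int = 1

    def density(self, x, x_a):
        L = self.half_width
        if self.dim == 1:
            x = np.asarray(x, dtype=float)
            inside = np.abs(x - x_a) <= L
            out = np.where(inside, 1.0 / (2.0 * L), 0.0)
        else:
            x = np.asarray(x, dtype=float)
            x_a = np.asarray(x_a, dtype=float)
            r = np.linalg.norm(x - x_a, axis=-1)
            out = np.where(r <= L, 1.0 / (math.pi * L * L), 0.0)
        if out.ndim == 0:
            return float(out)
        return out


def shape_factor(L: float, dim: int = 1) -> ShapeFactor:
    if L <= 0:
        raise ValueError("cargo half-width L must be positive")
    if dim not in (1, 2):
        raise ValueError("dim must be 1 or 2")
    return ShapeFactor(half_width=float(L), dim=dim)


@dataclasses.dataclass(frozen=True)
class Domain:
    """Simulation domain.  ``mode``: periodic | open | edged.

    In 2D the same bounds apply independently along each axis (square box).
    ``edged`` marks a finite substrate whose edges enter through the rate
    profile supports; positions themselves are not clipped.
    """

    lo: float = -10.0
    hi: float = 10.0
    mode: str = "periodic"

    def __post_init__(self):
        if self.hi <= self.lo:
            raise ValueError("domain requires hi > lo")
        if self.mode not in ("periodic", "open", "edged"):
            raise ValueError(f"unknown domain mode {self.mode!r}")

    @property
    def width(self) -> float:
        return self.hi - self.lo

    @property
    def periodic(self) -> bool:
        return self.mode == "periodic"

    def wrap(self, x):
        """Map (possibly unwrapped) coordinates into the domain if periodic."""
        if not self.periodic:
            return x
        return self.lo + np.mod(np.asarray(x, dtype=float) - self.lo, self.width)


@dataclasses.dataclass
class CargoModel:
    """Full model definition for one cargo species on one substrate."""

    N: int
    kappa1: RateProfile
    kappa2: RateProfile
    L: float = 1.0
    shape: Optional[ShapeFactor] = None
    k3_rate: float = 0.0
    k3_step: float = 0.05
    dim: int = 1
    domain: Domain = dataclasses.field(default_factory=Domain)

    def __post_init__(self):
        self.kappa1 = make_rate_profile(self.kappa1)
        self.kappa2 = make_rate_profile(self.kappa2)
        if self.N < 1:
            raise ValueError("cargo must have at least one leg")
        if self.L <= 0:
            raise ValueError("cargo half-width L must be positive")
        if self.k3_rate < 0:
            raise ValueError("k3_rate must be nonnegative")
        if not math.isfinite(self.k3_rate * self.k3_step):
            raise ValueError("drift velocity k3_rate * k3_step must be finite")
        if self.dim not in (1, 2):
            raise ValueError("dim must be 1 or 2")
        if self.shape is None:
            self.shape = shape_factor(self.L, self.dim)

    @property
    def drift_velocity(self) -> float:
        """Deterministic drift k3_rate * k3_step (L/t_c or physical units)."""
        return self.k3_rate * self.k3_step

    def kappa1_at(self, x):
        return self.kappa1(self.domain.wrap(x))

    def kappa2_at(self, x):
        return self.kappa2(self.domain.wrap(x))


@dataclasses.dataclass(frozen=True)
class DimensionlessConvention:
    """Unit system: lengths in units of L, times in units of t_c = 1/kappa2.

    The default (1, 1) is the dimensionless convention used throughout;
    the tip-tracking application works in nanometres and seconds instead
    (``length_unit`` = L in nm, ``time_unit`` = 1/max kappa2 in s).
    """

    length_unit: float = 1.0
    time_unit: float = 1.0

    def __post_init__(self):
        if self.length_unit <= 0 or self.time_unit <= 0:
            raise ValueError("units must be positive")

    def _factor(self, quantity: str) -> float:
        Lu, tu = self.length_unit, self.time_unit
        return {
            "length": Lu,
            "time": tu,
            "rate": 1.0 / tu,
            "velocity": Lu / tu,
            "diffusivity": Lu * Lu / tu,
        }[quantity]

    def to_physical(self, value, quantity: str):
        return value * self._factor(quantity)

    def to_dimensionless(self, value, quantity: str):
        return value / self._factor(quantity)
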