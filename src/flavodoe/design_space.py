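"""Process factors and the coded/actual transform.

Every design-of-experiments stage in this package works in *coded* units,
where a factor's center maps to 0 and its low/high levels map to -1/+1.
A :class:`Factor` stores the affine map (center, half-range) between the
coded scale and actual process units (mL solvent per g material, degrees
Celsius, percent ethanol, ...); :class:`DesignSpace` is an ordered
collection of factors with vectorized encode/decode.

The solid-to-liquid ratio is represented by its denominator -- mL of
solvent per g of dry material -- so "1:20" is the value 20.0 and the
factor is continuous.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Factor",
    "DesignSpace",
    "default_bbd_space",
    "default_pbd_space",
]


@dataclass(frozen=True)
class Factor:
    """One continuous process variable with its coded-unit mapping.

    Parameters
    ----------
    name : str
        Unique label, e.g. ``"ratio"``.
    units : str
        Actual units, e.g. ``"mL/g"``.
    center : float
        Actual value that codes to 0.
    half_range : float
        Actual distance from center to the +1 level; must be positive.
    """

    name: str
    units: str
    center: float
    half_range: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.center) and math.isfinite(self.half_range)):
            raise ValueError(f"factor {self.name!r}: center/half_range must be finite")
        if self.half_range <= 0:
            raise ValueError(f"factor {self.name!r}: half_range must be > 0")

    @property
    def low(self) -> float:
        return self.center - self.half_range

    @property
    def high(self) -> float:
        return self.center + self.half_range

    def encode(self, actual):
        """Map actual units to coded units: (actual - center) / half_range."""
        actual = np.asarray(actual, dtype=float)
        if not np.all(np.isfinite(actual)):
            raise ValueError(f"factor {self.name!r}: cannot encode non-finite value")
        out = (actual - self.center) / self.half_range
        return float(out) if out.ndim == 0 else out

    def decode(self, coded):
        """Inverse of :meth:`encode`: center + half_range * coded."""
        coded = np.asarray(coded, dtype=float)
        out = self.center + self.half_range * coded
        return float(out) if out.ndim == 0 else out

    @classmethod
    def from_bounds(cls, name: str, units: str, low: float, high: float) -> "Factor":
        """Build a factor from its -1/+1 actual levels instead of center/half-range."""
        if not high > low:
            raise ValueError(f"factor {name!r}: need high > low")
        return cls(name, units, center=(low + high) / 2.0, half_range=(high - low) / 2.0)


@dataclass(frozen=True)
class DesignSpace:
    """Ordered set of factors defining the coded box [-1, 1]^k."""

    factors: tuple[Factor, ...]

    def __init__(self, factors) -> None:
        object.__setattr__(self, "factors", tuple(factors))
        names = [f.name for f in self.factors]
        if len(names) != len(set(names)):
            raise ValueError("factor names must be unique")
        if not names:
            raise ValueError("a design space needs at least one factor")

    @property
    def k(self) -> int:
        return len(self.factors)

    @property
    def names(self) -> list[str]:
        return [f.name for f in self.factors]

    def __getitem__(self, name: str) -> Factor:
        for f in self.factors:
            if f.name == name:
                return f
        raise KeyError(f"unknown factor {name!r}")

    def encode(self, actual) -> np.ndarray:
        """Encode rows of actual values (n x k or length-k) to coded units."""
        actual = np.atleast_2d(np.asarray(actual, dtype=float))
        if actual.shape[-1] != self.k:
            raise ValueError(f"expected {self.k} columns, got {actual.shape[-1]}")
        cols = [f.encode(actual[:, j]) for j, f in enumerate(self.factors)]
        return np.column_stack(cols)

    def decode(self, coded) -> np.ndarray:
        """Decode rows of coded values to actual units."""
        coded = np.atleast_2d(np.asarray(coded, dtype=float))
        if coded.shape[-1] != self.k:
            raise ValueError(f"expected {self.k} columns, got {coded.shape[-1]}")
        cols = [f.decode(coded[:, j]) for j, f in enumerate(self.factors)]
        return np.column_stack(cols)

    def to_dict(self) -> dict:
        return {
            f.name: {"units": f.units, "center": f.center, "half_range": f.half_range}
            for f in self.factors
        }

    @classmethod
    def from_dict(cls, spec: dict) -> "DesignSpace":
        """Build from a mapping name -> {units, center, half_range} or {units, low, high}."""
        factors = []
        for name, d in spec.items():
            units = d.get("units", "")
            if "center" in d and "half_range" in d:
                factors.append(Factor(name, units, float(d["center"]), float(d["half_range"])))
            elif "low" in d and "high" in d:
                factors.append(Factor.from_bounds(name, units, float(d["low"]), float(d["high"])))
            else:
                raise ValueError(f"factor {name!r}: give center/half_range or low/high")
        return cls(factors)


def default_bbd_space() -> DesignSpace:
    """Three-factor space for the Box-Behnken stage.

    Levels (15/20/25 mL/g, 40/50/60 degC, 60/70/80 %) are the package
    defaults; they place the quadratic ground-truth optimum at the
    reference process conditions (21.26 mL/g, 48.4 degC, 69.16 %).
    """
    return DesignSpace(
        [
            Factor("ratio", "mL/g", 20.0, 5.0),
            Factor("temperature", "degC", 50.0, 10.0),
            Factor("ethanol", "%", 70.0, 10.0),
        ]
    )


def default_pbd_space() -> DesignSpace:
    """Five-factor space for the Plackett-Burman screening stage.

    Two-level settings bracket the single-factor optima; only the coded
    analysis is consumed downstream, so the actual levels affect nothing
    but decoded reporting.
    """
    return DesignSpace(
        [
            Factor("ratio", "mL/g", 20.0, 5.0),
            Factor("time", "min", 60.0, 15.0),
            Factor("temperature", "degC", 50.0, 10.0),
            Factor("power", "W", 200.0, 50.0),
            Factor("ethanol", "%", 70.0, 10.0),
        ]
    )
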