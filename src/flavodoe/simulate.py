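"""Synthetic response generator for the extraction-optimization pipeline.

Raw run-level yields are emulated by evaluating a ground-truth response
surface at the coded design rows and adding i.i.d. Gaussian measurement
noise. The default truths are the package's reference surfaces for total
flavonoid content (TFC, mg/g) from *Cortex Mori* under ultrasound-assisted
enzymatic extraction:

* a five-factor first-order screening truth over (ratio, time,
  temperature, power, ethanol),
* a three-factor quadratic truth over (ratio, temperature, ethanol) whose
  box-constrained maximum sits at 21.26 mL/g, 48.39 degC, 69.16 % ethanol,
* single-factor concave scan curves peaking at the reference one-variable
  optima.

The default noise standard deviation, 0.2512 mg/g, is the square root of
the replicate (pure-error) mean square of the quadratic stage, so the
simulated center-point scatter matches the replicate scatter the ANOVA
assumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .designs import DesignMatrix
from .fitting import PolyModel

__all__ = [
    "GroundTruth",
    "quadratic_truth",
    "first_order_truth",
    "simulate_responses",
    "simulate_pbd_responses",
    "simulate_single_factor_curve",
    "SINGLE_FACTOR_CURVES",
    "DEFAULT_NOISE_SD",
]

# Replicate-scatter default: sqrt(pure-error mean square 0.0631).
DEFAULT_NOISE_SD = float(np.sqrt(0.0631))

_QUADRATIC_FACTORS = ["ratio", "temperature", "ethanol"]
# Intercept; linear A,C,E; interactions AC, AE, CE; quadratics A2, C2, E2.
_QUADRATIC_COEFFS = [20.74, 0.6146, -0.4384, -0.6933, 0.2776, 0.4901, -0.3598, -1.05, -1.05, -3.04]

_FIRST_ORDER_FACTORS = ["ratio", "time", "temperature", "power", "ethanol"]
_FIRST_ORDER_COEFFS = [18.95, 1.2, 0.1457, -0.7075, 0.0810, 0.3185]


def quadratic_truth() -> PolyModel:
    """Reference second-order TFC surface in coded (ratio, temperature, ethanol)."""
    return PolyModel.from_coefficients(_QUADRATIC_FACTORS, 2, _QUADRATIC_COEFFS)


def first_order_truth() -> PolyModel:
    """Reference first-order screening truth in coded (ratio, time, temperature, power, ethanol)."""
    return PolyModel.from_coefficients(_FIRST_ORDER_FACTORS, 1, _FIRST_ORDER_COEFFS)


@dataclass
class GroundTruth:
    """Noise model wrapped around a deterministic response surface.

    ``sigma`` is the measurement noise standard deviation in mg/g;
    homoscedastic Gaussian noise matches the OLS/ANOVA assumptions of the
    downstream analysis.
    """

    quadratic: PolyModel = field(default_factory=quadratic_truth)
    first_order: PolyModel = field(default_factory=first_order_truth)
    sigma: float = DEFAULT_NOISE_SD

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


def _simulate(model: PolyModel, design: DesignMatrix, sigma: float, seed) -> np.ndarray:
    if design.k != model.k:
        raise ValueError(f"design has {design.k} factors but truth expects {model.k}")
    mean = model.predict(design.levels)
    if sigma == 0:
        return np.asarray(mean, dtype=float)
    rng = np.random.default_rng(seed)
    return mean + rng.normal(0.0, sigma, size=design.n_runs)


def simulate_responses(design: DesignMatrix, truth: GroundTruth, seed=None) -> np.ndarray:
    """Quadratic-truth responses at the design rows plus N(0, sigma) noise."""
    return _simulate(truth.quadratic, design, truth.sigma, seed)


def simulate_pbd_responses(design: DesignMatrix, truth: GroundTruth, seed=None) -> np.ndarray:
    """First-order screening-truth responses plus N(0, sigma) noise."""
    return _simulate(truth.first_order, design, truth.sigma, seed)


@dataclass(frozen=True)
class _ScanCurve:
    peak_x: float
    peak_y: float
    anchor_x: float
    anchor_y: float
    anchored: bool  # False -> anchor chosen for illustration only

    def curvature(self) -> float:
        return (self.peak_y - self.anchor_y) / (self.anchor_x - self.peak_x) ** 2

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        return self.peak_y - self.curvature() * (x - self.peak_x) ** 2


# Concave single-variable scan curves: quadratic through the peak and one
# anchor. Only the temperature scan has a second reference value
# (14.64 mg/g at 30 degC); the other anchors are illustrative choices at the
# scanned range's edge.
SINGLE_FACTOR_CURVES: dict[str, _ScanCurve] = {
    "ratio": _ScanCurve(20.0, 19.44, 10.0, 15.5, anchored=False),
    "time": _ScanCurve(60.0, 19.24, 15.0, 15.8, anchored=False),
    "temperature": _ScanCurve(50.0, 19.38, 30.0, 14.64, anchored=True),
    "power": _ScanCurve(200.0, 19.3, 125.0, 16.8, anchored=False),
    "ethanol": _ScanCurve(70.0, 20.30, 30.0, 13.5, anchored=False),
}


def simulate_single_factor_curve(
    factor_name: str,
    grid,
    sigma: float = 0.4,
    seed=None,
) -> tuple[np.ndarray, np.ndarray]:
    """One-variable scan responses: concave quadratic through the reference peak.

    Returns (levels, responses) in actual units; used for smoke tests and
    demonstration plots, not for model fitting.
    """
    try:
        curve = SINGLE_FACTOR_CURVES[factor_name]
    except KeyError:
        raise KeyError(f"no single-factor curve for {factor_name!r}") from None
    levels = np.asarray(grid, dtype=float)
    y = curve(levels)
    if sigma > 0:
        y = y + np.random.default_rng(seed).normal(0.0, sigma, size=levels.shape)
    return levels, y
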