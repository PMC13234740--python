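"""Assay arithmetic: TFC standard curve and yield, DPPH scavenging, validation table.

Total flavonoid content (TFC) is quantified colorimetrically against a
rutin standard curve C = slope*A + intercept (C in mg/mL, A the absorbance
at 510 nm), then converted to a mass yield

    yield (mg/g) = C * V * N / M

with extract volume V (mL), dilution ratio N and sample mass M (g). DPPH
radical scavenging is [1 - (A1 - A2)/A0] * 100 %. The validation layer
compares predicted optima against (simulated or measured) experimental
means via the relative error 100 * |predicted - actual| / actual.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "StandardCurve",
    "DEFAULT_STANDARD_CURVE",
    "tfc_concentration",
    "tfc_yield",
    "dpph_scavenging",
    "relative_error",
    "build_comparison",
]


@dataclass(frozen=True)
class StandardCurve:
    """Linear calibration C = slope*A + intercept (mg/mL per absorbance unit)."""

    slope: float = 5.8833
    intercept: float = 0.0031

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("calibration slope must be positive")


DEFAULT_STANDARD_CURVE = StandardCurve()


def tfc_concentration(absorbance: float, curve: StandardCurve = DEFAULT_STANDARD_CURVE) -> float:
    """Flavonoid concentration (mg/mL) from absorbance via the standard curve."""
    if absorbance < 0:
        raise ValueError("absorbance must be >= 0")
    return curve.slope * absorbance + curve.intercept


def tfc_yield(C: float, V: float, N: float, M: float) -> float:
    """TFC yield in mg per g dry material: C*V*N/M."""
    if V <= 0 or M <= 0:
        raise ValueError("V and M must be positive")
    if N < 1:
        raise ValueError("dilution ratio N must be >= 1")
    return C * V * N / M


def dpph_scavenging(A0: float, A1: float, A2: float) -> float:
    """DPPH radical scavenging percentage [1 - (A1 - A2)/A0] * 100.

    A0: radical solution, A1: sample+radical mixture, A2: sample blank.
    Pathological absorbances can push the value outside [0, 100]; it is
    returned as-is with a warning.
    """
    if A0 <= 0:
        raise ValueError("A0 must be positive")
    pct = (1.0 - (A1 - A2) / A0) * 100.0
    if not 0.0 <= pct <= 100.0:
        warnings.warn(f"scavenging {pct:.2f}% outside [0, 100]", stacklevel=2)
    return pct


def relative_error(predicted: float, actual: float) -> float:
    """Model-validation relative error 100*|predicted - actual|/|actual|."""
    if actual == 0:
        raise ValueError("actual value must be nonzero")
    return 100.0 * abs(predicted - actual) / abs(actual)


def build_comparison(records: list[dict], factor_names: list[str]) -> pd.DataFrame:
    """Validation table comparing optimizer predictions with experimental means.

    Each record needs: method, conditions (actual units, one per factor),
    predicted (mg/g), actual_mean, actual_sd. Relative errors are
    recomputed here, never carried in.
    """
    rows = []
    for rec in records:
        cond = np.asarray(rec["conditions"], dtype=float)
        if cond.shape[0] != len(factor_names):
            raise ValueError("conditions length must match factor_names")
        row = {"method": rec["method"]}
        row.update(dict(zip(factor_names, cond)))
        row["predicted"] = float(rec["predicted"])
        row["actual_mean"] = float(rec["actual_mean"])
        row["actual_sd"] = float(rec.get("actual_sd", np.nan))
        row["relative_error_pct"] = relative_error(row["predicted"], row["actual_mean"])
        rows.append(row)
    return pd.DataFrame(rows)
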