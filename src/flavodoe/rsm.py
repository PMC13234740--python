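"""Canonical analysis and constrained optimization of second-order models.

A fitted quadratic Y = b0 + b'x + x'Ax (A symmetric, built from the
quadratic and interaction coefficients) has stationary point
x* = -(2A)^{-1} b, classified by the Hessian 2A eigenvalues. The box
optimum over the coded cube is found exactly by recursion over faces: each
face of the box is a lower-dimensional quadratic, so the global constrained
maximum is attained either at an interior stationary point or on a face,
down to the vertices. No numeric search is involved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design_space import DesignSpace
from .fitting import PolyModel

__all__ = ["StationaryPoint", "stationary_point", "optimize_in_box", "predict", "surface_grid"]

_DEGENERATE_EIG = 1e-10


@dataclass
class StationaryPoint:
    """Critical (or constrained-optimal) point of a quadratic surface."""

    coded: np.ndarray
    predicted: float
    nature: str  # maximum | minimum | saddle | degenerate | boundary
    inside_box: bool
    actual: np.ndarray | None = None
    factor_names: list[str] | None = None

    def decode(self, space: DesignSpace) -> "StationaryPoint":
        self.actual = space.decode(self.coded)[0]
        self.factor_names = space.names
        return self


def _quadratic_parts(model: PolyModel) -> tuple[float, np.ndarray, np.ndarray]:
    """Split coefficients into constant c, linear vector b, symmetric matrix A."""
    if model.order != 2:
        raise ValueError("canonical analysis needs a second-order model")
    k = model.k
    names = model.factor_names
    c = model.coef["Intercept"]
    b = np.array([model.coef[n] for n in names])
    A = np.zeros((k, k))
    for i in range(k):
        A[i, i] = model.coef[f"{names[i]}^2"]
        for j in range(i + 1, k):
            A[i, j] = A[j, i] = model.coef[f"{names[i]}:{names[j]}"] / 2.0
    return c, b, A


def _classify(H: np.ndarray) -> str:
    eig = np.linalg.eigvalsh(H)
    if np.any(np.abs(eig) < _DEGENERATE_EIG):
        return "degenerate"
    if np.all(eig < 0):
        return "maximum"
    if np.all(eig > 0):
        return "minimum"
    return "saddle"


def predict(model: PolyModel, point) -> float:
    """Polynomial prediction at one coded point."""
    return model.predict(np.asarray(point, dtype=float))


def stationary_point(model: PolyModel, space: DesignSpace | None = None) -> StationaryPoint:
    """Solve grad Y = 0 and classify by Hessian eigenvalues.

    Falls back to the exact box optimum when the Hessian is singular.
    """
    c, b, A = _quadratic_parts(model)
    H = 2.0 * A
    nature = _classify(H)
    if nature == "degenerate":
        sp = optimize_in_box(model, space=space)
        sp.nature = "degenerate"
        return sp
    x = np.linalg.solve(H, -b)
    sp = StationaryPoint(
        coded=x,
        predicted=float(c + b @ x + x @ A @ x),
        nature=nature,
        inside_box=bool(np.all(np.abs(x) <= 1.0)),
        factor_names=list(model.factor_names),
    )
    if space is not None:
        sp.decode(space)
    return sp


def _maximize_quadratic_box(c: float, b: np.ndarray, A: np.ndarray, lo: np.ndarray, hi: np.ndarray):
    """Exact recursive maximization of c + b'x + x'Ax over [lo, hi]^k.

    Candidates: the interior stationary point (when the Hessian is
    invertible and the point lies in the box) and, recursively, the optimum
    of every face obtained by pinning one coordinate at a bound. Vertices
    terminate the recursion.
    """
    k = len(b)
    if k == 0:
        return np.empty(0), c
    best_x, best_v = None, -np.inf
    H = 2.0 * A
    if abs(np.linalg.det(H)) > _DEGENERATE_EIG:
        x = np.linalg.solve(H, -b)
        if np.all(x >= lo - 1e-12) and np.all(x <= hi + 1e-12):
            x = np.clip(x, lo, hi)
            best_x, best_v = x, float(c + b @ x + x @ A @ x)
    keep = np.arange(k)
    for i in range(k):
        rest = keep[keep != i]
        for v in (lo[i], hi[i]):
            c2 = c + b[i] * v + A[i, i] * v * v
            b2 = b[rest] + 2.0 * A[rest, i] * v
            A2 = A[np.ix_(rest, rest)]
            sub_x, sub_v = _maximize_quadratic_box(c2, b2, A2, lo[rest], hi[rest])
            if sub_v > best_v:
                x = np.empty(k)
                x[rest], x[i] = sub_x, v
                best_x, best_v = x, sub_v
    return best_x, best_v


def optimize_in_box(
    model: PolyModel,
    bounds: tuple[float, float] | np.ndarray = (-1.0, 1.0),
    space: DesignSpace | None = None,
) -> StationaryPoint:
    """Global maximum of the quadratic over a coded box (default [-1,1]^k)."""
    c, b, A = _quadratic_parts(model)
    k = model.k
    bnd = np.asarray(bounds, dtype=float)
    if bnd.shape == (2,):
        lo, hi = np.full(k, bnd[0]), np.full(k, bnd[1])
    else:
        lo, hi = bnd[:, 0].copy(), bnd[:, 1].copy()
    x, v = _maximize_quadratic_box(c, b, A, lo, hi)
    interior = bool(np.all(x > lo + 1e-12) and np.all(x < hi - 1e-12))
    nature = _classify(2.0 * A) if interior else "boundary"
    sp = StationaryPoint(
        coded=x,
        predicted=v,
        nature=nature,
        inside_box=True,
        factor_names=list(model.factor_names),
    )
    if space is not None:
        sp.decode(space)
    return sp


def surface_grid(
    model: PolyModel,
    factor_pair: tuple[str, str],
    fixed_levels: dict[str, float] | None = None,
    resolution: int = 41,
) -> pd.DataFrame:
    """Regular prediction grid over two factors for surface/contour plots.

    Remaining factors are held at the given coded levels (default 0).
    """
    if resolution < 2:
        raise ValueError("resolution must be >= 2")
    names = model.factor_names
    fa, fb = factor_pair
    for f in (fa, fb):
        if f not in names:
            raise KeyError(f"unknown factor {f!r}")
    fixed_levels = dict(fixed_levels or {})
    for f in fixed_levels:
        if f not in names:
            raise KeyError(f"unknown factor {f!r}")
    axis = np.linspace(-1.0, 1.0, resolution)
    ga, gb = np.meshgrid(axis, axis, indexing="ij")
    pts = np.zeros((resolution * resolution, len(names)))
    for j, nm in enumerate(names):
        if nm == fa:
            pts[:, j] = ga.ravel()
        elif nm == fb:
            pts[:, j] = gb.ravel()
        else:
            pts[:, j] = fixed_levels.get(nm, 0.0)
    preds = model.predict(pts)
    return pd.DataFrame({fa: ga.ravel(), fb: gb.ravel(), "predicted": preds})
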