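"""Experimental design generators: Plackett-Burman, Box-Behnken, Latin hypercube.

All designs are produced in coded units. The 12-run Plackett-Burman design
screens up to 11 two-level factors for main effects; the 3-factor
Box-Behnken design (12 edge midpoints + replicated centers) supports a full
second-order model; Latin hypercube samples feed the neural-network
surrogate stage.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import qmc

__all__ = ["DesignMatrix", "plackett_burman", "box_behnken", "latin_hypercube"]

# Canonical first row of the N=12 Plackett-Burman cyclic construction.
_PB12_GENERATOR = np.array([+1, +1, -1, +1, +1, +1, -1, -1, -1, +1, -1], dtype=float)


@dataclass
class DesignMatrix:
    """Runs-by-factors matrix of coded levels plus design metadata.

    ``levels`` holds the columns assigned to real factors. For a
    Plackett-Burman design the unassigned generator columns are kept in
    ``dummy_levels``: they carry no factor but remain available as error
    contrasts.
    """

    levels: np.ndarray
    factor_names: list[str]
    design_kind: str
    center_point_flags: np.ndarray
    run_ids: np.ndarray = field(default=None)
    dummy_levels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=float)
        if self.levels.ndim != 2:
            raise ValueError("levels must be a 2-D runs x factors array")
        n, k = self.levels.shape
        if len(self.factor_names) != k:
            raise ValueError("factor_names length must match number of columns")
        self.center_point_flags = np.asarray(self.center_point_flags, dtype=bool)
        if self.center_point_flags.shape != (n,):
            raise ValueError("center_point_flags must have one entry per run")
        if self.run_ids is None:
            self.run_ids = np.arange(1, n + 1)

    @property
    def n_runs(self) -> int:
        return self.levels.shape[0]

    @property
    def k(self) -> int:
        return self.levels.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.levels, columns=[f"{c}_coded" for c in self.factor_names])
        df.insert(0, "run_id", self.run_ids)
        df["is_center"] = self.center_point_flags.astype(int)
        return df


def plackett_burman(n_factors: int, seed: int | None = None, factor_names=None) -> DesignMatrix:
    """12-run Plackett-Burman screening design for up to 11 factors.

    Built from the canonical generator row by cyclic shifts plus a final
    all-minus run. The first ``n_factors`` generator columns are assigned to
    the declared factors (assignment is immaterial by orthogonality); the
    remaining columns are retained as dummy contrasts in ``dummy_levels``.
    ``seed`` is accepted for interface symmetry; the construction and run
    order are deterministic.
    """
    if not 1 <= n_factors <= 11:
        raise ValueError("the 12-run Plackett-Burman design supports 1..11 factors")
    rows = [np.roll(_PB12_GENERATOR, shift) for shift in range(11)]
    rows.append(-np.ones(11))
    full = np.array(rows)
    if factor_names is None:
        factor_names = [f"X{i + 1}" for i in range(n_factors)]
    if len(factor_names) != n_factors:
        raise ValueError("factor_names length must equal n_factors")
    return DesignMatrix(
        levels=full[:, :n_factors],
        factor_names=list(factor_names),
        design_kind="pbd",
        center_point_flags=np.zeros(12, dtype=bool),
        dummy_levels=full[:, n_factors:] if n_factors < 11 else None,
    )


def box_behnken(k: int = 3, n_center: int = 5, factor_names=None) -> DesignMatrix:
    """Three-factor Box-Behnken design: 12 edge midpoints plus center replicates.

    Each non-center run sets one factor to 0 and the other two to +/-1; the
    default 5 center replicates give 17 runs and a pure-error estimate.
    """
    if k != 3:
        raise ValueError("only the 3-factor Box-Behnken design is supported")
    if n_center < 0:
        raise ValueError("n_center must be >= 0")
    edges = []
    for zero_axis in range(3):
        for s1, s2 in itertools.product((-1.0, 1.0), repeat=2):
            row = [0.0, 0.0, 0.0]
            others = [a for a in range(3) if a != zero_axis]
            row[others[0]], row[others[1]] = s1, s2
            edges.append(row)
    levels = np.array(edges + [[0.0, 0.0, 0.0]] * n_center)
    flags = np.array([False] * 12 + [True] * n_center)
    if factor_names is None:
        factor_names = [f"X{i + 1}" for i in range(k)]
    return DesignMatrix(
        levels=levels,
        factor_names=list(factor_names),
        design_kind="bbd",
        center_point_flags=flags,
    )


def latin_hypercube(n: int, k: int, seed: int, factor_names=None) -> DesignMatrix:
    """n-point Latin hypercube sample on the coded box [-1, 1]^k.

    Plain stratified LHS (one uniform draw per equal-width stratum per
    dimension, random stratum pairing), with no optimization criterion;
    reproducible under ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    sampler = qmc.LatinHypercube(d=k, seed=np.random.default_rng(seed))
    unit = sampler.random(n)
    levels = 2.0 * unit - 1.0
    if factor_names is None:
        factor_names = [f"X{i + 1}" for i in range(k)]
    return DesignMatrix(
        levels=levels,
        factor_names=list(factor_names),
        design_kind="lhs",
        center_point_flags=np.zeros(n, dtype=bool),
    )
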