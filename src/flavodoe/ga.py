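"""Real-coded genetic algorithm over the coded factor box.

Maximizes an arbitrary objective (neural-network surrogate or polynomial)
with tournament selection (size 2), BLX-alpha blend crossover, per-gene
Gaussian mutation, bound clipping and single-individual elitism. Random
draws are streamed per generation from (seed, generation), so extending
``max_generations`` replays the identical prefix and can only improve the
returned best value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .design_space import DesignSpace

__all__ = ["GAConfig", "GAResult", "run_ga"]

log = logging.getLogger(__name__)


@dataclass
class GAConfig:
    population_size: int = 30
    max_generations: int = 50
    crossover_probability: float = 0.7
    mutation_probability: float = 0.15
    bounds: tuple[float, float] = (-1.0, 1.0)
    n_genes: int = 3
    elite_count: int = 1
    blx_alpha: float = 0.5
    mutation_sd_fraction: float = 0.1  # sd = fraction * box width, per gene
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        for p in (self.crossover_probability, self.mutation_probability):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if not 0 <= self.elite_count < self.population_size:
            raise ValueError("elite_count must be in [0, population_size)")

    def box(self) -> tuple[np.ndarray, np.ndarray]:
        bnd = np.asarray(self.bounds, dtype=float)
        if bnd.shape == (2,):
            return np.full(self.n_genes, bnd[0]), np.full(self.n_genes, bnd[1])
        return bnd[:, 0], bnd[:, 1]


@dataclass
class GAResult:
    best_coded: np.ndarray
    best_value: float
    trace: list[float]  # best-so-far per generation (non-decreasing)
    evaluations: int
    best_actual: np.ndarray | None = None
    factor_names: list[str] | None = None

    def decode(self, space: DesignSpace) -> "GAResult":
        self.best_actual = space.decode(self.best_coded)[0]
        self.factor_names = space.names
        return self


def _evaluate(objective, pop: np.ndarray) -> np.ndarray:
    vals = np.empty(len(pop))
    for i, ind in enumerate(pop):
        v = float(objective(ind))
        if not np.isfinite(v):
            log.warning("objective returned non-finite value at %s; assigning -inf", ind)
            v = -np.inf
        vals[i] = v
    return vals


def run_ga(objective, config: GAConfig) -> GAResult:
    """Maximize ``objective`` over the box; deterministic under ``config.seed``."""
    lo, hi = config.box()
    width = hi - lo
    n, g_max = config.population_size, config.max_generations

    rng0 = np.random.default_rng([int(config.seed), 0])
    pop = rng0.uniform(lo, hi, size=(n, config.n_genes))
    fitness = _evaluate(objective, pop)
    evals = n
    best_i = int(np.argmax(fitness))
    best_x, best_v = pop[best_i].copy(), float(fitness[best_i])
    trace = []

    for gen in range(1, g_max + 1):
        rng = np.random.default_rng([int(config.seed), gen])
        order = np.argsort(fitness)[::-1]
        elites = pop[order[: config.elite_count]].copy()
        children = []
        while len(children) < n - config.elite_count:
            # two independent size-2 tournaments
            parents = []
            for _ in range(2):
                a, b = rng.integers(0, n, size=2)
                parents.append(pop[a] if fitness[a] >= fitness[b] else pop[b])
            p1, p2 = parents
            if rng.random() < config.crossover_probability:
                cmin = np.minimum(p1, p2)
                cmax = np.maximum(p1, p2)
                d = cmax - cmin
                child = rng.uniform(cmin - config.blx_alpha * d, cmax + config.blx_alpha * d)
            else:
                child = p1.copy()
            mutate = rng.random(config.n_genes) < config.mutation_probability
            if mutate.any():
                child = child + mutate * rng.normal(0.0, config.mutation_sd_fraction * width)
            children.append(np.clip(child, lo, hi))
        pop = np.vstack([elites, np.array(children)])
        fitness = _evaluate(objective, pop)
        evals += n
        gen_best = int(np.argmax(fitness))
        if fitness[gen_best] > best_v:
            best_v = float(fitness[gen_best])
            best_x = pop[gen_best].copy()
        trace.append(best_v)

    return GAResult(best_coded=best_x, best_value=best_v, trace=trace, evaluations=evals)
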