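"""Genetic-algorithm maximization of a removal surrogate over a factor box.

Individuals are real-valued 4-vectors in actual units.  Each generation
applies elitism (the best ``elite_count`` copied unchanged), roulette
(fitness-proportional) selection after shifting scores to be positive,
single-point crossover, and per-gene Gaussian mutation clipped to the
bounds.  The fitness of a candidate with predicted removal y is
``1 - 1/y``, strictly increasing in y, so maximizing fitness maximizes
the surrogate's predicted removal; non-positive predictions receive a
large penalty instead of raising.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .errors import ConfigurationError

__all__ = ["GAConfig", "GAResult", "fitness", "evolve", "optimize", "optimize_restarts"]

#: Fitness assigned to candidates whose predicted removal is <= 0.
PENALTY_FITNESS = -1.0e9

#: Factor bounds of the As(III) biosorption optimization: biomass dose
#: 0.1-1.3 g/L, pH 2-10, temperature 25-45 degC, As(III) 0.1-1.3 mg/L.
DEFAULT_BOUNDS: tuple[tuple[float, float], ...] = (
    (0.1, 1.3),
    (2.0, 10.0),
    (25.0, 45.0),
    (0.1, 1.3),
)


@dataclass(frozen=True)
class GAConfig:
    population_size: int = 100
    elite_count: int = 20
    crossover_prob: float = 0.8
    generations: int = 100
    mutation_sd: tuple[float, ...] | None = None  # per gene; default 0.1*(hi-lo)
    bounds: tuple[tuple[float, float], ...] = DEFAULT_BOUNDS
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.elite_count < self.population_size:
            raise ConfigurationError("elite_count must be < population_size")
        if not 0.0 <= self.crossover_prob <= 1.0:
            raise ConfigurationError("crossover_prob must be in [0, 1]")
        for lo, hi in self.bounds:
            # equality is tolerated as the degenerate "factor pinned" case
            if not (np.isfinite(lo) and np.isfinite(hi) and lo <= hi):
                raise ConfigurationError("bounds must be finite with lower <= upper")

    @property
    def lower(self) -> np.ndarray:
        return np.array([b[0] for b in self.bounds], dtype=float)

    @property
    def upper(self) -> np.ndarray:
        return np.array([b[1] for b in self.bounds], dtype=float)

    @property
    def sigma(self) -> np.ndarray:
        if self.mutation_sd is not None:
            return np.asarray(self.mutation_sd, dtype=float)
        return 0.1 * (self.upper - self.lower)


@dataclass
class GAResult:
    best_x: np.ndarray  # actual units
    best_prediction: float  # % removal at best_x
    best_fitness: float
    fitness_history: list[float] = field(default_factory=list)  # best per generation
    config: GAConfig | None = None

    def to_dict(self) -> dict:
        d = {
            "best_x": self.best_x.tolist(),
            "best_prediction": self.best_prediction,
            "best_fitness": self.best_fitness,
            "fitness_history": list(self.fitness_history),
        }
        if self.config is not None:
            d["config"] = {
                "population_size": self.config.population_size,
                "elite_count": self.config.elite_count,
                "crossover_prob": self.config.crossover_prob,
                "generations": self.config.generations,
                "bounds": [list(b) for b in self.config.bounds],
                "seed": self.config.seed,
            }
        return d


def fitness(y_pred: float | np.ndarray) -> float | np.ndarray:
    """Fitness score 1 - 1/y of a predicted removal; penalized for y <= 0."""
    y = np.asarray(y_pred, dtype=float)
    with np.errstate(divide="ignore"):
        eps = np.where(y > 0.0, 1.0 - 1.0 / np.where(y > 0.0, y, 1.0), PENALTY_FITNESS)
    return float(eps) if np.ndim(y_pred) == 0 else eps


def _selection_weights(fit: np.ndarray) -> np.ndarray:
    """Roulette weights: shift by the generation minimum so all are positive.

    When every candidate has equal fitness the shift makes all weights
    equal, i.e. selection degenerates to uniform sampling.
    """
    w = fit - fit.min() + 1e-12
    return w / w.sum()


def evolve(
    population: np.ndarray,
    surrogate: Callable[[np.ndarray], np.ndarray],
    config: GAConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """One generation: elitism, roulette selection, single-point crossover,
    Gaussian mutation with clipping.  Returns the next population."""
    pop = np.asarray(population, dtype=float)
    n, L = pop.shape
    if n != config.population_size:
        raise ConfigurationError("population size does not match config")
    y = np.asarray(surrogate(pop), dtype=float)
    fit = fitness(y)
    order = np.argsort(-fit, kind="stable")
    weights = _selection_weights(fit)
    lo, hi, sigma = config.lower, config.upper, config.sigma

    children: list[np.ndarray] = [pop[i].copy() for i in order[: config.elite_count]]
    while len(children) < n:
        i, j = rng.choice(n, size=2, p=weights)
        c1, c2 = pop[i].copy(), pop[j].copy()
        if rng.random() < config.crossover_prob:
            cut = int(rng.integers(1, L))
            c1[cut:], c2[cut:] = pop[j][cut:].copy(), pop[i][cut:].copy()
        for c in (c1, c2):
            if len(children) < n:
                mutated = c + rng.normal(0.0, sigma)
                children.append(np.clip(mutated, lo, hi))
    return np.array(children)


def optimize(
    surrogate: Callable[[np.ndarray], np.ndarray],
    config: GAConfig = GAConfig(),
) -> GAResult:
    """Run the GA for ``config.generations`` generations and report the
    best-ever individual.  ``surrogate`` maps (n, 4) actual-unit factor
    matrices to predicted removals (%).  Deterministic under the seed."""
    rng = np.random.default_rng(config.seed)
    lo, hi = config.lower, config.upper
    pop = rng.uniform(lo, hi, size=(config.population_size, len(config.bounds)))
    best_x, best_y, best_fit = None, -np.inf, -np.inf
    history: list[float] = []
    for _ in range(config.generations):
        y = np.asarray(surrogate(pop), dtype=float)
        fit = fitness(y)
        k = int(np.argmax(fit))
        if fit[k] > best_fit:
            best_fit, best_y, best_x = float(fit[k]), float(y[k]), pop[k].copy()
        history.append(best_fit)
        pop = evolve(pop, surrogate, config, rng)
    # evaluate the final population as well
    y = np.asarray(surrogate(pop), dtype=float)
    fit = fitness(y)
    k = int(np.argmax(fit))
    if fit[k] > best_fit:
        best_fit, best_y, best_x = float(fit[k]), float(y[k]), pop[k].copy()
    return GAResult(best_x, best_y, best_fit, history, config)


def optimize_restarts(
    surrogate: Callable[[np.ndarray], np.ndarray],
    config: GAConfig = GAConfig(),
    restarts: int = 10,
) -> tuple[GAResult, list[GAResult]]:
    """Re-run the GA from ``restarts`` seeded initial populations and return
    (consensus best result, all results).  The consensus best is the run
    with the highest best-ever prediction; agreement across restarts is
    what certifies it as a global rather than a lucky local optimum."""
    seeds = np.random.SeedSequence(config.seed).generate_state(restarts) % (2**31)
    results = [optimize(surrogate, replace(config, seed=int(s))) for s in seeds]
    best = max(results, key=lambda r: r.best_prediction)
    return best, results
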