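"""Real-coded genetic algorithm over box-bounded extraction conditions.

The GA maximizes any predictor mapping actual-unit condition triples to
yield %: the trained neural surrogate, the fitted quadratic, or an
arbitrary callable.  Operators are the conventional real-coded set —
tournament selection (size 2), arithmetic blend crossover, per-gene uniform
reset mutation, and elitist carry-over — all driven by one seeded
generator, so a run is fully reproducible.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .design import Dataset
from .neural import MLPParams, TrainConfig, TrainHistory, forward, train

__all__ = ["GAConfig", "GAResult", "FitnessDomainError", "run_ga", "ga_bp_pipeline", "write_trace"]

Fitness = Callable[[np.ndarray], float]


class FitnessDomainError(RuntimeError):
    """Raised when no finite-fitness individual can be produced."""


@dataclass
class GAConfig:
    bounds: tuple[tuple[float, float], ...]
    population_size: int = 50
    generations: int = 600
    crossover_prob: float = 0.8
    mutation_prob: float = 0.1
    elitism: int = 1
    #: optional stagnation patience; None means a fixed generation budget
    stagnation_patience: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for lo, hi in self.bounds:
            if not lo < hi:
                raise ValueError(f"invalid bound ({lo}, {hi}): low < high required")
        if not 0 <= self.elitism < self.population_size:
            raise ValueError("require 0 <= elitism < population_size")
        for name in ("crossover_prob", "mutation_prob"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass
class GAResult:
    best_point: tuple[float, ...]
    best_fitness: float
    #: per-generation (best fitness, mean fitness)
    trace: list[tuple[float, float]] = field(default_factory=list)
    n_rejected: int = 0


def _evaluate(
    fitness: Fitness,
    pop: np.ndarray,
    lo: np.ndarray,
    hi: np.ndarray,
    rng: np.random.Generator,
    max_resample: int = 100,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Fitness per row; non-finite individuals are resampled uniformly."""
    vals = np.empty(len(pop))
    rejected = 0
    for i in range(len(pop)):
        v = float(fitness(pop[i]))
        tries = 0
        while not np.isfinite(v):
            rejected += 1
            tries += 1
            if tries > max_resample:
                raise FitnessDomainError(
                    "could not sample an individual with finite fitness"
                )
            pop[i] = rng.uniform(lo, hi)
            v = float(fitness(pop[i]))
        vals[i] = v
    return pop, vals, rejected


def run_ga(
    fitness: Fitness,
    config: GAConfig,
    seed_points: Sequence[Sequence[float]] | None = None,
) -> GAResult:
    """Maximize ``fitness`` over the configured box.

    ``seed_points`` (clipped to bounds) are injected into generation 0,
    replacing uniformly sampled individuals; the remainder of the initial
    population is sampled uniformly within bounds.
    """
    lo = np.array([b[0] for b in config.bounds], dtype=float)
    hi = np.array([b[1] for b in config.bounds], dtype=float)
    d = len(config.bounds)
    rng = np.random.default_rng(config.seed)

    pop = rng.uniform(lo, hi, size=(config.population_size, d))
    if seed_points is not None:
        injected = np.clip(np.asarray(seed_points, dtype=float), lo, hi)
        k = min(len(injected), config.population_size)
        pop[:k] = injected[:k]
    pop, vals, n_rejected = _evaluate(fitness, pop, lo, hi, rng)

    trace: list[tuple[float, float]] = []
    best_x, best_v = pop[int(np.argmax(vals))].copy(), float(vals.max())
    stale = 0
    for _gen in range(config.generations):
        order = np.argsort(vals)[::-1]
        elite = pop[order[: config.elitism]].copy()

        # tournament selection, size 2
        n_offspring = config.population_size - config.elitism
        idx = rng.integers(0, config.population_size, size=(2 * n_offspring, 2))
        winners = np.where(
            vals[idx[:, 0]] >= vals[idx[:, 1]], idx[:, 0], idx[:, 1]
        )
        parents = pop[winners].reshape(n_offspring, 2, d)

        # arithmetic (blend) crossover with a per-gene mixing weight
        children = parents[:, 0].copy()
        cross = rng.uniform(size=n_offspring) < config.crossover_prob
        alpha = rng.uniform(size=(n_offspring, d))
        blended = alpha * parents[:, 0] + (1 - alpha) * parents[:, 1]
        children[cross] = blended[cross]

        # per-gene uniform reset mutation
        mutate = rng.uniform(size=(n_offspring, d)) < config.mutation_prob
        resets = rng.uniform(lo, hi, size=(n_offspring, d))
        children[mutate] = resets[mutate]

        pop = np.vstack([elite, children])
        pop, vals, rej = _evaluate(fitness, pop, lo, hi, rng)
        n_rejected += rej

        gen_best = float(vals.max())
        if gen_best > best_v:
            best_v = gen_best
            best_x = pop[int(np.argmax(vals))].copy()
            stale = 0
        else:
            stale += 1
        trace.append((best_v if config.elitism else gen_best, float(vals.mean())))
        if config.stagnation_patience is not None and stale >= config.stagnation_patience:
            break
    return GAResult(
        best_point=tuple(best_x), best_fitness=best_v, trace=trace, n_rejected=n_rejected
    )


def ga_bp_pipeline(
    data: Dataset,
    train_config: TrainConfig | None = None,
    ga_config: GAConfig | None = None,
) -> tuple[MLPParams, TrainHistory, GAResult]:
    """Train the neural surrogate, then GA-maximize its predicted yield.

    The experimental input rows are injected into the initial population,
    so the search starts from conditions the surrogate has actually seen;
    the optimum is reported in actual units.
    """
    train_config = train_config or TrainConfig()
    obs = data.observed()
    if ga_config is None:
        X = obs.actual_matrix
        ga_config = GAConfig(
            bounds=tuple((float(c.min()), float(c.max())) for c in X.T)
        )
    params, history = train(data, train_config)
    fitness = lambda x: float(forward(params, x))
    result = run_ga(fitness, ga_config, seed_points=obs.actual_matrix)
    return params, history, result


def write_trace(result: GAResult, path: str | Path) -> None:
    """CSV trace ``generation,best_fitness,mean_fitness``."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["generation", "best_fitness", "mean_fitness"])
        for g, (best, mean) in enumerate(result.trace):
            writer.writerow([g, repr(best), repr(mean)])
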