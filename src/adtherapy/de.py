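"""Differential evolution with the DE/rand-to-best/1 mutation strategy.

Small, fully seeded global optimizer used for both planning phases.  The
donor vector is

    v = x_r1 + F (x_best - x_r1) + F (x_r2 - x_r3)

with r1, r2, r3 drawn without replacement from the population excluding the
target index, followed by binomial crossover with a guaranteed donor
coordinate, boundary clipping, and greedy one-to-one selection (the trial
replaces the target when its objective is not worse, which favours
exploration on plateaus).  A fixed generation budget is used; there is no
early stopping.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .params import DEConfig

__all__ = ["mutate", "crossover", "optimize", "OptimizationResult"]


@dataclass
class OptimizationResult:
    best_vector: np.ndarray
    best_objective: float
    history: np.ndarray     # best objective after each generation (non-increasing)
    evaluations: int
    seed: int


def mutate(population: np.ndarray, best: np.ndarray, F: float,
           rng: np.random.Generator, target_index: int | None = None) -> np.ndarray:
    """DE/rand-to-best/1 donor vector.

    r1, r2, r3 are distinct members, excluding ``target_index`` if given.
    """
    n = population.shape[0]
    pool = np.arange(n)
    if target_index is not None:
        pool = pool[pool != target_index]
    if pool.size < 3:
        raise ValueError("population too small for rand-to-best/1 mutation")
    r1, r2, r3 = rng.choice(pool, size=3, replace=False)
    x1 = population[r1]
    return x1 + F * (best - x1) + F * (population[r2] - population[r3])


def crossover(target: np.ndarray, donor: np.ndarray, CR: float,
              rng: np.random.Generator) -> np.ndarray:
    """Binomial crossover with a guaranteed donor coordinate (j_rand)."""
    if target.shape != donor.shape:
        raise ValueError("target and donor must have equal dimensionality")
    d = target.size
    mask = rng.random(d) < CR
    mask[rng.integers(d)] = True
    trial = np.where(mask, donor, target)
    return trial


def optimize(objective, bounds, config: DEConfig,
             log_path=None) -> OptimizationResult:
    """Minimize ``objective`` over the box ``bounds`` = [(lo, hi), ...].

    Fully reproducible for a given config (seed included).  Out-of-bounds
    trial coordinates are clipped to the nearest bound.  A non-finite
    objective value aborts with the offending vector in the message.
    ``log_path`` appends one JSON line per generation
    (gen, best_J, best_vector, seed) as an optimizer audit trail.
    """
    lo = np.array([b[0] for b in bounds], dtype=float)
    hi = np.array([b[1] for b in bounds], dtype=float)
    if not (np.all(np.isfinite(lo)) and np.all(np.isfinite(hi)) and np.all(lo < hi)):
        raise ValueError("bounds must be finite with lo < hi")
    d = lo.size
    rng = np.random.default_rng(config.seed)
    n = config.population_size

    pop = lo + rng.random((n, d)) * (hi - lo)
    J = np.empty(n)
    for i in range(n):
        J[i] = objective(pop[i])
    _check_finite(J, pop)
    evaluations = n

    best_i = int(np.argmin(J))
    best_x = pop[best_i].copy()
    best_J = float(J[best_i])
    history = np.empty(config.generations)

    log_fh = open(log_path, "a") if log_path is not None else None
    try:
        for g in range(config.generations):
            for i in range(n):
                donor = mutate(pop, best_x, config.F, rng, target_index=i)
                trial = crossover(pop[i], donor, config.CR, rng)
                np.clip(trial, lo, hi, out=trial)
                Jt = float(objective(trial))
                evaluations += 1
                if not np.isfinite(Jt):
                    raise RuntimeError(f"non-finite objective {Jt} at vector {trial}")
                if Jt <= J[i]:
                    pop[i] = trial
                    J[i] = Jt
                    if Jt <= best_J:
                        best_J = Jt
                        best_x = trial.copy()
            history[g] = best_J
            if log_fh is not None:
                json.dump({"gen": g, "best_J": best_J,
                           "best_vector": best_x.tolist(),
                           "seed": config.seed}, log_fh)
                log_fh.write("\n")
    finally:
        if log_fh is not None:
            log_fh.close()

    return OptimizationResult(best_vector=best_x, best_objective=best_J,
                              history=history, evaluations=evaluations,
                              seed=config.seed)


def _check_finite(J: np.ndarray, pop: np.ndarray) -> None:
    bad = np.flatnonzero(~np.isfinite(J))
    if bad.size:
        raise RuntimeError(f"non-finite objective {J[bad[0]]} at vector {pop[bad[0]]}")
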