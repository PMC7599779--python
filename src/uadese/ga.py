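"""Real-coded genetic algorithm over box bounds, plus a quadratic oracle.

The GA maximizes a black-box objective on a box by internally minimizing
its negation with the operator pipeline common to MATLAB-style toolboxes:
rank-based fitness scaling, stochastic-uniform selection, elite carry-over,
scattered (uniform-mask) crossover, and Gaussian mutation whose scale
shrinks linearly over the generations.  Offspring are clipped to the
bounds.  One seeded generator owns all randomness, so identical seed and
configuration reproduce the result bit for bit.

For quadratic objectives the stationary point is available in closed form
(solve grad Y = 0, classify by the Hessian); it serves as the analytic
cross-check for the GA throughout the package.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .rsm import QuadraticModel

__all__ = [
    "GAConfig",
    "GAResult",
    "ga_maximize",
    "stationary_point",
    "round_to_practice",
]


@dataclass
class GAConfig:
    """Operator settings and bounds for one GA run.

    Defaults: population 50, 200 generations, crossover fraction 0.8,
    2 elites, initial mutation scale 1.0 shrinking linearly to
    ``mutation_shrink`` x scale by the final generation.  These converge far
    beyond the needed tolerance on a 4-variable quadratic.
    """

    bounds: list[tuple[float, float]] = field(
        default_factory=lambda: [(-1.0, 1.0)] * 4
    )
    population_size: int = 50
    max_generations: int = 200
    crossover_fraction: float = 0.8
    elite_count: int = 2
    mutation_scale: float = 1.0
    mutation_shrink: float = 1.0  # fraction of the scale removed by the last generation
    seed: int = 0
    # optional early stop; off by default so the mutation-shrink schedule
    # always runs to completion (late, small mutations do the refinement)
    stall_generations: Optional[int] = None
    stall_tolerance: float = 1e-8

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if not 0 <= self.crossover_fraction <= 1:
            raise ValueError("crossover_fraction must be in [0, 1]")
        if not 0 <= self.elite_count < self.population_size:
            raise ValueError("elite_count must be in [0, population_size)")
        for lo, hi in self.bounds:
            if lo > hi:
                raise ValueError(f"lower bound {lo} exceeds upper bound {hi}")

    @property
    def n_vars(self) -> int:
        return len(self.bounds)

    def to_dict(self) -> dict:
        return {
            "bounds": [list(b) for b in self.bounds],
            "population_size": self.population_size,
            "max_generations": self.max_generations,
            "crossover_fraction": self.crossover_fraction,
            "elite_count": self.elite_count,
            "mutation_scale": self.mutation_scale,
            "mutation_shrink": self.mutation_shrink,
            "seed": self.seed,
            "stall_generations": self.stall_generations,
            "stall_tolerance": self.stall_tolerance,
        }


@dataclass
class GAResult:
    best_point: np.ndarray
    best_fitness: float
    history_best: np.ndarray  # per-generation best objective value
    history_mean: np.ndarray
    generations_run: int
    config: GAConfig
    best_point_natural: Optional[np.ndarray] = None

    def to_dict(self) -> dict:
        d = {
            "best_point": self.best_point.tolist(),
            "best_fitness": self.best_fitness,
            "history_best": self.history_best.tolist(),
            "history_mean": self.history_mean.tolist(),
            "generations_run": self.generations_run,
            "config": self.config.to_dict(),
        }
        if self.best_point_natural is not None:
            d["best_point_natural"] = self.best_point_natural.tolist()
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _rank_scaled_weights(neg_scores: np.ndarray) -> np.ndarray:
    """Rank scaling: selection weight proportional to 1/sqrt(rank).

    Ranks depend only on score order, so the selection pressure is
    insensitive to the objective's absolute magnitude.
    """
    order = np.argsort(neg_scores)  # ascending: best (lowest negated) first
    ranks = np.empty_like(order)
    ranks[order] = np.arange(1, len(neg_scores) + 1)
    w = 1.0 / np.sqrt(ranks)
    return w / w.sum()


def _stochastic_uniform_select(weights: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    """Stochastic-uniform (SUS) sampling: one random phase, n equally spaced pointers."""
    cum = np.cumsum(weights)
    step = 1.0 / n
    pointers = (rng.random() * step + step * np.arange(n)) % 1.0
    return np.searchsorted(cum, pointers, side="right").clip(max=len(weights) - 1)


def ga_maximize(
    objective: Callable[[np.ndarray], float],
    config: GAConfig,
) -> GAResult:
    """Maximize ``objective`` over ``config.bounds`` with the real-coded GA.

    The objective is negated internally and minimized; the reported
    ``best_fitness`` is the (positive) objective at the best point.  With
    ``elite_count >= 1`` the per-generation best is monotone non-decreasing.
    Degenerate bounds (lower == upper) pin that variable with a warning.
    """
    lo = np.array([b[0] for b in config.bounds], dtype=float)
    hi = np.array([b[1] for b in config.bounds], dtype=float)
    if not (np.all(np.isfinite(lo)) and np.all(np.isfinite(hi))):
        raise ValueError("bounds must be finite")
    degenerate = lo == hi
    if degenerate.any():
        warnings.warn(
            f"degenerate bounds for variables {np.where(degenerate)[0].tolist()}; "
            "those variables are fixed",
            UserWarning,
            stacklevel=2,
        )

    rng = np.random.default_rng(config.seed)
    n_pop, n_var = config.population_size, config.n_vars

    def evaluate(pop: np.ndarray) -> np.ndarray:
        vals = np.empty(len(pop))
        for idx, x in enumerate(pop):
            v = float(objective(x))
            if not np.isfinite(v):
                raise ValueError(f"objective returned a non-finite value at {x.tolist()}")
            vals[idx] = -v  # internal minimization of the negated objective
        return vals

    pop = lo + (hi - lo) * rng.random((n_pop, n_var))
    neg = evaluate(pop)

    hist_best: list[float] = []
    hist_mean: list[float] = []
    stall = 0
    gens_run = 0

    n_elite = config.elite_count
    n_xover = int(round(config.crossover_fraction * (n_pop - n_elite)))
    n_mut = n_pop - n_elite - n_xover

    for gen in range(config.max_generations):
        gens_run = gen + 1
        order = np.argsort(neg)
        best_now = -neg[order[0]]
        hist_best.append(best_now)
        hist_mean.append(float(-neg.mean()))

        if gen > 0 and hist_best[-1] - hist_best[-2] <= config.stall_tolerance:
            stall += 1
        else:
            stall = 0
        if config.stall_generations is not None and stall >= config.stall_generations:
            break
        if gen == config.max_generations - 1:
            break

        weights = _rank_scaled_weights(neg)
        frac = gen / max(config.max_generations - 1, 1)
        scale = config.mutation_scale * (1 - config.mutation_shrink * frac)

        children = np.empty((n_pop, n_var))
        children[:n_elite] = pop[order[:n_elite]]

        # scattered crossover: each gene drawn from either parent uniformly
        if n_xover > 0:
            p1 = pop[_stochastic_uniform_select(weights, n_xover, rng)]
            p2 = pop[_stochastic_uniform_select(weights, n_xover, rng)]
            mask = rng.random((n_xover, n_var)) < 0.5
            children[n_elite : n_elite + n_xover] = np.where(mask, p1, p2)

        # Gaussian mutation with per-generation shrinking scale
        if n_mut > 0:
            parents = pop[_stochastic_uniform_select(weights, n_mut, rng)]
            noise = rng.normal(0.0, 1.0, (n_mut, n_var)) * scale * (hi - lo) / 2
            children[n_elite + n_xover :] = parents + noise

        pop = np.clip(children, lo, hi)
        pop[:, degenerate] = lo[degenerate]
        neg = evaluate(pop)

    order = np.argsort(neg)
    best_point = pop[order[0]].copy()
    return GAResult(
        best_point=best_point,
        best_fitness=float(objective(best_point)),
        history_best=np.array(hist_best),
        history_mean=np.array(hist_mean),
        generations_run=gens_run,
        config=config,
    )


def stationary_point(
    model: QuadraticModel,
    clamp_box: tuple[float, float] = (-1.0, 1.0),
) -> tuple[np.ndarray, str, float]:
    """Closed-form stationary point of a fitted quadratic surface.

    Writes the surface as Y = c + b.x + x'Ax, solves 2Ax = -b, and
    classifies the point by the Hessian eigenvalues (all negative:
    maximum; all positive: minimum; mixed: saddle).  Coordinates outside
    the coded box are clamped with a warning — the optimum then sits on
    the boundary and the GA, not this oracle, is authoritative.
    """
    c, b, A = model.quadratic_form()
    if np.allclose(A, 0):
        raise ValueError("model has no nonzero quadratic term; no stationary point")
    H = 2 * A  # Hessian
    if abs(np.linalg.det(H)) < 1e-12:
        raise np.linalg.LinAlgError("singular Hessian: no isolated stationary point")
    x = np.linalg.solve(H, -b)
    eig = np.linalg.eigvalsh(H)
    if np.all(eig < 0):
        nature = "maximum"
    elif np.all(eig > 0):
        nature = "minimum"
    else:
        nature = "saddle"
    lo, hi = clamp_box
    if np.any(x < lo) or np.any(x > hi):
        warnings.warn(
            f"stationary point {x.tolist()} lies outside the coded box "
            f"[{lo}, {hi}]; clamping",
            UserWarning,
            stacklevel=2,
        )
        x = np.clip(x, lo, hi)
    value = c + b @ x + x @ A @ x
    return x, nature, float(value)


def round_to_practice(
    natural_point: Sequence[float],
    grains: Sequence[float],
) -> np.ndarray:
    """Round a natural-unit operating point to practical setting grains.

    E.g. a water content of 29.24% with grain 1 becomes 29%; an ultrasonic
    power of 209.6 W with grain 10 becomes 210 W.
    """
    pt = np.asarray(natural_point, dtype=float)
    gr = np.asarray(grains, dtype=float)
    if pt.shape != gr.shape:
        raise ValueError("natural_point and grains must have the same length")
    if np.any(gr <= 0):
        raise ValueError("grains must be positive")
    return np.round(pt / gr) * gr
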