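"""Teaching-learning-based optimization (TLBO).

A population metaheuristic without algorithm-specific tuning parameters
beyond population size and iteration count.  Each learner is a candidate
solution ("scores" over the decision variables, the "courses").  Every
iteration runs two phases:

teacher phase   Z_new = Z_old + r (Z_teacher - T_F M), with r ~ U[0,1] per
                learner, teaching factor T_F drawn equiprobably from {1, 2},
                M the population mean and Z_teacher the current best;
learner phase   each learner pairs with a distinct random partner and moves
                toward the better of the pair: Z_new = Z_old + r (Z_better -
                Z_worse).

Moves are clipped to the box bounds and accepted greedily (only if the
objective improves), so the best-so-far value is non-increasing.  The whole
search is deterministic for a fixed seed.

Used here to solve the maximum-entropy moment equations by minimizing the
squared moment residual over the multipliers, but the interface is a plain
black-box minimizer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError


@dataclass
class Learner:
    """One candidate solution with its cached objective value."""

    scores: np.ndarray
    value: float


@dataclass
class Population:
    """Learners plus the shared per-dimension box bounds."""

    learners: list
    bounds: np.ndarray  # (dim, 2)

    def __post_init__(self):
        if len(self.learners) < 2:
            raise ConfigurationError("population needs at least two learners")

    def best(self) -> Learner:
        return min(self.learners, key=lambda l: l.value)

    def mean_scores(self) -> np.ndarray:
        return np.mean([l.scores for l in self.learners], axis=0)


@dataclass(frozen=True)
class TLBOConfig:
    """Search configuration; bounds is a (dim, 2) array-like of [lo, hi]."""

    bounds: object
    pop_size: int = 30
    max_iters: int = 200
    seed: int = 0
    tolerance: float | None = None

    def __post_init__(self):
        if self.pop_size < 2:
            raise ConfigurationError("pop_size must be >= 2")
        if self.max_iters < 0:
            raise ConfigurationError("max_iters must be >= 0")
        b = np.atleast_2d(np.asarray(self.bounds, dtype=float))
        if b.shape[1] != 2 or np.any(b[:, 0] >= b[:, 1]) or not np.all(np.isfinite(b)):
            raise ConfigurationError("bounds must be finite [lo, hi] per dimension")
        object.__setattr__(self, "bounds", b)


def _clip(x, bounds):
    return np.clip(x, bounds[:, 0], bounds[:, 1])


def teacher_phase(pop: Population, objective, rng: np.random.Generator) -> Population:
    """One teacher phase, in place; returns the population for chaining."""
    teacher = pop.best().scores.copy()
    mean = pop.mean_scores()
    for learner in pop.learners:
        r = rng.uniform()
        t_f = rng.integers(1, 3)  # teaching factor, 1 or 2 equiprobably
        proposal = _clip(learner.scores + r * (teacher - t_f * mean), pop.bounds)
        value = float(objective(proposal))
        if value < learner.value:
            learner.scores = proposal
            learner.value = value
    return pop


def learner_phase(pop: Population, objective, rng: np.random.Generator) -> Population:
    """One learner phase: pairwise interaction with a random distinct partner."""
    n = len(pop.learners)
    if n < 2:
        raise ConfigurationError("learner phase needs at least two learners")
    for i, learner in enumerate(pop.learners):
        j = int(rng.integers(0, n - 1))
        if j >= i:
            j += 1
        partner = pop.learners[j]
        if partner.value < learner.value:
            better, worse = partner.scores, learner.scores
        else:
            better, worse = learner.scores, partner.scores
        r = rng.uniform()
        proposal = _clip(learner.scores + r * (better - worse), pop.bounds)
        value = float(objective(proposal))
        if value < learner.value:
            learner.scores = proposal
            learner.value = value
    return pop


def optimize(objective, config: TLBOConfig):
    """Minimize a black-box objective by alternating TLBO phases.

    Returns (best_learner, best_value, trace) where trace[k] is the best
    objective value after iteration k (trace[0] is the initial population's
    best).  Stops early once the best value falls below config.tolerance.
    """
    rng = np.random.default_rng(config.seed)
    bounds = config.bounds
    dim = bounds.shape[0]
    init = rng.uniform(bounds[:, 0], bounds[:, 1], size=(config.pop_size, dim))
    learners = [Learner(row.copy(), float(objective(row))) for row in init]
    pop = Population(learners, bounds)

    trace = [pop.best().value]
    for _ in range(config.max_iters):
        teacher_phase(pop, objective, rng)
        learner_phase(pop, objective, rng)
        trace.append(pop.best().value)
        if config.tolerance is not None and trace[-1] <= config.tolerance:
            break
    best = pop.best()
    return Learner(best.scores.copy(), best.value), best.value, np.asarray(trace)


def solve_lambda_tlbo(constraints, support, config: TLBOConfig | None = None):
    """Solve the ME moment equations with TLBO on the squared residual.

    The objective over the free multipliers lambda_1..lambda_N is
    sum_i (G_i(lambda) - mu_i)^2 with the density normalized through the
    log-partition (so the normalization equation holds identically and the
    search space stays N-dimensional).  Returns a MaxEntDensity like the
    Newton solver; the two agree because the ME dual is convex with a
    unique optimum.
    """
    from .maxent_core import (
        LambdaVector,
        MaxEntDensity,
        _log_partition_stats,
        quadrature_nodes,
    )

    nodes, weights = quadrature_nodes(*support)
    basis = constraints.basis
    mu_free = constraints.targets[1:]
    n_free = len(basis) - 1

    def objective(lam_free):
        _, ephi, _ = _log_partition_stats(lam_free, basis, nodes, weights)
        resid = ephi - mu_free
        return float(resid @ resid)

    if config is None:
        config = TLBOConfig(bounds=[[-10.0, 10.0]] * n_free, pop_size=30,
                            max_iters=600, seed=0, tolerance=1e-16)
    best, _, trace = optimize(objective, config)
    lam_free = best.scores
    log_z, _, _ = _log_partition_stats(lam_free, basis, nodes, weights)
    density = MaxEntDensity(tuple(support),
                            LambdaVector(np.r_[log_z, lam_free]), basis)
    return density, trace


def trace_to_csv(trace, path) -> None:
    """Write the per-iteration best-value trace as (iteration, best_value)."""
    arr = np.column_stack([np.arange(len(trace)), np.asarray(trace, dtype=float)])
    np.savetxt(path, arr, delimiter=",", header="iteration,best_value",
               comments="", fmt=["%d", "%.17g"])
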