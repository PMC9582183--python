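"""Maximum entropy with soft moment constraints (the MET/REG solver).

Instead of forcing the moment conditions to hold exactly, the density is
estimated on a finite grid by minimizing

    J(p) = || mu - E_p[phi] ||^2  +  w * KL(p, g)

over the probability simplex, where g is a reference (empirical) density —
here a kernel-density estimate of the samples — and w > 0 the regularization
weight trading moment fidelity against closeness to the reference.  J is
strictly convex, so the minimizer is unique.

Two independent routes to the solution are provided:

solve_primal    entropic mirror descent directly on the simplex;
solve_dual      the smooth low-dimensional Fenchel dual

    min_eta  ln sum_j g_j exp(-(Phi' eta)_j) + eta' mu + (w/4) ||eta||^2,

with primal recovery p_j = g_j exp(-(Phi' eta)_j) / Z(eta).  As w -> 0 the
dual vector eta converges to the equality-constrained maximum-entropy
multipliers of :mod:`metaif.maxent_core` (with respect to the reference
measure), and as w -> infinity p -> g.

The four-step pipeline (moments -> KDE reference -> dual solve -> projection
onto a parametric family) is exposed as :func:`met_reg_pipeline`.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize as sp_optimize
from scipy import special, stats

from .errors import ConvergenceError, DomainError
from .maxent_core import (
    MomentConstraintSet,
    ParametricFamily,
    _grid_weights,
    basis_const,
    compute_moments,
    erlang_projection,
)

MASS_TOL = 1e-10
REFERENCE_FLOOR = 1e-300
DEFAULT_REG_WEIGHT = 0.1
KDE_GRID_SIZE = 512


# ---------------------------------------------------------------------------
# grid densities and problems
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GridDensity:
    """Discrete probability masses g_1..g_M on strictly increasing support points."""

    grid: np.ndarray
    masses: np.ndarray

    def __post_init__(self):
        x = np.asarray(self.grid, dtype=float)
        m = np.asarray(self.masses, dtype=float)
        if x.ndim != 1 or x.shape != m.shape:
            raise DomainError("grid and masses must be aligned 1-d arrays")
        if np.any(np.diff(x) <= 0):
            raise DomainError("grid must be strictly increasing")
        if np.any(m < 0):
            raise DomainError("masses must be non-negative")
        if abs(m.sum() - 1.0) > MASS_TOL:
            raise DomainError(f"masses sum to {m.sum()!r}, not 1")
        object.__setattr__(self, "grid", x)
        object.__setattr__(self, "masses", m)

    @classmethod
    def from_pdf(cls, grid, pdf_values) -> "GridDensity":
        """Build masses from density values via trapezoid quadrature weights."""
        x = np.asarray(grid, dtype=float)
        p = np.asarray(pdf_values, dtype=float)
        m = p * _grid_weights(x)
        total = m.sum()
        if total <= 0:
            raise DomainError("density values carry no mass")
        return cls(x, m / total)

    def pdf_values(self) -> np.ndarray:
        """Masses converted back to density values on the grid."""
        return self.masses / _grid_weights(self.grid)

    def expectation(self, fn) -> float:
        return float(self.masses @ fn(self.grid))

    def mean(self) -> float:
        return float(self.masses @ self.grid)


@dataclass(frozen=True)
class RegularizedProblem:
    """Soft-constrained ME problem: constraint rows, targets, reference, weight."""

    constraint_matrix: np.ndarray  # (N+1) x M, first row all ones
    targets: np.ndarray            # mu_0..mu_N with mu_0 = 1
    reference: GridDensity
    reg_weight: float = DEFAULT_REG_WEIGHT

    def __post_init__(self):
        phi = np.atleast_2d(np.asarray(self.constraint_matrix, dtype=float))
        mu = np.asarray(self.targets, dtype=float)
        m = self.reference.masses.size
        if phi.shape[1] != m:
            raise DomainError("constraint matrix columns must match the grid")
        if phi.shape[0] != mu.size:
            raise DomainError("one target per constraint row required")
        if not np.allclose(phi[0], 1.0) or not np.isclose(mu[0], 1.0):
            raise DomainError("first row must be the normalization constraint")
        if self.reg_weight <= 0:
            raise DomainError("reg_weight must be positive")
        if np.any(self.reference.masses <= 0):
            raise DomainError(
                "reference must be strictly positive on its grid (KL undefined)"
            )
        object.__setattr__(self, "constraint_matrix", phi)
        object.__setattr__(self, "targets", mu)

    @classmethod
    def from_constraints(cls, constraints: MomentConstraintSet,
                         reference: GridDensity,
                         reg_weight: float = DEFAULT_REG_WEIGHT) -> "RegularizedProblem":
        phi = np.stack([b(reference.grid) for b in constraints.basis])
        return cls(phi, constraints.targets, reference, reg_weight)

    def objective(self, masses: np.ndarray) -> float:
        """Primal objective J(p) = ||mu - Phi p||^2 + w KL(p, g)."""
        misfit = self.targets[1:] - self.constraint_matrix[1:] @ masses
        g = self.reference.masses
        pos = masses > 0
        kl = float(np.sum(masses[pos] * np.log(masses[pos] / g[pos])))
        return float(misfit @ misfit) + self.reg_weight * kl


@dataclass(frozen=True)
class DualSolution:
    """Dual vector with the recovered density and diagnostics."""

    lambda_hat: np.ndarray      # free multipliers eta_1..eta_N
    p_hat: GridDensity
    log_partition: float
    primal_objective: float

    def moment_residual(self, problem: RegularizedProblem) -> float:
        mis = problem.targets[1:] - problem.constraint_matrix[1:] @ self.p_hat.masses
        return float(np.linalg.norm(mis))


# ---------------------------------------------------------------------------
# solvers
# ---------------------------------------------------------------------------

def log_partition(lam, problem: RegularizedProblem) -> float:
    """ln Z(lam) = ln sum_j g_j exp(s_j) with s = -(Phi_free)' lam.

    Computed with max-subtraction so it is total on finite input.  For a
    product-form reference this is the sum of per-coordinate logarithmic
    Laplace transforms; on a one-dimensional grid it is the plain
    log-sum-exp against the reference measure.
    """
    lam = np.atleast_1d(np.asarray(lam, dtype=float))
    s = -(problem.constraint_matrix[1:].T @ lam)
    return log_sum_exp_measure(s, problem.reference.masses)


def log_sum_exp_measure(s, g) -> float:
    """Overflow-safe ln sum_j g_j e^{s_j} for a non-negative measure g."""
    s = np.asarray(s, dtype=float)
    g = np.asarray(g, dtype=float)
    m = np.max(s)
    return float(m + np.log(np.sum(g * np.exp(s - m))))


def _dual_density(lam, problem):
    """Masses g_j e^{s_j} / Z and ln Z for s = -(Phi_free)' lam."""
    s = -(problem.constraint_matrix[1:].T @ lam)
    m = np.max(s)
    unnorm = problem.reference.masses * np.exp(s - m)
    z = unnorm.sum()
    return unnorm / z, float(m + np.log(z))


def solve_dual(problem: RegularizedProblem, tol: float = 1e-11,
               max_iter: int = 300) -> DualSolution:
    """Minimize the smooth convex dual by damped Newton.

    F(eta) = ln Z(eta) + eta' mu + (w/4)||eta||^2, with gradient
    mu - E_p[phi] + (w/2) eta and Hessian Cov_p(phi) + (w/2) I (positive
    definite, so plain Newton with backtracking converges).
    """
    phi = problem.constraint_matrix[1:]
    mu = problem.targets[1:]
    w = problem.reg_weight
    lam = np.zeros(phi.shape[0])

    def value(lf):
        return log_partition(lf, problem) + lf @ mu + 0.25 * w * (lf @ lf)

    f_cur = value(lam)
    grad_norm = np.inf
    for _ in range(max_iter):
        p, log_z = _dual_density(lam, problem)
        ephi = phi @ p
        grad = mu - ephi + 0.5 * w * lam
        grad_norm = float(np.max(np.abs(grad)))
        if grad_norm < tol:
            break
        centered = phi - ephi[:, None]
        hess = (centered * p) @ centered.T + 0.5 * w * np.eye(phi.shape[0])
        step = np.linalg.solve(hess, grad)
        t = 1.0
        for _ in range(60):
            trial = lam - t * step
            f_new = value(trial)
            if f_new < f_cur - 1e-15:
                lam, f_cur = trial, f_new
                break
            t *= 0.5
        else:
            break
    else:
        raise ConvergenceError(
            f"dual solver stalled at gradient norm {grad_norm:.3e}",
            residual=grad_norm,
        )
    p, log_z = _dual_density(lam, problem)
    density = GridDensity(problem.reference.grid, p / p.sum())
    return DualSolution(lam, density, log_z, problem.objective(density.masses))


def solve_primal(problem: RegularizedProblem, tol: float = 1e-9,
                 max_iter: int = 200_000) -> GridDensity:
    """Minimize J(p) on the simplex by entropic mirror descent.

    Multiplicative updates p <- p exp(-t grad J) / norm with backtracking on
    J; the iteration stops when the KKT residual max_j |grad_j - <p, grad>|
    falls below ``tol`` (the optimum is interior because of the KL barrier,
    so the stationarity condition is a constant gradient).
    """
    phi = problem.constraint_matrix[1:]
    mu = problem.targets[1:]
    g = problem.reference.masses
    w = problem.reg_weight

    p = g.copy()

    def grad_of(pv):
        misfit = mu - phi @ pv
        return -2.0 * (phi.T @ misfit) + w * (np.log(pv / g) + 1.0)

    j_cur = problem.objective(p)
    step = 1.0 / max(w, 1.0)
    residual = np.inf
    for _ in range(max_iter):
        grad = grad_of(p)
        residual = float(np.max(np.abs(grad - p @ grad)))
        if residual < tol:
            return GridDensity(problem.reference.grid, p)
        accepted = False
        shifted = grad - np.min(grad)  # shift only changes the normalizer
        for _ in range(80):
            trial = p * np.exp(-step * shifted)
            trial = np.maximum(trial, REFERENCE_FLOOR)
            trial /= trial.sum()
            j_new = problem.objective(trial)
            if j_new < j_cur - 1e-16:
                p, j_cur = trial, j_new
                step *= 1.25
                accepted = True
                break
            step *= 0.5
        if not accepted:
            break
    if residual < 1e-6:  # stalled by floating point but essentially converged
        return GridDensity(problem.reference.grid, p)
    raise ConvergenceError(
        f"mirror descent stalled at KKT residual {residual:.3e}",
        residual=residual,
    )


# ---------------------------------------------------------------------------
# the four-step MET/REG pipeline
# ---------------------------------------------------------------------------

def kde_reference_grid(samples, grid_size: int = KDE_GRID_SIZE) -> GridDensity:
    """Gaussian KDE (Silverman bandwidth) of positive samples on a fixed grid.

    The grid spans [min/2, 2 max] of the samples with ``grid_size`` points;
    the density is floored at a tiny positive value so the KL term stays
    defined everywhere.
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 2 or np.std(x) == 0:
        raise DomainError("KDE reference needs >= 2 samples with variation")
    if np.any(x <= 0):
        raise DomainError("reference construction expects positive samples")
    kde = stats.gaussian_kde(x, bw_method="silverman")
    grid = np.linspace(x.min() / 2.0, 2.0 * x.max(), grid_size)
    pdf = np.maximum(kde(grid), REFERENCE_FLOOR)
    return GridDensity.from_pdf(grid, pdf)


@dataclass(frozen=True)
class MetRegResult:
    """Projected parametric family plus the raw dual solution."""

    family: ParametricFamily
    dual: DualSolution
    reg_weight: float
    moment_residual: float
    kl_to_reference: float

    def to_json(self) -> str:
        return json.dumps({
            "family": self.family.family,
            "alpha": self.family.alpha,
            "beta": self.family.beta,
            "reg_weight": self.reg_weight,
            "moment_residual": self.moment_residual,
            "kl_to_reference": self.kl_to_reference,
            "log_partition": self.dual.log_partition,
        })


def _project_family(p_hat: GridDensity, family_target: str) -> ParametricFamily:
    """Match the grid density's E[X] and E[ln X] within the requested family."""
    ex = p_hat.mean()
    elog = p_hat.expectation(np.log)
    gap = math.log(ex) - elog  # >= 0 by Jensen
    if family_target in ("gamma", "erlang"):
        if gap <= 0:
            alpha = 1e6  # degenerate: essentially a point mass
        else:
            alpha = _solve_gamma_shape(gap)
        fam = ParametricFamily("gamma", alpha, ex / alpha)
        return erlang_projection(fam) if family_target == "erlang" else fam
    if family_target == "weibull":
        alpha = _solve_weibull_shape(gap)
        beta = ex / special.gamma(1.0 + 1.0 / alpha)
        return ParametricFamily("weibull", alpha, beta)
    if family_target == "exponential":
        return ParametricFamily("exponential", 1.0, ex)
    raise DomainError(f"unknown family target {family_target!r}")


def _solve_gamma_shape(gap: float) -> float:
    """Solve ln(alpha) - psi(alpha) = gap for the gamma shape."""
    f = lambda a: math.log(a) - special.digamma(a) - gap
    lo, hi = 1e-8, 1e8
    return float(sp_optimize.brentq(f, lo, hi, xtol=1e-12))


def _solve_weibull_shape(gap: float) -> float:
    """Solve ln Gamma(1 + 1/a) + euler_gamma / a = gap for the Weibull shape."""
    f = lambda a: math.lgamma(1.0 + 1.0 / a) + np.euler_gamma / a - gap
    lo, hi = 1e-2, 1e6
    if f(lo) * f(hi) > 0:  # gap outside the attainable range: clamp
        return lo if abs(f(lo)) < abs(f(hi)) else hi
    return float(sp_optimize.brentq(f, lo, hi, xtol=1e-12))


def met_reg_pipeline(samples, basis, reg_weight: float = DEFAULT_REG_WEIGHT,
                     family_target: str = "gamma",
                     grid_size: int = KDE_GRID_SIZE) -> MetRegResult:
    """Run the full soft-constrained ME estimation on raw samples.

    (1) empirical moments of the basis functions; (2) kernel-density
    reference on a positive grid; (3) dual solve of the regularized
    problem; (4) projection of the solution onto the requested parametric
    family by matching E[X] and E[ln X].
    """
    x = np.asarray(samples, dtype=float)
    x = x[x > 0]
    constraints = compute_moments(x, basis)
    reference = kde_reference_grid(x, grid_size)
    problem = RegularizedProblem.from_constraints(constraints, reference, reg_weight)
    dual = solve_dual(problem)
    fam = _project_family(dual.p_hat, family_target)
    kl = float(np.sum(dual.p_hat.masses *
                      np.log(dual.p_hat.masses / reference.masses)))
    return MetRegResult(fam, dual, reg_weight, dual.moment_residual(problem), kl)


def choose_reg_weight(constraints: MomentConstraintSet, reference: GridDensity,
                      residual_tol: float,
                      candidates=(10.0, 1.0, 0.1, 0.01, 1e-3, 1e-4)) -> float:
    """Discrepancy principle: largest weight with moment residual below tol."""
    for w in sorted(candidates, reverse=True):
        problem = RegularizedProblem.from_constraints(constraints, reference, w)
        sol = solve_dual(problem)
        if sol.moment_residual(problem) < residual_tol:
            return w
    return min(candidates)
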