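"""Maximum-entropy density estimation under moment constraints.

Among all densities p on a support S satisfying E_p[phi_i(X)] = mu_i for a
small set of known basis functions phi_i (with phi_0 = 1, mu_0 = 1), the
density maximizing Shannon's differential entropy H(p) = -int p ln p has the
exponential-family form

    p(x) = exp(- sum_i lambda_i phi_i(x)),    x in S,

where the Lagrange multipliers lambda_i are fixed by the moment conditions
G_i(lambda) = int phi_i p dx = mu_i.  lambda_0 is the log-partition
ln int exp(-sum_{i>=1} lambda_i phi_i) dx, so normalization always holds.

For the bases used in AIF modelling the multipliers correspond one-to-one to
classical parametric families:

    {1, x}           -> exponential(beta):  lambda_x = 1/beta
    {1, ln x, x}     -> gamma(alpha, beta): lambda_log = -(alpha-1),
                                            lambda_x = 1/beta
    {1, ln x, x^a}   -> Weibull(alpha=a, beta): lambda_log = -(alpha-1),
                                            lambda_pow = beta^{-alpha}
    gamma with integer shape -> Erlang.

The module also provides the three classical Weibull baseline estimators
(method of moments, MLE, frequency-weighted MLE) used as comparison fits.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
from scipy import special, stats

from .errors import (
    ConvergenceError,
    DegenerateDataError,
    DomainError,
    UnsupportedFamilyError,
)

MOMENT_TOL = 1e-10         # Newton stopping tolerance on max |G_i - mu_i|
NORMALIZATION_TOL = 1e-6   # densities must integrate to 1 within this


# ---------------------------------------------------------------------------
# quadrature on (0, U]-type supports
# ---------------------------------------------------------------------------

def quadrature_nodes(lo: float, hi: float, order: int = 16,
                     panels_per_decade: int = 6, min_panels: int = 32):
    """Composite Gauss-Legendre nodes/weights on geometric panels of (lo, hi].

    Geometric spacing resolves integrands with ln(x) or x^{a-1} behaviour
    near the lower endpoint, which arise for every basis used here.
    """
    if not (0 < lo < hi):
        raise DomainError("support must satisfy 0 < lo < hi")
    decades = math.log10(hi / lo)
    n_panels = max(min_panels, int(math.ceil(panels_per_decade * decades)))
    edges = np.geomspace(lo, hi, n_panels + 1)
    gl_x, gl_w = np.polynomial.legendre.leggauss(order)
    half = 0.5 * (edges[1:] - edges[:-1])
    mid = 0.5 * (edges[1:] + edges[:-1])
    nodes = (mid[:, None] + half[:, None] * gl_x[None, :]).ravel()
    weights = (half[:, None] * gl_w[None, :]).ravel()
    return nodes, weights


# ---------------------------------------------------------------------------
# basis functions and constraint sets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BasisFunction:
    """One constraint function phi(x): const, identity, log, xlogx or power(p)."""

    tag: str
    exponent: float | None = None

    _TAGS = ("const", "identity", "log", "xlogx", "power")

    def __post_init__(self):
        if self.tag not in self._TAGS:
            raise DomainError(f"unknown basis tag {self.tag!r}")
        if self.tag == "power":
            if self.exponent is None or self.exponent <= 0:
                raise DomainError("power basis needs a positive exponent")
        elif self.exponent is not None:
            raise DomainError(f"{self.tag} basis takes no exponent")

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        if self.tag == "const":
            return np.ones_like(x)
        if self.tag == "identity":
            return x
        if self.tag == "log":
            return np.log(x)
        if self.tag == "xlogx":
            return x * np.log(x)
        return np.power(x, self.exponent)

    @property
    def needs_positive(self) -> bool:
        return self.tag in ("log", "xlogx")

    def label(self) -> str:
        return f"power({self.exponent:g})" if self.tag == "power" else self.tag


def basis_const() -> BasisFunction:
    return BasisFunction("const")


def basis_identity() -> BasisFunction:
    return BasisFunction("identity")


def basis_log() -> BasisFunction:
    return BasisFunction("log")


def basis_xlogx() -> BasisFunction:
    return BasisFunction("xlogx")


def basis_power(p: float) -> BasisFunction:
    return BasisFunction("power", float(p))


@dataclass(frozen=True)
class MomentConstraintSet:
    """Basis functions phi_0..phi_N (phi_0 = const) with targets mu_0..mu_N."""

    basis: tuple
    targets: np.ndarray

    def __post_init__(self):
        basis = tuple(self.basis)
        mu = np.asarray(self.targets, dtype=float)
        if len(basis) != mu.size:
            raise DomainError("basis and targets differ in length")
        if len(basis) < 2:
            raise DomainError("need at least one constraint beyond normalization")
        if basis[0].tag != "const":
            raise DomainError("first basis function must be const")
        if not np.isclose(mu[0], 1.0):
            raise DomainError("normalization target mu_0 must be 1")
        if len(set(basis)) != len(basis):
            raise DomainError("basis functions must be pairwise distinct")
        object.__setattr__(self, "basis", basis)
        object.__setattr__(self, "targets", mu)

    @property
    def n_constraints(self) -> int:
        return len(self.basis)


@dataclass(frozen=True)
class LambdaVector:
    """Multipliers lambda_0..lambda_N; lambda_0 absorbs the log-partition."""

    lambdas: np.ndarray

    def __post_init__(self):
        lam = np.asarray(self.lambdas, dtype=float)
        if lam.ndim != 1 or lam.size < 2:
            raise DomainError("lambda vector must have length >= 2")
        object.__setattr__(self, "lambdas", lam)


@dataclass(frozen=True)
class MaxEntDensity:
    """Density exp(-sum lambda_i phi_i(x)) on a support interval (lo, hi]."""

    support: tuple
    lam: LambdaVector
    basis: tuple

    def __post_init__(self):
        lo, hi = self.support
        if not (0 < lo < hi):
            raise DomainError("support must lie in (0, inf) with lo < hi")
        if len(self.basis) != self.lam.lambdas.size:
            raise DomainError("basis and lambda vector differ in length")
        object.__setattr__(self, "basis", tuple(self.basis))

    def __call__(self, x):
        return density_eval(self, x)

    def quadrature(self):
        return quadrature_nodes(*self.support)

    def to_json(self) -> str:
        fam = None
        try:
            f = lambda_to_family(self.lam, self.basis)
            fam = {"family": f.family, "alpha": f.alpha, "beta": f.beta}
        except UnsupportedFamilyError:
            pass
        payload = {
            "family": fam,
            "lambdas": self.lam.lambdas.tolist(),
            "support": list(self.support),
            "basis_tags": [b.label() for b in self.basis],
        }
        return json.dumps(payload)


@dataclass(frozen=True)
class ParametricFamily:
    """Exponential / Weibull / gamma / Erlang with shape alpha, scale beta."""

    family: str
    alpha: float
    beta: float

    _FAMILIES = ("exponential", "weibull", "gamma", "erlang")

    def __post_init__(self):
        if self.family not in self._FAMILIES:
            raise DomainError(f"unknown family {self.family!r}")
        if self.alpha <= 0 or self.beta <= 0:
            raise DomainError("shape and scale must be positive")
        if self.family == "erlang" and abs(self.alpha - round(self.alpha)) > 1e-12:
            raise DomainError("Erlang shape must be a positive integer")
        if self.family == "exponential" and not np.isclose(self.alpha, 1.0):
            raise DomainError("exponential family has shape fixed at 1")

    def frozen(self):
        """Scipy frozen distribution with matching parametrization."""
        if self.family == "weibull":
            return stats.weibull_min(self.alpha, scale=self.beta)
        if self.family == "exponential":
            return stats.expon(scale=self.beta)
        return stats.gamma(self.alpha, scale=self.beta)

    def pdf(self, x):
        x = np.asarray(x, dtype=float)
        out = np.zeros_like(x)
        pos = x > 0
        out[pos] = self.frozen().pdf(x[pos])
        return out

    def mean(self) -> float:
        return float(self.frozen().mean())

    def sample(self, n: int, rng) -> np.ndarray:
        return self.frozen().rvs(size=n, random_state=rng)

    def to_json(self) -> str:
        lam = family_to_lambda(self)
        basis = family_basis(self)
        return json.dumps({
            "family": self.family,
            "alpha": self.alpha,
            "beta": self.beta,
            "lambdas": lam.lambdas.tolist(),
            "basis_tags": [b.label() for b in basis],
        })


# ---------------------------------------------------------------------------
# moments
# ---------------------------------------------------------------------------

def compute_moments(samples, basis) -> MomentConstraintSet:
    """Empirical moment targets mu_i = mean of phi_i over the sample.

    The constraint expectations are plain sample averages of the basis
    functions; mu_0 = 1 by construction.  Samples must be strictly positive
    whenever the basis involves ln(x) (callers drop non-positive
    concentrations beforehand).
    """
    x = np.asarray(samples, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise DomainError("samples must be a non-empty 1-d array")
    basis = tuple(basis)
    if basis[0].tag != "const":
        basis = (basis_const(),) + basis
    if any(b.needs_positive for b in basis) and np.any(x <= 0):
        raise DomainError("log-type basis requires strictly positive samples")
    mu = np.array([1.0] + [float(np.mean(b(x))) for b in basis[1:]])
    return MomentConstraintSet(basis, mu)


# ---------------------------------------------------------------------------
# Newton solver for the multipliers
# ---------------------------------------------------------------------------

def _log_partition_stats(lam_free, basis, nodes, weights):
    """Z, E[phi], Cov(phi) of p = exp(-sum lam phi)/Z on the quadrature grid."""
    phi = np.stack([b(nodes) for b in basis[1:]])       # N x M
    s = -lam_free @ phi                                  # M
    m = np.max(s)
    e = weights * np.exp(s - m)
    z = e.sum()
    prob = e / z
    ephi = phi @ prob
    centered = phi - ephi[:, None]
    cov = (centered * prob) @ centered.T
    log_z = m + np.log(z)
    return log_z, ephi, cov


def solve_lambda_newton(constraints: MomentConstraintSet, support,
                        tol: float = MOMENT_TOL, max_iter: int = 200) -> MaxEntDensity:
    """Solve the ME moment equations by damped Newton on the convex dual.

    Minimizes D(lam) = ln Z(lam) + sum_i lam_i mu_i over the free
    multipliers (i >= 1); the gradient is mu - E_p[phi] and the Hessian the
    covariance of phi under the current density, both evaluated by
    composite Gauss-Legendre quadrature on the support.  Infeasible targets
    (no density on the support attains them) make the dual unbounded below;
    this surfaces as a ConvergenceError carrying the final moment residual.
    """
    lo, hi = support
    nodes, weights = quadrature_nodes(lo, hi)
    basis = constraints.basis
    mu_free = constraints.targets[1:]
    lam = np.zeros(len(basis) - 1)

    def dual_and_grad(lf):
        log_z, ephi, cov = _log_partition_stats(lf, basis, nodes, weights)
        return log_z + lf @ mu_free, mu_free - ephi, cov, log_z

    d_cur, grad, cov, log_z = dual_and_grad(lam)
    residual = float(np.max(np.abs(grad)))
    for _ in range(max_iter):
        if residual < tol:
            return MaxEntDensity((lo, hi), LambdaVector(np.r_[log_z, lam]), basis)
        try:
            step = np.linalg.solve(cov + 1e-14 * np.eye(cov.shape[0]), grad)
        except np.linalg.LinAlgError:
            step = grad
        # backtracking: accept on dual decrease or (near the optimum, where
        # the dual improvement is below float resolution) on residual decrease
        t = 1.0
        accepted = False
        for _ in range(60):
            trial = lam - t * step
            d_new, g_new, c_new, z_new = dual_and_grad(trial)
            r_new = float(np.max(np.abs(g_new)))
            if d_new < d_cur or r_new < residual:
                lam, d_cur, grad, cov, log_z = trial, d_new, g_new, c_new, z_new
                residual = r_new
                accepted = True
                break
            t *= 0.5
        if not accepted:
            break  # fully stalled
    if residual < 1e-8:  # meets the contract even if the last step stalled
        return MaxEntDensity((lo, hi), LambdaVector(np.r_[log_z, lam]), basis)
    raise ConvergenceError(
        f"moment equations did not converge (max residual {residual:.3e}); "
        "the targets may be infeasible on this support",
        residual=residual,
    )


def density_eval(density: MaxEntDensity, x):
    """Evaluate exp(-sum lambda_i phi_i(x)); zero outside the support."""
    x = np.asarray(x, dtype=float)
    scalar = x.ndim == 0
    x = np.atleast_1d(x)
    lo, hi = density.support
    out = np.zeros_like(x)
    inside = (x >= lo) & (x <= hi)
    if np.any(inside):
        xi = x[inside]
        s = np.zeros_like(xi)
        for lam_i, b in zip(density.lam.lambdas, density.basis):
            s -= lam_i * b(xi)
        out[inside] = np.exp(s)
    return float(out[0]) if scalar else out


# ---------------------------------------------------------------------------
# family <-> multiplier mappings
# ---------------------------------------------------------------------------

def family_basis(fam: ParametricFamily) -> tuple:
    if fam.family == "weibull":
        return (basis_const(), basis_log(), basis_power(fam.alpha))
    return (basis_const(), basis_log(), basis_identity())


def family_to_lambda(fam: ParametricFamily) -> LambdaVector:
    """Closed-form multipliers of the classical families.

    Weibull(alpha, beta):  lambda_0 = -ln(alpha / beta^alpha),
                           lambda_log = -(alpha - 1),
                           lambda_power(alpha) = beta^{-alpha}.
    Gamma(alpha, beta):    lambda_0 = ln(Gamma(alpha) beta^alpha),
                           lambda_log = -(alpha - 1), lambda_x = 1/beta.
    Erlang: gamma with (alpha-1)! for Gamma(alpha); exponential: gamma, alpha=1.
    """
    a, b = fam.alpha, fam.beta
    if fam.family == "weibull":
        lam0 = -(math.log(a) - a * math.log(b))
        return LambdaVector(np.array([lam0, -(a - 1.0), b ** (-a)]))
    if fam.family == "erlang":
        lam0 = math.lgamma(round(a)) + a * math.log(b)  # ln((alpha-1)! beta^alpha)
    else:
        lam0 = math.lgamma(a) + a * math.log(b)
    return LambdaVector(np.array([lam0, -(a - 1.0), 1.0 / b]))


def lambda_to_family(lv: LambdaVector, basis, integer_tol: float = 1e-9) -> ParametricFamily:
    """Invert the multiplier mapping by pattern-matching the basis.

    {const, log, identity} -> gamma (Erlang when the shape is an integer,
    exponential when it is 1); {const, log, power(a)} -> Weibull with
    shape a; {const, identity} -> exponential.
    """
    basis = tuple(basis)
    tags = [b.tag for b in basis]
    lam = lv.lambdas
    if lam.size != len(basis):
        raise UnsupportedFamilyError("lambda vector and basis differ in length")
    if tags == ["const", "identity"]:
        rate = lam[1]
        if rate <= 0:
            raise UnsupportedFamilyError("exponential requires a positive rate")
        return ParametricFamily("exponential", 1.0, 1.0 / rate)
    if tags == ["const", "log", "identity"]:
        alpha = 1.0 - lam[1]
        rate = lam[2]
        if alpha <= 0 or rate <= 0:
            raise UnsupportedFamilyError("multipliers outside the gamma domain")
        beta = 1.0 / rate
        if abs(alpha - 1.0) <= integer_tol:
            return ParametricFamily("exponential", 1.0, beta)
        if abs(alpha - round(alpha)) <= integer_tol:
            return ParametricFamily("erlang", float(round(alpha)), beta)
        return ParametricFamily("gamma", alpha, beta)
    if tags == ["const", "log", "power"]:
        alpha = basis[2].exponent
        if abs(lam[1] + (alpha - 1.0)) > 1e-6:
            raise UnsupportedFamilyError(
                "log multiplier inconsistent with the Weibull shape"
            )
        if lam[2] <= 0:
            raise UnsupportedFamilyError("Weibull needs a positive power multiplier")
        beta = lam[2] ** (-1.0 / alpha)
        return ParametricFamily("weibull", alpha, beta)
    raise UnsupportedFamilyError(f"unrecognized basis pattern {tags}")


def is_erlang_like(fam: ParametricFamily, tol: float = 1e-9) -> bool:
    """True for gamma-type families whose shape is a positive integer."""
    return fam.family in ("gamma", "erlang", "exponential") and \
        abs(fam.alpha - round(fam.alpha)) <= tol


def erlang_projection(fam: ParametricFamily) -> ParametricFamily:
    """Nearest integer-shape Erlang, with the scale refit to preserve the mean."""
    if fam.family not in ("gamma", "erlang", "exponential"):
        raise DomainError("Erlang projection applies to gamma-type families")
    k = max(1, int(round(fam.alpha)))
    mean = fam.alpha * fam.beta
    return ParametricFamily("erlang", float(k), mean / k)


# ---------------------------------------------------------------------------
# entropy
# ---------------------------------------------------------------------------

def differential_entropy(density) -> float:
    """Shannon differential entropy -int p ln p dx, in nats.

    Accepts a MaxEntDensity (quadrature on its support), a ParametricFamily
    (adaptive quadrature between extreme quantiles), or any grid density
    object exposing ``grid`` and ``masses``.
    """
    if isinstance(density, ParametricFamily):
        fr = density.frozen()
        lo, hi = fr.ppf(1e-14), fr.ppf(1.0 - 1e-14)
        nodes, weights = quadrature_nodes(max(lo, 1e-300), hi)
        p = fr.pdf(nodes)
        mass = float(weights @ p)
        if abs(mass - 1.0) > NORMALIZATION_TOL:
            raise DomainError(f"density integrates to {mass}, not 1")
        plogp = np.where(p > 0, p * np.log(np.where(p > 0, p, 1.0)), 0.0)
        return float(-(weights @ plogp))
    if isinstance(density, MaxEntDensity):
        nodes, weights = density.quadrature()
        p = density_eval(density, nodes)
        mass = float(weights @ p)
        if abs(mass - 1.0) > NORMALIZATION_TOL:
            raise DomainError(f"density integrates to {mass}, not 1")
        plogp = np.where(p > 0, p * np.log(np.where(p > 0, p, 1.0)), 0.0)
        return float(-(weights @ plogp))
    if hasattr(density, "grid") and hasattr(density, "masses"):
        x = np.asarray(density.grid, dtype=float)
        m = np.asarray(density.masses, dtype=float)
        w = _grid_weights(x)
        pdf = m / w
        plogp = np.where(pdf > 0, pdf * np.log(np.where(pdf > 0, pdf, 1.0)), 0.0)
        return float(-(w @ plogp))
    raise DomainError(f"cannot compute entropy of {type(density).__name__}")


def _grid_weights(x: np.ndarray) -> np.ndarray:
    """Trapezoid quadrature weights of a strictly increasing grid."""
    w = np.zeros_like(x)
    dx = np.diff(x)
    w[:-1] += dx / 2
    w[1:] += dx / 2
    return w


# ---------------------------------------------------------------------------
# classical Weibull baseline estimators
# ---------------------------------------------------------------------------

def _check_positive_sample(x):
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise DegenerateDataError("need at least two samples")
    if np.any(x <= 0):
        raise DomainError("Weibull fitting requires strictly positive samples")
    if np.std(x) == 0:
        raise DegenerateDataError("sample has zero variance")
    return x


def fit_weibull_empirical(samples) -> ParametricFamily:
    """Method-of-moments Weibull fit.

    alpha = (s / xbar)^(-1.086), beta = xbar / Gamma(1 + 1/alpha), with s the
    sample standard deviation — the classical coefficient-of-variation
    approximation to the shape equation.
    """
    x = _check_positive_sample(samples)
    xbar = float(np.mean(x))
    s = float(np.std(x, ddof=1))
    alpha = (s / xbar) ** (-1.086)
    beta = xbar / special.gamma(1.0 + 1.0 / alpha)
    return ParametricFamily("weibull", alpha, beta)


def _weibull_shape_fixed_point(x, w, alpha0, tol=1e-10, max_iter=500):
    """Damped fixed-point iteration for the implicit MLE shape equation.

    alpha = [ sum w x^a ln x / sum w x^a  -  sum w ln x / sum w ]^{-1},
    with weights w (uniform for the plain MLE).
    """
    logx = np.log(x)
    wlog = float(w @ logx) / float(w.sum())
    alpha = alpha0
    for _ in range(max_iter):
        xa = np.power(x, alpha)
        num = float(w @ (xa * logx))
        den = float(w @ xa)
        g = num / den - wlog
        if g <= 0:
            raise ConvergenceError("shape equation has no positive solution",
                                   residual=g)
        new = 1.0 / g
        new = 0.5 * (alpha + new)  # damping keeps the iteration contractive
        if abs(new - alpha) < tol:
            return new
        alpha = new
    raise ConvergenceError("Weibull MLE shape iteration did not converge",
                           residual=abs(new - alpha))


def fit_weibull_mle(samples) -> ParametricFamily:
    """Maximum-likelihood Weibull fit via the implicit shape equation."""
    x = _check_positive_sample(samples)
    alpha0 = fit_weibull_empirical(x).alpha
    w = np.ones_like(x)
    alpha = _weibull_shape_fixed_point(x, w, alpha0)
    beta = float(np.mean(np.power(x, alpha))) ** (1.0 / alpha)
    return ParametricFamily("weibull", alpha, beta)


def fit_weibull_modified_mle(values, freqs) -> ParametricFamily:
    """Frequency-weighted Weibull MLE for data given as a frequency table.

    Zero-valued bins carry no likelihood information and are dropped; the
    remaining mass P(x > 0) renormalizes the weighted averages, so a
    frequency table equal to the empirical distribution of a raw sample
    reproduces the plain MLE exactly.
    """
    x = np.asarray(values, dtype=float)
    p = np.asarray(freqs, dtype=float)
    if x.shape != p.shape or x.ndim != 1:
        raise DomainError("values and frequencies must be 1-d and aligned")
    if np.any(p < 0) or p.sum() <= 0:
        raise DomainError("frequencies must be non-negative with positive total")
    if np.any(x < 0):
        raise DomainError("values must be non-negative")
    p = p / p.sum()
    keep = (x > 0) & (p > 0)
    x, p = x[keep], p[keep]
    if x.size == 0:
        raise DegenerateDataError("all probability mass at zero")
    if x.size == 1:
        raise DegenerateDataError("a single nonzero bin cannot identify a shape")
    mean = float(p @ x) / p.sum()
    var = float(p @ (x - mean) ** 2) / p.sum()
    if var <= 0:
        raise DegenerateDataError("frequency table has zero variance")
    alpha0 = (math.sqrt(var) / mean) ** (-1.086)
    alpha = _weibull_shape_fixed_point(x, p, alpha0)
    beta = (float(p @ np.power(x, alpha)) / p.sum()) ** (1.0 / alpha)
    return ParametricFamily("weibull", alpha, beta)
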