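"""Estimation of the exchange-rate constants K = (Ka, Kb).

The Murase linearization turns the two-compartment model into the linear
system Y = A K + b with Gaussian noise b.  This module solves it by

* ordinary least squares (normal equations via a stable factorization),
* ridge / Tikhonov regularization (A'A + w I)^{-1} A' Y, and
* Bayesian MAP: maximize -||Y - AK||^2 / sigma^2 + ln p(K) over K >= 0,
  where the prior p(K) may be flat, exponential, or a maximum-entropy
  density fitted by the companion modules.

Estimates are reported in 1/min.  Plain LS is left unconstrained (a warning
is emitted when a component comes out negative); the MAP estimate enforces
the physiological non-negativity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize as sp_optimize

from .errors import ConfigurationError, DomainError
from .pk_model import DesignMatrix

_POSITIVE_FLOOR = 1e-300


@dataclass(frozen=True)
class MeasurementVector:
    """Measured tissue concentrations aligned with a design matrix."""

    y: np.ndarray

    def __post_init__(self):
        y = np.asarray(self.y, dtype=float)
        if y.ndim != 1 or not np.all(np.isfinite(y)):
            raise DomainError("measurement vector must be finite and 1-d")
        object.__setattr__(self, "y", y)


@dataclass(frozen=True)
class PriorSpec:
    """Prior over (Ka, Kb) for MAP estimation.

    kind='flat' is the improper uniform prior on the non-negative quadrant;
    kind='exponential' uses independent exponential priors with the given
    per-component ``rates``; kind='maxent' evaluates the supplied
    per-component ``densities`` (objects with a ``pdf`` method or plain
    callables, e.g. a fitted ParametricFamily) independently per component.
    """

    kind: str = "flat"
    rates: tuple = (1.0, 1.0)
    densities: tuple = ()

    def __post_init__(self):
        if self.kind not in ("flat", "exponential", "maxent"):
            raise ConfigurationError(f"unknown prior kind {self.kind!r}")
        if self.kind == "exponential" and any(r <= 0 for r in self.rates):
            raise ConfigurationError("exponential prior rates must be positive")
        if self.kind == "maxent" and len(self.densities) != 2:
            raise ConfigurationError("maxent prior needs one density per component")

    def log_prior(self, k: np.ndarray) -> float:
        if np.any(k < 0):
            return -np.inf
        if self.kind == "flat":
            return 0.0
        if self.kind == "exponential":
            r = np.asarray(self.rates, dtype=float)
            return float(np.sum(np.log(r) - r * k))
        total = 0.0
        for d, ki in zip(self.densities, k):
            pdf = d.pdf(ki) if hasattr(d, "pdf") else d(ki)
            total += float(np.log(max(float(pdf), _POSITIVE_FLOOR)))
        return total

    def log_prior_grad(self, k: np.ndarray) -> np.ndarray:
        if self.kind == "flat":
            return np.zeros_like(k)
        if self.kind == "exponential":
            return -np.asarray(self.rates, dtype=float)
        eps = 1e-7
        g = np.zeros_like(k)
        for i in range(k.size):
            up, dn = k.copy(), k.copy()
            up[i] += eps
            dn[i] = max(dn[i] - eps, 0.0)
            g[i] = (self.log_prior(up) - self.log_prior(dn)) / (up[i] - dn[i])
        return g


@dataclass(frozen=True)
class KineticsFit:
    """Estimated rate constants (1/min) with fit diagnostics."""

    ka: float
    kb: float
    method: str
    residual_ss: float
    sigma2: float | None = None
    covariance: np.ndarray | None = None
    log_posterior: float | None = None

    def as_array(self) -> np.ndarray:
        return np.array([self.ka, self.kb])


def _system(design: DesignMatrix, y: MeasurementVector):
    a = design.to_per_minute_system()
    yv = y.y if isinstance(y, MeasurementVector) else MeasurementVector(y).y
    if yv.size != a.shape[0]:
        raise DomainError("measurement length does not match the design matrix")
    return a, yv


def estimate_ls(design: DesignMatrix, y) -> KineticsFit:
    """Ordinary least squares K = (A'A)^{-1} A'Y via QR/SVD (lstsq).

    Raises on a rank-deficient design (use ridge there); warns when the
    unconstrained solution has a negative component.
    """
    a, yv = _system(design, y)
    if np.linalg.matrix_rank(a) < 2:
        raise DomainError(
            "design matrix is rank deficient; use estimate_ridge instead"
        )
    k, _, _, _ = np.linalg.lstsq(a, yv, rcond=None)
    resid = yv - a @ k
    rss = float(resid @ resid)
    n = yv.size
    sigma2 = rss / (n - 2) if n > 2 else np.nan
    cov = np.linalg.inv(a.T @ a) * sigma2
    if np.any(k < 0):
        warnings.warn("least-squares estimate has a negative rate constant",
                      stacklevel=2)
    return KineticsFit(float(k[0]), float(k[1]), "ls", rss, sigma2, cov)


def estimate_ridge(design: DesignMatrix, y, ridge_weight: float) -> KineticsFit:
    """Tikhonov-regularized solution K = (A'A + w I)^{-1} A'Y."""
    if ridge_weight < 0:
        raise DomainError("ridge weight must be non-negative")
    a, yv = _system(design, y)
    ata = a.T @ a + ridge_weight * np.eye(2)
    k = np.linalg.solve(ata, a.T @ yv)
    resid = yv - a @ k
    return KineticsFit(float(k[0]), float(k[1]), "ridge", float(resid @ resid))


def estimate_sigma2(design: DesignMatrix, y, k_hat) -> float:
    """Residual noise variance ||Y - A K||^2 / (n - 2)."""
    a, yv = _system(design, y)
    if yv.size <= 2:
        raise DomainError("need more than two samples to estimate the variance")
    k = np.asarray(k_hat.as_array() if hasattr(k_hat, "as_array") else k_hat,
                   dtype=float)
    resid = yv - a @ k
    return float(resid @ resid) / (yv.size - 2)


def estimate_map(design: DesignMatrix, y, prior: PriorSpec,
                 sigma2: float | None = None) -> KineticsFit:
    """MAP estimate: maximize -Q(K) + ln p(K) over K >= 0.

    Q(K) = ||Y - AK||^2 / sigma^2 is the Gaussian log-likelihood (up to a
    constant).  When sigma2 is not supplied it defaults to the residual
    variance of a preliminary LS fit.  Optimization is bounded L-BFGS with
    an analytic likelihood gradient, started from the clipped LS solution.
    """
    a, yv = _system(design, y)
    if sigma2 is None:
        sigma2 = estimate_ls(design, y).sigma2
    if not (sigma2 > 0):
        raise DomainError("sigma2 must be positive")

    def neg_log_post(k):
        resid = yv - a @ k
        lp = prior.log_prior(k)
        if not np.isfinite(lp):
            return 1e300
        return float(resid @ resid) / sigma2 - lp

    def grad(k):
        resid = yv - a @ k
        return -2.0 * (a.T @ resid) / sigma2 - prior.log_prior_grad(k)

    ls = estimate_ls(design, y)
    x0 = np.maximum(ls.as_array(), 1e-6)
    res = sp_optimize.minimize(
        neg_log_post, x0, jac=grad, method="L-BFGS-B",
        bounds=[(0.0, None), (0.0, None)],
        options={"ftol": 1e-16, "gtol": 1e-12, "maxiter": 500},
    )
    k = res.x
    resid = yv - a @ k
    return KineticsFit(float(k[0]), float(k[1]), "map", float(resid @ resid),
                       sigma2, None, -float(res.fun))
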