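"""Goodness-of-fit metrics for estimated AIF densities and curves.

A fitted density is compared against the empirical evidence through the
Kullback-Leibler divergence to a kernel-density reference, its differential
entropy, and pointwise regression metrics (RMSE, reduced chi-square, R^2)
between the fitted pdf and the KDE on the KDE grid.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
from scipy import stats

from .errors import DegenerateDataError, DomainError
from .maxent_core import _grid_weights, differential_entropy
from .maxent_reg import GridDensity


@dataclass(frozen=True)
class EvaluationReport:
    """KL divergence (nats), entropy (nats), RMSE, reduced chi^2, R^2."""

    kl_divergence: float
    entropy: float
    rmse: float
    chi_square: float
    r_squared: float

    def __post_init__(self):
        if self.kl_divergence < -1e-10:
            raise DomainError("KL divergence cannot be negative")
        if self.r_squared > 1 + 1e-12:
            raise DomainError("R^2 cannot exceed 1")

    def to_json(self) -> str:
        return json.dumps(asdict(self))


def kl_divergence(p_hat, g, grid) -> float:
    """int p_hat ln(p_hat / g) dx by trapezoid quadrature on the grid.

    Uses the convention 0 ln 0 = 0; raises where p_hat puts mass outside
    the support of g.
    """
    x = np.asarray(grid, dtype=float)
    p = np.asarray(p_hat, dtype=float)
    q = np.asarray(g, dtype=float)
    if p.shape != x.shape or q.shape != x.shape:
        raise DomainError("densities and grid must be aligned")
    if np.any(p < 0) or np.any(q < 0):
        raise DomainError("densities must be non-negative")
    if np.any((p > 0) & (q == 0)):
        raise DomainError("p has mass where the reference is zero")
    w = _grid_weights(x)
    pos = p > 0
    integrand = np.zeros_like(p)
    integrand[pos] = p[pos] * np.log(p[pos] / q[pos])
    return float(w @ integrand)


def rmse(observed, predicted) -> float:
    """Root mean squared error."""
    y = np.asarray(observed, dtype=float)
    yh = np.asarray(predicted, dtype=float)
    if y.shape != yh.shape or y.ndim != 1 or y.size == 0:
        raise DomainError("observed and predicted must be equal-length vectors")
    return float(np.sqrt(np.mean((y - yh) ** 2)))


def chi_square(observed, predicted, n_params: int) -> float:
    """Reduced residual sum of squares, sum (y - yhat)^2 / (l - n)."""
    y = np.asarray(observed, dtype=float)
    yh = np.asarray(predicted, dtype=float)
    if y.shape != yh.shape or y.ndim != 1:
        raise DomainError("observed and predicted must be equal-length vectors")
    if y.size <= n_params:
        raise DomainError("need more observations than parameters")
    return float(np.sum((y - yh) ** 2) / (y.size - n_params))


def r_squared(observed, predicted) -> float:
    """Coefficient of determination 1 - SS_res / SS_tot."""
    y = np.asarray(observed, dtype=float)
    yh = np.asarray(predicted, dtype=float)
    if y.shape != yh.shape or y.ndim != 1:
        raise DomainError("observed and predicted must be equal-length vectors")
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    if ss_tot == 0:
        raise DegenerateDataError("R^2 undefined for a constant observed vector")
    ss_res = float(np.sum((y - yh) ** 2))
    return 1.0 - ss_res / ss_tot


def kde_reference(samples, grid_size: int = 512) -> GridDensity:
    """Gaussian KDE with Silverman bandwidth on a regular positive grid.

    The grid spans the sample range padded by three bandwidths, is clipped
    to x > 0, and the density renormalized to integrate to one.
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 2 or np.std(x) == 0:
        raise DegenerateDataError("KDE needs at least two distinct samples")
    kde = stats.gaussian_kde(x, bw_method="silverman")
    bw = float(np.sqrt(kde.covariance[0, 0]))
    lo, hi = x.min() - 3 * bw, x.max() + 3 * bw
    grid = np.linspace(lo, hi, grid_size)
    grid = grid[grid > 0]
    if grid.size < 2:
        raise DegenerateDataError("positive part of the KDE grid is empty")
    pdf = np.maximum(kde(grid), 1e-300)
    return GridDensity.from_pdf(grid, pdf)


class ECDF:
    """Right-continuous empirical CDF: 0 below the minimum, 1 at the maximum."""

    def __init__(self, samples):
        x = np.asarray(samples, dtype=float)
        if x.size == 0:
            raise DegenerateDataError("empty sample")
        self.sorted = np.sort(x)
        self.n = x.size

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        out = np.searchsorted(self.sorted, x, side="right") / self.n
        return float(out) if out.ndim == 0 else out


def ecdf(samples) -> ECDF:
    return ECDF(samples)


def evaluate_aif_fit(samples, fitted_family, grid_size: int = 512) -> EvaluationReport:
    """Score a fitted AIF density against the KDE of the samples.

    KL is taken fitted || reference; RMSE, reduced chi^2 (2 fitted
    parameters) and R^2 compare the fitted pdf with the KDE pdf pointwise
    on the KDE grid.
    """
    ref = kde_reference(samples, grid_size)
    fitted_pdf = fitted_family.pdf(ref.grid)
    ref_pdf = ref.pdf_values()
    kl = kl_divergence(fitted_pdf, ref_pdf, ref.grid)
    return EvaluationReport(
        kl_divergence=max(kl, 0.0),
        entropy=differential_entropy(fitted_family),
        rmse=rmse(ref_pdf, fitted_pdf),
        chi_square=chi_square(ref_pdf, fitted_pdf, 2),
        r_squared=r_squared(ref_pdf, fitted_pdf),
    )
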