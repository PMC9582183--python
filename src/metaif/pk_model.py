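"""Two-compartment (Tofts) forward model and its Murase linearization.

The tissue concentration C_T(t) obeys

    dC_T/dt = Ka * C_p(t) - Kb * C_T(t),        C_T(0) = 0,

where C_p is the arterial input function (AIF).  The closed-form solution is
the convolution C_T(t) = Ka * int_0^t C_p(s) exp(-Kb (t - s)) ds.  Murase's
linearization integrates the ODE once, giving at each sample time t_I

    C_T(t_I) = Ka * int_0^{t_I} C_p ds  -  Kb * int_0^{t_I} C_T ds,

i.e. a linear system  C = A K  in K = (Ka, Kb), with the design matrix A
holding cumulative integrals of the AIF and of the tissue curve.

Units: time grids are in seconds; concentrations in mmol/L; the rate
constants Ka, Kb are reported in 1/min (the conventional DCE-MRI scale) and
converted internally by a factor of 60.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .errors import DomainError, GridError

SECONDS_PER_MINUTE = 60.0

#: in vivo longitudinal relaxivity of Gd-DTPA protons, l/s/mmol
DEFAULT_R1 = 4.24


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TimeGrid:
    """Strictly increasing acquisition times in seconds."""

    times: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        if t.ndim != 1 or t.size < 2:
            raise GridError("time grid needs at least two samples")
        if not np.all(np.isfinite(t)):
            raise GridError("time grid contains non-finite values")
        if t[0] < 0:
            raise GridError("time grid starts before t=0")
        if np.any(np.diff(t) <= 0):
            raise GridError("time grid must be strictly increasing")
        object.__setattr__(self, "times", t)

    def __len__(self):
        return self.times.size

    def __eq__(self, other):
        return isinstance(other, TimeGrid) and np.array_equal(self.times, other.times)


@dataclass(frozen=True)
class ConcentrationCurve:
    """Sampled concentration-time curve C(t), mmol/L on a TimeGrid."""

    grid: TimeGrid
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.grid),):
            raise GridError(
                f"curve has {v.size} values for a {len(self.grid)}-point grid"
            )
        if not np.all(np.isfinite(v)):
            raise DomainError("curve contains non-finite concentrations")
        object.__setattr__(self, "values", v)

    @property
    def times(self) -> np.ndarray:
        return self.grid.times


@dataclass(frozen=True)
class PKParameters:
    """Exchange-rate constants of the two-compartment model, in 1/min."""

    ka: float
    kb: float

    def __post_init__(self):
        if self.ka < 0 or self.kb < 0:
            raise DomainError("rate constants must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array([self.ka, self.kb], dtype=float)


@dataclass(frozen=True)
class DesignMatrix:
    """n x 2 matrix of cumulative integrals; row I = (∫C_p ds, -∫C_T ds).

    Integrals are taken in seconds, so a coefficient vector solving
    ``tissue = A @ k`` is in 1/s; ``to_per_minute_system`` rescales the
    columns so the solution is directly in the conventional 1/min units.
    """

    grid: TimeGrid
    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.grid), 2):
            raise GridError("design matrix must be n x 2 on its grid")
        object.__setattr__(self, "matrix", m)

    def to_per_minute_system(self) -> np.ndarray:
        """Column-rescaled matrix such that y = A_min @ (ka, kb) with K in 1/min."""
        return self.matrix / SECONDS_PER_MINUTE


@dataclass(frozen=True)
class NoiseModel:
    """Additive white centered Gaussian measurement noise, variance sigma2."""

    sigma2: float

    def __post_init__(self):
        if self.sigma2 < 0:
            raise DomainError("noise variance must be non-negative")

    @property
    def sigma(self) -> float:
        return float(np.sqrt(self.sigma2))


@dataclass(frozen=True)
class RelaxationCurve:
    """Longitudinal relaxation times T1(t) with pre-contrast baseline T10.

    r1 is the contrast agent's relaxivity in l/s/mmol.
    """

    grid: TimeGrid
    t1_values: np.ndarray
    t10: float
    r1: float = DEFAULT_R1

    def __post_init__(self):
        v = np.asarray(self.t1_values, dtype=float)
        if v.shape != (len(self.grid),):
            raise GridError("T1 curve length must match its grid")
        if np.any(v <= 0) or self.t10 <= 0:
            raise DomainError("relaxation times must be positive")
        if self.r1 <= 0:
            raise DomainError("relaxivity r1 must be positive")
        object.__setattr__(self, "t1_values", v)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def simulate_tissue_curve(aif: ConcentrationCurve, params: PKParameters) -> ConcentrationCurve:
    """Forward-convolve the AIF through the two-compartment model.

    C_T(t_i) = Ka ∫_0^{t_i} C_p(s) e^{-Kb (t_i - s)} ds, evaluated exactly
    for the linear interpolant of the sampled AIF (the per-interval integral
    of a linear segment against the exponential kernel has a closed form),
    so the discrete model is self-consistent with the underlying ODE.

    The AIF is taken to be zero before the first sample.
    """
    t = aif.times
    cp = aif.values
    ka = params.ka / SECONDS_PER_MINUTE  # 1/s
    kb = params.kb / SECONDS_PER_MINUTE  # 1/s

    n = t.size
    ct = np.zeros(n)
    # recursion: C_T(t_{j+1}) = C_T(t_j) e^{-kb dt} + ka * segment integral
    for j in range(n - 1):
        dt = t[j + 1] - t[j]
        a = cp[j]                       # value at segment start
        b = (cp[j + 1] - cp[j]) / dt    # slope
        x = kb * dt
        if x > 1e-6:
            e = np.exp(-x)
            i0 = (1.0 - e) / kb                         # ∫ e^{-kb v} dv
            i1 = (1.0 - (1.0 + x) * e) / (kb * kb)      # ∫ v e^{-kb v} dv
            decay = e
        else:
            # series expansions, stable as kb*dt -> 0
            i0 = dt * (1.0 - x / 2.0 + x * x / 6.0)
            i1 = dt * dt * (0.5 - x / 3.0 + x * x / 8.0)
            decay = 1.0 - x + x * x / 2.0
        # ∫_0^{dt} (a + b(dt - v)) e^{-kb v} dv  with v = time before t_{j+1}
        seg = (a + b * dt) * i0 - b * i1
        ct[j + 1] = ct[j] * decay + ka * seg
    return ConcentrationCurve(aif.grid, ct)


def build_design_matrix(aif: ConcentrationCurve, tissue: ConcentrationCurve) -> DesignMatrix:
    """Murase design matrix: cumulative trapezoid integrals of C_p and -C_T.

    The first row is (0, 0) because the cumulative integral starts at the
    first sample (the curves are taken as zero before it).
    """
    if aif.grid != tissue.grid:
        raise GridError("AIF and tissue curves must share one time grid")
    t = aif.times
    col1 = cumulative_trapezoid(aif.values, t, initial=0.0)
    col2 = -cumulative_trapezoid(tissue.values, t, initial=0.0)
    return DesignMatrix(aif.grid, np.column_stack([col1, col2]))


def add_noise(curve: ConcentrationCurve, noise: NoiseModel, seed) -> ConcentrationCurve:
    """Add i.i.d. centered Gaussian noise; reproducible for a fixed seed.

    ``seed`` may be an int or a numpy Generator.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if noise.sigma2 == 0:
        return ConcentrationCurve(curve.grid, curve.values.copy())
    draw = rng.normal(0.0, noise.sigma, size=curve.values.shape)
    return ConcentrationCurve(curve.grid, curve.values + draw)


def signal_to_concentration(relax: RelaxationCurve) -> ConcentrationCurve:
    """Convert a T1 relaxation-time curve to Gd-DTPA concentration.

    C(t) = (1/r1) * (1/T1(t) - 1/T10), with T10 the pre-contrast baseline.
    """
    c = (1.0 / relax.r1) * (1.0 / relax.t1_values - 1.0 / relax.t10)
    return ConcentrationCurve(relax.grid, c)
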