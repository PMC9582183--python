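# Methods

## Pharmacokinetic model and units

The tissue curve follows the two-compartment exchange model
dC_T/dt = Ka·C_p − Kb·C_T with C_T(0) = 0, equivalently the convolution
C_T(t) = Ka ∫₀ᵗ C_p(s) e^{−Kb(t−s)} ds. Time grids are kept in seconds
(acquisition native); Ka and Kb are reported in 1/min, the conventional
DCE-MRI scale on which published per-patient values (0.16–1.54 /min) are
plausible. The factor of 60 is applied once, inside the design-matrix
rescaling and the forward model, and nowhere else.

The forward simulator integrates the convolution exactly for the linear
interpolant of the sampled AIF: over each frame interval the integral of a
linear segment against the exponential kernel has a closed form, with series
expansions below Kb·dt = 1e−6 for numerical stability. This makes the
discrete model self-consistent with the ODE — on the 46 × 11.9 s grid it
agrees with an adaptive ODE solve to ~1e−10 relative error, so discretization
of the forward model never limits parameter recovery. The Murase design
matrix uses cumulative trapezoid integrals (the natural rule for sampled
curves); its residual discretization bias on the study grid is below 1% in
(Ka, Kb) and vanishes quadratically under grid refinement.

Curves are taken as zero before the first sample; the first design-matrix
row is (0, 0) when t₁ = 0. The T1-to-concentration conversion is
C = (1/r1)(1/T1 − 1/T10) with r1 defaulting to 4.24 l/s/mmol (in vivo
Gd-DTPA relaxivity).

## Maximum-entropy estimation

Moment targets are plain sample means of the basis functions over the
(strictly positive) concentration samples; non-positive values are dropped
before any ln x constraint and the dropped count is logged and reported.
"Moment computation via Taylor's theorem" in the source literature is not
otherwise defined; sample means are the natural reading and are documented
here as an interpretation.

The ME density on a support (ε, U] is exp(−Σ λᵢφᵢ); λ₀ is always recomputed
as the log-partition, so normalization is structural. The default support is
ε = 1e−12 to U = 10 × max(sample) — wide enough that truncation error is far
below solver tolerances for the families of interest. All integrals use
composite Gauss–Legendre quadrature (order 16) on geometrically spaced
panels, which resolves the x^{α−1} and ln x behaviour near the origin to
near machine precision (gamma entropy matches the closed form to ~5e−13).

**Newton solver.** Minimizes the convex dual ln Z(λ) + λᵀμ with analytic
gradient (μ − E_p[φ]) and Hessian (the covariance of φ under p), damped by
backtracking. Near the optimum the dual improvement falls below floating-
point resolution, so steps are also accepted on a decrease of the gradient
norm; the solver guarantees max |E_p[φᵢ] − μᵢ| < 1e−8 or raises a
convergence error carrying the residual. Infeasible targets (the dual is
then unbounded below) surface as that error — e.g. any pair with
E[ln X] > ln E[X], impossible for every density by Jensen's inequality.

**Family ↔ multiplier maps.** Gamma(α, β) ↔ (λ_log, λ_x) = (−(α−1), 1/β)
with λ₀ = ln Γ(α) + α ln β; Weibull(α, β) ↔ (λ_log, λ_{x^α}) = (−(α−1),
β^{−α}); Erlang is gamma with integer shape; exponential is gamma with
α = 1. The power basis therefore accepts any positive real exponent (the
Weibull shape), not just integers. The inverse map pattern-matches the
basis and flags gamma fits with integer shape as Erlang. Erlang projection
of a non-integer gamma uses the nearest positive integer shape with the
scale refit to preserve the mean — the integerization rule is otherwise
ambiguous in the source material.

**TLBO solver.** Teacher phase Z' = Z + r(Z_best − T_F·mean) with r ~ U[0,1]
per learner and teaching factor T_F ∈ {1, 2} equiprobable; learner phase
moves each learner toward the better of a random distinct pair. Both phases
clip to the box bounds and accept greedily, so the best-so-far trace is
non-increasing and the search is deterministic per seed. Population size,
iteration count, initialization and bounds handling are not specified in the
source description; the defaults here are uniform random initialization,
clip-to-bounds, pop 30, 200 iterations (600 when solving moment equations).
Duplicate-learner elimination is deliberately not implemented. The moment
equations are solved by minimizing Σᵢ (E_p[φᵢ] − μᵢ)² over the free
multipliers with normalization folded into the log-partition, which reduces
the search dimension by one and leaves the solution identical to Newton's
(the dual is strictly convex, so the optimum is unique — the basis of the
cross-solver agreement tests). Default bounds ±10 per multiplier cover every
family in the parameter ranges of interest.

## Soft-constrained (regularized) estimation

The regularized problem minimizes J(p) = ‖μ − E_p[φ]‖² + w·KL(p, g) over
probability vectors on a grid, where g is a reference density and w > 0 the
regularization weight. The printed dual in the source (a (1/λ)‖λ‖² term,
and a min/max inconsistency) is not well defined; the implementation uses
the standard Fenchel dual of J,

    min_η  ln Σⱼ gⱼ e^{−(Φᵀη)ⱼ} + ηᵀμ + (w/4)‖η‖²,

with primal recovery pⱼ ∝ gⱼ e^{−(Φᵀη)ⱼ}. Solved by damped Newton (the
Hessian Cov(φ) + (w/2)I is positive definite). Optimality gives the exact
identity μ − E_p[φ] = −(w/2)η, so the moment residual shrinks linearly in w
and η converges to the equality-constrained multipliers (w.r.t. the
reference measure) as w → 0; with a uniform reference on the quadrature
grid the gap to Newton's λ measures ≈ Cov(φ)⁻¹(w/2)λ — about 1e−4 at
w = 1e−6 for gamma-type sets, which is where the cross-solver tests pin the
limit. The independent primal route is entropic mirror descent with
backtracking and an interior KKT stopping rule (the KL term keeps the
optimum strictly positive); primal and dual agree to < 1e−5 on random
problems, a strong-duality check that would catch an error in either
derivation.

The pipeline: (1) sample moments; (2) Gaussian-KDE reference (Silverman
bandwidth) on a 512-point grid spanning [min/2, 2·max] of the samples,
floored at 1e−300 so KL stays defined; (3) dual solve at reg_weight
(default 0.1; a discrepancy-principle search for the largest weight meeting
a residual tolerance is available, since no selection rule is prescribed);
(4) projection onto the requested family by matching E[X] and E[ln X] of
the grid solution (gamma shape via ln α − ψ(α) = ln E[X] − E[ln X], solved
by bisection; Weibull analogously; Erlang by integer projection).

## Rate-constant estimation

LS solves the rescaled per-minute system by QR/SVD and reports the
(AᵀA)⁻¹σ̂² covariance; it is left unconstrained (with a warning on negative
components) to match the plain normal-equations formulation. Ridge is
(AᵀA + wI)⁻¹Aᵀy. MAP maximizes −‖y − AK‖²/σ² + ln p(K) over K ≥ 0 by
bounded L-BFGS with analytic likelihood gradient, started from the clipped
LS solution; σ² defaults to the residual variance of a preliminary LS fit
(‖y − AK̂‖²/(n−2)). Priors: flat (MAP then equals non-negative LS),
independent exponentials, or "maxent" — any per-component density with a
pdf, typically the family fitted to the AIF. Estimates returned by the
fitters are plain floats rather than the non-negative PKParameters
container, because LS may legitimately produce a negative component.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the study acquisition: 46 frames at 11.9 s, four
pre-bolus baseline frames at zero concentration, additive centered Gaussian
noise with SD quoted as a fraction of the noise-free tissue peak (default
2%, the cohort harness condition; the recovery study uses 5%). AIF time
courses are scaled family pdfs evaluated in minutes post-bolus (default
gamma(2.719, 0.237), the best-fitting reported AIF model; peak 5 mmol/L), or
the classical bi-exponential population curve. Cohorts draw Ka uniformly
from 0.16–1.54 /min (the span of reported per-patient values) and Kb from
0.2–3 /min, 12 subjects by default.

The density-estimation stages model the distribution of AIF concentration
*values*, which the source conflates silently with the time course. The
value histogram of a smooth unimodal curve is not itself a gamma density
(it concentrates mass near extrema), so each subject record also carries
i.i.d. draws from the generating family (500 by default), and the pipeline
uses those when supplied, falling back to positive curve values otherwise.
Passing tests on the i.i.d. path demonstrate density recovery under the
model's own sampling assumption; they do not show that real voxel
time-series values follow any named family. Other idealizations: no T1
estimation noise, no bolus dispersion or delay, no spatial structure, no
recirculation bump in the AIF.

## Numerical choices and degenerate inputs

* Newton/dual tolerances: 1e−10 gradient targets with an 1e−8 contract;
  mirror descent stops at KKT residual 1e−9 (accepts 1e−6 on stall).
* Weibull MLE shape equation: damped fixed-point iteration (average of old
  and new iterate) to |Δα| < 1e−10, started from the method-of-moments
  shape; the frequency-weighted variant drops zero-valued bins and
  renormalizes by the remaining mass, which makes it exactly equal to the
  raw MLE on an empirical frequency table.
* Degenerate inputs raise typed errors: zero-variance samples, all mass at
  zero or a single nonzero bin, non-monotone time grids, non-positive T1,
  rank-deficient designs (with a pointer to ridge), references with zero
  mass (KL undefined), constant observed vectors in R².
* KL between fitted and reference densities is evaluated by trapezoid
  quadrature on the reference grid with 0·ln 0 = 0; evaluation reports are
  computed fitted-vs-KDE on the KDE grid, which is an interpretation — the
  pairing of "estimated" and "empirical" values for RMSE/χ²/R² is not
  otherwise specified.

## Known limitations

* The reported clinical tables cannot be reproduced: the underlying patient
  data are unavailable, and two printed quantities are internally
  inconsistent (a moment pair that no density can satisfy, and an entropy
  column matching no closed form for the named fits). The package therefore
  validates against closed forms, independent oracles and synthetic
  recovery, not against those table entries.
* Problem sizes in tests and the acceptance script (e.g. 200 recovery
  simulations, 12-subject cohorts, 1e5-draw estimator checks) are the
  package's chosen desk-scale defaults; all scale up by configuration.
* Constraint bases beyond {1, ln x, x, x^a, x ln x} (e.g. trigonometric
  moments) and image-domain processing (DICOM/NIfTI, T1 mapping, voxel-wise
  parameter maps) are out of scope.
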