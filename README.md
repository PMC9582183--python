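# metaif

Maximum-entropy estimation of the arterial input function (AIF) and
two-compartment pharmacokinetic parameters from DCE-MRI concentration-time
curves.

## The problem

In dynamic contrast-enhanced MRI, the concentration of a gadolinium contrast
agent in tissue, C_T(t), follows the two-compartment (Tofts) exchange model

    dC_T/dt = Ka · C_p(t) − Kb · C_T(t),        C_T(0) = 0,

driven by the arterial input function C_p(t) — the plasma concentration in
the feeding blood pool — with forward and reverse exchange rates Ka, Kb
(1/min). Integrating once (the Murase linearization) yields a linear system
C_T = A·K in K = (Ka, Kb), where the rows of A hold cumulative integrals of
C_p and −C_T. The system is ill-conditioned under measurement noise, and in
many scans (e.g. breast) no artery lies in the field of view, so the AIF must
itself be estimated from the data.

This package treats the AIF statistically: the distribution of AIF
concentration values is estimated as the maximum-entropy (ME) density under
empirical moment constraints

    p(x) = exp(−Σᵢ λᵢ φᵢ(x)),    E_p[φᵢ] = μᵢ,

with basis functions φ ∈ {1, ln x, x, x^a}, whose multipliers map in closed
form onto the exponential, gamma, Erlang and Weibull families. Three solvers
are provided:

* **Newton** — damped Newton on the convex ME dual (hard constraints);
* **TLBO** — teaching–learning-based optimization of the squared moment
  residual, a derivative-free population search;
* **soft-constrained / regularized** — minimize
  ‖μ − E_p[φ]‖² + w·KL(p, g) over densities on a grid, where g is a
  kernel-density reference and w a regularization weight; solved through its
  smooth Fenchel dual, with an independent mirror-descent primal route.

The fitted density then supplies the prior for Bayesian MAP estimation of
(Ka, Kb), alongside plain least-squares and ridge solutions of the Murase
system, classical Weibull baseline fits (method of moments, MLE,
frequency-weighted MLE), and an evaluation suite (KL divergence, entropy,
RMSE, reduced χ², R², eCDF).

A synthetic-data module emulates the study acquisition (46 frames at 11.9 s,
four pre-bolus baseline frames, additive Gaussian noise, gamma/Weibull or
bi-exponential AIF shapes) so the whole stack runs without clinical data.

## Worked example

```python
import json
import metaif as m

cfg = m.SimulationConfig(seed=1, pk_truth=m.PKParameters(0.53, 1.1))
subject = m.generate_subject(cfg)               # one synthetic patient
pipe = m.PipelineConfig(aif_method="met_reg", pk_method="map", seed=1)
bundle = m.run_pipeline(pipe, {"aif": subject.aif,
                               "tissue": subject.tissue_noisy,
                               "aif_samples": subject.aif_samples})
print(json.dumps(bundle["aif_fit"], indent=2))
print(json.dumps(bundle["pk_fit"], indent=2))
```

prints (numbers from this exact run)

```json
{
  "dropped_samples": 0,
  "n_samples": 500,
  "moment_residual": 0.008207597447024225,
  "kl_to_reference": 0.00033401443354787104,
  "log_partition": -0.14419877385541974,
  "family": "gamma",
  "alpha": 2.7618507355446726,
  "beta": 0.2291711161965172
}
{
  "ka_per_min": 0.5389299257170892,
  "kb_per_min": 1.1220836073965434,
  "method": "map",
  "sigma2": 0.000432198428410621,
  "residual_ss": 0.019016848918043054
}
```

The subject was generated with a gamma(2.719, 0.237) AIF value distribution
and true rates Ka = 0.53, Kb = 1.1 /min: the soft-constrained ME fit recovers
the gamma shape and scale to a few percent, and the MAP estimate lands within
2% of both rate constants. The accompanying evaluation report
(`bundle["aif_evaluation"]`) gives KL ≈ 0.008 to the kernel-density reference
and R² ≈ 0.99.

The same workflow is available from the shell:

```sh
metaif simulate --seed 1 --n-subjects 12 --out-dir cohort/
metaif run cohort/subject_0_aif.csv cohort/subject_0_tissue.csv \
    --aif-method met_reg --pk-method map --out result.json
metaif fit-pk cohort/subject_0_aif.csv cohort/subject_0_tissue.csv --method ls
```

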