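# Methods

## The model

`rwmtune` analyses the random walk Metropolis (RWM) algorithm — proposal
θ′ = θ + **S** ε with ε ~ N(0, **1**), accepted with probability
min{1, π(θ′)/π(θ)} — in the large-sample regime. When the target π_n is a
posterior satisfying a Bernstein–von Mises theorem, the chain rescaled by
√n around the estimator behaves like a RWM chain targeting
N(0, I(θ₀)⁻¹), where I(θ₀) is the Fisher information of the data-generating
model. All tuning theory in the package is about that *limiting chain*.

Efficiency is measured by the expected squared jumping distance in the
information norm,

    ESJD(λ, M) = E[ ‖Z_{k+1} − Z_k‖²_{I(θ₀)} ],   ‖x‖²_I = xᵀ I x,

for a proposal scale **S** = λ**M**. Two choices of **M** are covered:

* **cholesky** (matched): **M M**ᵀ = I(θ₀)⁻¹. Writing λ = ℓ/√d,

      ESJD = 2λ² E[χ_d² Φ(−λ χ_d / 2)],   acceptance = 2 E[Φ(−λ χ_d / 2)],

  with χ_d chi-distributed with d degrees of freedom. Both are invariant to
  the covariance structure, so the optimal ℓ depends on d alone.
* **identity** (isotropic): **M** = **1**. The same expressions hold with
  χ_d replaced by ‖ε‖_I, the metric norm of a standard normal vector; they
  now depend on I(θ₀) and degrade when the parameters are strongly
  correlated.

As d → ∞ the matched-proposal quantities converge to 2ℓ²Φ(−ℓ/2) and
2Φ(−ℓ/2): maximizing the former gives ℓ ≈ 2.3812, acceptance 23.38%, i.e.
the classical 0.234 rule is recovered as the high-dimensional limit of the
dimension-dependent guideline. For the isotropic proposal the analogous
limit is 2ℓ²L′Φ(−ℓ√L′/2), where L′ = lim ‖ε‖²_I / d; for an AR(1) target
covariance (entries ρ^|i−j|, tridiagonal inverse) L′ = (1+ρ²)/(1−ρ²).

The practical guideline for a posterior with n observations is
**S**_n = (ℓ̂/√(dn)) **M**_n with **M**_n **M**_nᵀ the inverse standardized
observed information at the MAP — computable before any chain is run.

## Numerical evaluation

* **Quadrature** (default for the matched case): 1-D adaptive quadrature of
  the integrand against the chi density on [0, √d + 12], absolute and
  relative tolerance 1e-10, with the density's mode passed as a
  break-point so the sharp peak is never missed at large d. Quadrature
  results are seed-free and reproducible to ~1e-10.
* **Monte Carlo**: default 10⁶ draws with a mandatory explicit seed; the
  standard error is reported alongside the value. For a general information
  metric the isotropic-case norm ‖ε‖_I has no 1-D reduction, so these
  expectations are Monte-Carlo only (the exact reduction is used when the
  metric is a scalar multiple of the identity).
* **Grid search** (`optimize_ell`): default grids (0.5, 6.0, 0.01) for the
  matched mode and (0.01, 20.0, 0.01) for the isotropic mode, whose optimum
  can sit far from 2.4 under strong correlation. Ties break toward the
  smallest ℓ; an argmax on the grid boundary raises instead of returning a
  censored value. Within one Monte-Carlo tuning run, common random numbers
  are shared across all grid points, so the argmax is not jittered by
  independent sampling noise. Reported ℓ̂ is rounded to two decimals in
  tables (matching the guideline table's print precision); the unrounded
  value is kept internally.

A caution when comparing tabulated optima across implementations: near its
maximum the matched-proposal ESJD is flat to below 1e-5 per 0.01 step in ℓ,
while the acceptance rate moves by ~0.14 percentage points per 0.01. Any
noise in the optimizer (e.g. a Monte-Carlo grid search) can therefore shift
the reported ℓ̂ by a grid step, and with it the quoted acceptance rate by
more than a tenth of a point, without any practical difference in sampler
efficiency.

## Sampler and diagnostics

The sampler decides acceptance in the log domain (log U < Δ log π), so
unnormalized densities and −∞ tails are safe. Chains are reproducible from
a single integer seed; all proposal increments and uniforms come from one
`numpy` Generator. Gaussian targets carry an exact sampler, enabling true
stationary starts; posterior chains start at the MAP and discard a 10%
burn-in as an approximation to stationarity.

Diagnostics: acceptance rate (exact mean of the indicators), empirical ESJD
in a supplied information norm with a non-overlapping batch-means standard
error (⌊√T⌋ batches), and per-coordinate effective sample size by Geyer's
initial monotone positive sequence estimator (autocovariances via FFT,
paired-sum truncation at the first nonpositive pair, running-minimum
monotonization). The chain-quality summary is the minimum marginal ESS per
iteration. A constant coordinate yields ESS 0 with a warning, not an
exception. The ESS estimator was chosen because it is standard and
tuning-free; any initial-sequence estimator would do.

## Synthetic data

The logistic-regression generator emulates the *shape* of a moderately
large epidemiological study: n = 4866 observations, d = 9 coefficients
(intercept + 8 covariates), covariates jointly Gaussian with AR(1)
cross-correlation ρ = 0.5, and true coefficients drawn once per seed from
N(0, 0.5²). The AR(1) correlation induces enough parameter correlation in
the posterior to separate the matched and isotropic proposals, which is the
phenomenon the study demonstrates. What it does not emulate: real
covariates are rarely Gaussian (binary/skewed predictors change the design
distribution, not the asymptotics), responses may be misspecified, and
observations may be dependent — so passing tests show the large-sample
theory and the implementation are consistent, not that any particular real
dataset will match the limiting values equally well.

The prior is independent N(0, 10²) per coefficient — weak enough that the
MAP is essentially the MLE at n ≈ 5000. The standardized observed
information is the data-term average Hessian (1/n) Σ p_i(1−p_i) x_i x_iᵀ at
the MAP, excluding the (negligible) prior curvature, matching the
definition of the empirical information of the sampling model.
`true_fisher_information` estimates E[p(1−p) X Xᵀ] at θ₀ from fresh
covariate draws (default 10⁶) and reports an entrywise standard error.

## Study problem sizes and test design

Defaults chosen for desk-scale replication: chains of 2×10⁵ steps with 10
replicate seeds for the AR(1) study (ρ ∈ {0, 0.3, 0.6, 0.8, 0.9},
d ∈ {5, 10, 50}); Monte-Carlo tuning with 10⁵–10⁶ draws. Stochastic
assertions use 3 batch-means (or replicate) standard errors with fixed
seeds, so test outcomes are deterministic.

The Bernstein–von Mises convergence test for the posterior sampler compares
sample sizes n ∈ {50, 500, 5000}: at larger n the remaining gap between the
posterior chain's acceptance rate and the limiting value (≲3×10⁻³) is
smaller than the Monte-Carlo error of any desk-scale chain, so the
monotone-decrease property is only resolvable where the gap dominates —
the package tests it there.

## Known limitations

* The isotropic-mode expectations are Monte Carlo; their argmax inherits
  O(n^{-1/2}) jitter (mitigated, not removed, by common random numbers).
* The ESJD-optimal ℓ is a proxy: it is optimal for the identity functional,
  not universally. ESS-based tuning is deliberately not implemented
  (empirically it lands at nearly the same ℓ).
* No within-chain adaptation, no acceptance-rate targeting, no MALA/HMC.
* Posterior chains cannot start exactly in stationarity; MAP start plus
  burn-in is an approximation that is excellent at the sample sizes used.
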