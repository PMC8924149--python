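# rwmtune

Dimension-dependent optimal scaling and information-matrix preconditioning
for the random walk Metropolis (RWM) algorithm, aimed at Bayesian analyses
of regular models with realistically large samples (the motivating setting
is biostatistics and epidemiological regression modelling).

## The problem and the method

RWM proposes θ′ = θ + **S** ε with ε ~ N(0, **1**) and accepts with
probability min{1, π(θ′)/π(θ)}. How should **S** be chosen? The classical
answer — scale so the acceptance rate is ≈ 0.234 — is derived for targets
with many i.i.d. coordinates. For a posterior π_n that satisfies a
Bernstein–von Mises theorem, the rescaled chain converges (as the sample
size n grows, for fixed dimension d) to a RWM chain targeting
N(0, I(θ₀)⁻¹), whose efficiency has closed one-dimensional representations.
Measuring efficiency by the expected squared jumping distance (ESJD) in the
information norm, the matched proposal **M M**ᵀ = I(θ₀)⁻¹ with λ = ℓ/√d
gives

    ESJD(ℓ, d) = 2 (ℓ²/d) E[χ_d² Φ(−ℓ χ_d / (2√d))],
    acceptance(ℓ, d) = 2 E[Φ(−ℓ χ_d / (2√d))],

with χ_d chi-distributed with d degrees of freedom — independent of the
covariance structure. Maximizing over ℓ yields a *dimension-dependent*
guideline (ℓ̂ = 2.42 and 44% acceptance at d = 1, decreasing to ℓ̂ = 2.38
and ≈ 23.4% as d → ∞, recovering the 0.234 rule). The practical recipe:

    S_n = (ℓ̂ / √(d·n)) · M_n,    M_n M_nᵀ = (standardized observed information)⁻¹,

computable from a single MAP fit before the first chain is run.

The package provides:

* `theory` — quadrature/Monte-Carlo evaluation of the limiting-chain ESJD
  and acceptance for matched and isotropic proposals, their d → ∞ limits,
  and the AR(1) roughness constant L′;
* `tuning` — grid optimization of ℓ, the guideline table, and proposal
  scaling construction;
* `sampler` / `diagnostics` — a seeded RWM sampler, metric ESJD with
  batch-means errors, and minimum marginal ESS per iteration (Geyer
  estimator);
* `gaussian_study` — identity vs Cholesky preconditioning on Gaussian
  targets with AR(1) covariance ρ^|i−j|;
* `logistic` / `synthetic` — Bayesian logistic regression (MAP, observed
  information, preconditioned posterior sampling) on synthetic data
  emulating an n = 4866, d = 9 regression study;
* `cli` — `rwmtune table1 | tune | ar1-study | logistic-demo | generate-data`.

## Worked example

```python
import rwmtune as rt

# dimension-dependent guideline for d = 9
tuned = rt.optimize_ell(9, mode="cholesky")
print(tuned.ell_hat_rounded, round(100 * tuned.acceptance_at_opt, 2))
# 2.39 26.26

# synthetic logistic study: n = 4866, d = 9, AR(1) covariates
spec = rt.LogisticGenSpec(seed=5)
data = rt.generate_logistic(spec)
tuned, summary, fit = rt.tune_and_sample_posterior(
    data, mode="cholesky", n_steps=50_000, seed=11, ell=2.39)
print(round(summary.acceptance_rate, 3), round(summary.min_ess_per_iter, 3))
# 0.265 0.029
```

The first block says: for a 9-parameter model the ESJD-optimal step
multiplier is ℓ̂ = 2.39 and the limiting chain accepts 26.26% of proposals —
noticeably above 0.234, which is only the d → ∞ limit. The second block
runs the preconditioned sampler on the actual (finite-n) posterior of a
synthetic dataset of the same shape: the realized acceptance rate 0.265 is
within Monte-Carlo error of the limiting value, confirming the asymptotic
tuning is accurate at n ≈ 5000, and the chain delivers ≈ 0.029 effective
draws per iteration on its worst coordinate (the isotropic proposal
manages roughly half that on the same data).

Equivalent shell commands:

```bash
rwmtune table1 --dims 1,2,3,4,5,10,15,20,30,50 --out table1.csv
rwmtune ar1-study --rhos 0,0.3,0.6,0.8,0.9 --dims 5,10 --out ar1.csv
rwmtune logistic-demo --mode cholesky --out demo.json
```

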