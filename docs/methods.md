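# Methods

## Models

All six analysis methods are Bayesian linear models for IPD from a
pretest–posttest design; records are `(study, arm, yB, yF)` with
historical studies contributing control arms only.

**No borrowing.** ANCOVA on the new trial alone:
`yF = β0 + β1 yB + λ trt + ε`, `ε ~ N(0, σ²)`, priors
`β0, λ ~ N(0, 10⁴)`, `β1 ~ N(0, 10²)`, `σ² ~ Inv-Gamma(10⁻³, 10⁻³)`.

**Pooling.** The same regression on all records stacked (historical
`trt = 0`), with a single error variance. This is full borrowing with no
heterogeneity adjustment.

**Bivariate MAP (`mmap_cor`, `mmap_ind`).** Study-specific
`(β0j, β1j) ~ MVN((μ0, μ1)', Σβ)` with
`Σβ = [[τ0², ρτ0τ1], [ρτ0τ1, τ1²]]`, per-study error variances, and for
the analysis phase the new trial enters the exchangeable set as study
J+1 with the treatment term `λ·trt` (the meta-analytic-combined, MAC
form). `mmap_ind` pins `ρ = 0`.

**Univariate MAP (`umap_com`, `umap_sep`).** Random intercepts
`β0j ~ N(μ0, τ0²)` with either one baseline effect shared by all studies
including the new one (`umap_com`) or independent per-study baseline
effects with `N(0, 10²)` priors (`umap_sep`).

Hyperpriors (defaults): `μ0 ~ N(0, 10⁴)`, `μ1 ~ N(0, 10²)`,
`λ ~ N(0, 10⁴)`, `σ²_j ~ Inv-Gamma(10⁻³, 10⁻³)`, `ρ ~ U(−1, 0)` (the
intercept and baseline effect of the same outcome are expected to be
negatively correlated; a `U(−1, 1)` override is available), and
independent priors on the between-study SDs τ0, τ1 by a separation
strategy — never an inverse-Wishart on Σβ, whose variance constraints are
known to distort small-J estimates.

### Heterogeneity-prior elicitation

"Large" heterogeneity for a regression coefficient is a between-study SD
equal to the within-study SD, computed as the per-study standard error
times √n. The half-normal scale is set so the 95th percentile (more
generally, `1 − tail_prob`) equals the maximum within-study SD across the
historical trials; exponential and uniform families with the same tail
condition are provided for sensitivity analysis. `heterogeneity_scale`
returns the exact quantile-matched value; the simulation harness instead
hard-codes the conventional rounded scales 10 (intercept) and 0.36
(baseline effect), whose 95th percentiles sit at the "large" grid values
20 and 0.72.

### MAP prior and prior ESS

For a design-phase (historical-only) fit, each posterior draw of
`(μ0, μ1, τ0, τ1, ρ)` yields one predictive draw
`β0* = μ0 + τ0 z0`, `β1* = μ1 + τ1(ρ z0 + √(1−ρ²) z1)`; the
moment-matched normal summary of those draws is the MAP prior. The prior
ESS for each borrowed coefficient is `(V₀ / Vτ)·N` with `Vτ` the
MAP-prior variance and `V₀` the posterior variance of the coefficient in
a pooled (τ = 0) fit of the stacked historical controls with one common
error variance; skewness and excess kurtosis of the predictive draws are
reported so the user can judge the normal approximation this ratio relies
on. ESS uncertainty intervals are produced across simulation replicates,
not within a single dataset. The joint MAC fit is the default analysis
route; a two-step analysis that replaces the historical data by the
moment-matched MAP prior is an approximation and is not used for the
reported operating characteristics.

## Posterior computation

The models are linear-Gaussian given the variance parameters, so we use a
blocked Gibbs sampler rather than a general-purpose gradient sampler:

* study coefficients (the new trial's jointly with λ via an extra scalar
  block), grand means and error variances have exact conjugate updates;
* `(τ0, τ1, ρ)` are updated by random-walk Metropolis on log / logit
  scales with Robbins–Monro step adaptation during warmup (target
  acceptance 0.44, adaptation frozen afterwards);
* a subsequent ancillarity–sufficiency interweaving (ASIS) step re-draws
  `(μ0, τ0)` and `(μ1, τ1)` in the non-centred parameterization, where
  they are linear-regression coefficients given the standardized study
  deviates; the half-normal (and exponential/uniform) τ priors are
  conjugate there, giving truncated-normal draws.

The interweaving matters: a purely centred Gibbs scheme mixes very slowly
for `(μ, τ)` when τ is near zero — precisely the compatible-historical
regime where borrowing is strongest and the prior ESS is computed. With
ASIS the effective draw count for τ is a sizeable fraction of the kept
draws even at zero true heterogeneity.

Every update is vectorized over a leading batch axis holding chains and —
in the simulation harness — all replicate datasets of a scenario
simultaneously, so hundreds of MCMC runs advance in lock-step through a
few hundred numpy operations per iteration. Whole-scenario runs are
reproducible bit-for-bit from a master seed (data streams are spawned per
replicate; the sampler uses one batched stream).

Numerical safeguards: τ draws floored at 10⁻⁸; σ² clipped to
[10⁻¹², 10¹²] (relevant only for prior-only runs with the vague
inverse-gamma); truncated normals drawn through the upper-tail inverse
CDF, which stays accurate far into the tail; residual sums of squares
clamped at zero against cancellation.

Diagnostics: classic split R-hat per parameter (threshold 1.01), computed
vectorized in the simulation path and via arviz (together with bulk ESS)
in `Results.summary()`. Replicates whose treatment-effect chain exceeds
the threshold are counted and reported, never dropped. Default protocol
for single-dataset analyses: 4 chains × (1000 warmup + 4000 kept); the
simulation harness uses 2 chains × (500 + 1500), which keeps the
credible-interval Monte-Carlo error well below the decision noise at the
replicate counts used.

## Synthetic-data generator

`ScenarioConfig` emulates a mild-to-moderate Alzheimer's-disease
population with ADAS-cog as outcome: grand intercept 1.06, baseline
effect 1.16, `yB ~ N(24.53, 9.47²)`, residual SD 6.79, 60 subjects per
arm, J ∈ {3, 5} historical control arms, treatment effect 0 (null) or −3
points (a minimal clinically relevant 1-year change), between-study
correlation −0.9, and heterogeneity levels expressed as the ratio of the
between- to the within-study SD (≈20 for the intercept, ≈0.72 for the
baseline effect): No (0, 0), Small (2.5, 0.09), Moderate (5, 0.18),
Substantial (10, 0.36), Large (20, 0.72).

Two conventions exist for the new trial's own coefficients. Under
`new_trial_effects="fixed"` (the default) they sit at the grand means, so
heterogeneity is the displacement of the historical arms relative to the
trial being analyzed; under `"random"` the new trial also draws from the
between-study distribution, which roughly doubles the error of pooled
analyses under strong heterogeneity. The package's operating
characteristics are calibrated under the fixed convention.

The new trial's size defaults to 60 per arm — the single most
consequential choice the design leaves open — and is exposed as
`n_per_arm_new`.

What the generator does *not* emulate: missing follow-up (the data model
handles it, the generator never produces it), covariate differences
between trials, unequal study sizes, non-normal errors, or
treatment-by-baseline interaction. Passing tests therefore demonstrate
correctness of the machinery under exchangeable, normal, complete data —
not robustness of borrowing to real-world incomparability, which must be
argued on subject-matter grounds (comparability criteria) before any of
this applies.

## Operating characteristics

Per replicate the harness records the posterior mean, SD and equal-tailed
95% interval of λ; a replicate "rejects" when the interval excludes 0
(type I error under λ = 0, power under λ = −3). Aggregates: bias and
across-replicate SD/RMSE of the posterior mean (so `rmse² = bias² + sd²`
up to the n vs n−1 variance convention), plus the average posterior SD,
which is the quantity usually tabulated as "the SD of the treatment
effect" in method comparisons (borrowing makes it larger than the
across-replicate SD of the shrunken point estimate). The point estimator
is the posterior mean; the posterior median is available from the
replicate-level draws if preferred.

Desk-scale defaults (300 replicates, reduced chains) finish in seconds
per cell thanks to the batched sampler; replicate counts in the shipped
acceptance script (200–4000 per cell) were sized from the Monte-Carlo
standard error of each statistic (binomial for rates, `sd/√(2R)` for
SDs, heavier-tailed for the RMSE under large heterogeneity).

## Known limitations

* Two random effects only; extending to more coefficients needs a
  Cholesky-parameterized correlation matrix and is out of scope.
* No frequentist (ML/REML) estimation path: with J ≤ 5 the between-study
  covariance is barely identified and the priors above are integral to
  the method.
* The two-arm new trial must be analyzed jointly (MAC); a pure
  MAP-prior-then-analyze path is provided only as a normal approximation.
* Normal priors are centred at zero; non-zero prior means are not
  supported (they are never needed for these models).
* `umap_com` ignores the clustering of patients within studies for the
  baseline effect; it is included for comparison, and its known failure
  mode under large heterogeneity (worse than no borrowing) reproduces in
  the harness.
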