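# mvmap

Bayesian historical borrowing for pretest–posttest clinical trials:
multivariate **meta-analytic-predictive (MAP) priors** for ANCOVA models,
prior **effective sample size** (ESS) by the variance-ratio method, and an
**operating-characteristics simulation harness** (bias, SD, RMSE, type I
error, power).

## Who this is for

Trial statisticians designing or analyzing a randomized pretest–posttest
trial (e.g. a 12-month Alzheimer's disease trial with ADAS-cog measured at
baseline and follow-up) who have individual-participant data (IPD) from the
control arms of comparable historical trials and want to borrow that
information without inflating the type I error.

## The model

The new trial is analyzed with an ANCOVA,

```
yF_i = β0* + β1* yB_i + λ trt_i + ε_i,        ε_i ~ N(0, σ²),
```

where `yB`/`yF` are the baseline and follow-up outcomes and `λ` is the
treatment effect. Both the intercept `β0` and the baseline effect `β1`
influence the estimate of `λ`, so borrowing a single parameter is not
enough. The historical control arms j = 1…J are modelled jointly as

```
yF_ij = β0j + β1j yB_ij + ε_ij,               ε_ij ~ N(0, σ²_j),
(β0j, β1j)' ~ MVN( (μ0, μ1)', Σβ ),
Σβ = [[τ0², ρ τ0 τ1], [ρ τ0 τ1, τ1²]],
```

a one-stage bivariate random-effects meta-analysis on IPD. The predictive
distribution of the new trial's `(β0*, β1*)` given the posterior of
`(μ0, μ1, Σβ)` is the MAP prior; equivalently the historical and new data
can be fitted jointly (the meta-analytic-combined form, the package
default for analysis). Hyperpriors follow a separation strategy:
half-normal priors on the between-study SDs `τ0, τ1` scaled so that 5%
probability lies above the largest within-study SD (`se·√n`), a
Uniform(−1, 0) prior on the between-study correlation `ρ`, diffuse normals
on `μ0, μ1, λ` and vague inverse-gammas on the error variances.

Six analysis methods are implemented: `no_borrowing`, `mmap_cor`
(unstructured Σβ — the headline method), `mmap_ind` (ρ ≡ 0), `umap_com`
(random intercepts, one shared baseline effect), `umap_sep` (random
intercepts, independent per-study baseline effects) and `pooling` (stack
everything, one parameter set).

Information content of the MAP prior is reported as a prior ESS,
`n* = (V₀ / Vτ) · N`, where `V₀` is the posterior variance of the
coefficient under a zero-heterogeneity (pooled) fit of the N historical
controls and `Vτ` the MAP-prior variance.

Posterior sampling uses a blocked Gibbs sampler (all conditionals except
the heterogeneity block are conjugate) with adaptive Metropolis updates
for `(τ0, τ1, ρ)` and an ancillarity–sufficiency interweaving step that
keeps mixing fast when the heterogeneity is near zero. The sampler is
vectorized across chains *and* replicate datasets, so a full simulation
cell (hundreds of replicates × MCMC) runs in seconds.

## Worked example

```python
import numpy as np
from mvmap import (AncovaMAP, McmcSettings, ScenarioConfig, generate_dataset,
                   ess_workflow, simulation_grid_priors)

# synthetic IPD: 5 historical control arms (60 each) + a new 60/60 trial
ds = generate_dataset(ScenarioConfig(J=5, heterogeneity="No",
                                     lambda_true=-3.0, seed=42))

# design phase: how much is the historical information worth?
for e in ess_workflow(ds, "mmap_cor", priors=simulation_grid_priors(),
                      settings=McmcSettings(chains=2, warmup=500, draws=2000),
                      seed=1):
    print(f"{e.parameter}: ESS = {e.ess:.0f} of N = {e.N}")

# analysis phase: joint fit of historical + new data
res = AncovaMAP(ds, "mmap_cor", priors=simulation_grid_priors()).fit(
    settings=McmcSettings(chains=2, warmup=500, draws=2000), seed=2)
print(res.treatment_inference())
```

Output:

```
intercept: ESS = 57 of N = 300
baseline_effect: ESS = 68 of N = 300
lambda = -3.050 (SD 1.187), 95% CI [-5.451, -0.713] (excludes 0)
```

With five compatible historical arms the prior is worth roughly 60
patients per parameter, and the treatment-effect posterior SD (1.19) is
about 8% tighter than the no-borrowing analysis of the same data
(`AncovaMAP(ds, "no_borrowing", ...)` gives SD 1.29), while the 95%
credible interval correctly excludes zero (the true effect is −3).

The same workflow is available from the shell:

```bash
mvmap validate ipd.csv
mvmap elicit ipd.csv                  # data-driven heterogeneity priors
mvmap design  --data ipd.csv --method mmap-cor --seed 1 --out design/
mvmap analyze --data ipd.csv --seed 1
mvmap simulate --grid paper --reps 300 --seed 1 --out sim/
```

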