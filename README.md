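# prevconv

Bayesian interpolation of disease prevalence between misaligned areal
frameworks, using discrete process convolution with collateral morbidity and
ecological-covariate data.

## The problem

Chronic-disease prevalence registers are often kept for *service areas*
(e.g., GP practice populations, counts y_i with expected counts E_i) that do
not nest within the *neighbourhoods* (e.g., LSOAs) where health profiling is
needed.  Neighbourhoods, in turn, carry collateral information the service
areas lack: hospitalisation counts M_k that *reflect* local prevalence, and
an ecological risk factor x_k (a log air-quality index) that helps *explain*
it.  `prevconv` fits the joint model

    y_i ~ Po(E_i ρ_i),  log ρ_i = β₁ + β₂ X_L(s_i) + z₁(s_i) + e_i
    M_k ~ Po(G_k ν_k),  log ν_k = γ₁ + γ₂ ρ_k
    x_k ~ N(η₁ + z₂(t_k), σ²ₓ),  X_L(s_i) = η₁ + z₂(s_i)

where z₁, z₂ are kernel convolutions z(s) = Σⱼ κ(|s−uⱼ|) wⱼ of random
effects on a sparse regular grid (normal, exponential or Student-t kernels;
normal or t₅ grid processes), and e are heteroscedastic over-dispersion
residuals with log V = δ₁ + δ₂·(E/Ē).  Estimation is by adaptive
Metropolis-within-Gibbs MCMC; model variants are compared by per-stream DIC;
posterior draws of ρ_k yield exceedance probabilities Pr(ρ_k > 1), hotspot
flags, cluster-centre probabilities C_k over an adjacency structure, and
prevalence percentages.  See `docs/methods.md` for the full model, sampler
and design notes.

## Worked example

A full study-scale run (189 source areas, 562 neighbourhoods, 84 grid
points; a couple of minutes on one CPU):

```python
from prevconv import (ChainConfig, GeneratorConfig, ModelSpec,
                      gelman_rubin, generate_dataset, risk_summary, run_mcmc)

source, target, grid, truth = generate_dataset(GeneratorConfig(), seed=0)
draws = run_mcmc(source, target, grid, ModelSpec(),
                 ChainConfig(n_chains=2, n_iter=5000, seed=0))
print(draws.summary()[["parameter", "mean", "q2.5", "q97.5"]].head(4).round(3))
print("max PSRF:", round(max(gelman_rubin(draws).values()), 3))
summary = risk_summary(draws, target, regional_rate=0.046)
print(summary.n_hotspots, "hotspots;", summary.n_cluster_centres, "cluster centres")
print("mean prevalence %:", round(summary.table["prevalence_percent"].mean(), 2))
```

prints

```
  parameter   mean   q2.5  q97.5
0     beta1 -0.994 -1.567 -0.467
1     beta2  0.474  0.219  0.757
2    gamma1 -1.791 -1.864 -1.719
3    gamma2  0.329  0.269  0.394
max PSRF: 1.058
108 hotspots; 127 cluster centres
mean prevalence %: 3.73
```

The synthetic data were generated with β₂ = 0.31 (pollution effect on log
prevalence risk) and γ₂ = 0.38 (reflexive effect of prevalence on
hospitalisation risk); both 95% intervals cover their generating values, and
the tight positive γ₂ interval shows the hospitalisation stream informing
the interpolation.  β₁ is only identified jointly with the mean of the
latent field (the fit splits this realisation's field mean differently from
the generator), which is why its interval sits below the generating −0.25.
Hotspots are neighbourhoods with Pr(ρ_k > 1 | y, M, x) > 0.8; cluster
centres additionally require excess risk among their adjacent neighbourhoods
(C_k > 0.25); max PSRF < 1.1 says the two chains agree.

The `examples/` directory holds one short script per capability (kernels and
fields, the study-scale generator, fitting and DIC, risk classification).
A thin CLI mirrors the pipeline: `prevconv simulate | fit | assess |
classify | compare` (see `prevconv --help`).

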