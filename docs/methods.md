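# Methods

## The estimation problem

Chronic-disease prevalence is often recorded on a spatial framework that is
useless for neighbourhood profiling: in UK primary care, prevalence registers
are kept per GP practice, whose patients are scattered across many
neighbourhoods, while the neighbourhoods (LSOAs) carry no prevalence data of
their own.  `prevconv` interpolates relative prevalence from such *source*
areas to *target* neighbourhoods using two kinds of collateral data observed
on the target frame: a reflexive morbidity indicator (hospitalisation
counts, which reflect prevalence) and a formative ecological covariate (a
log air-quality index, which influences prevalence but is only observed for
neighbourhoods and must itself be interpolated to the source frame).

## Model

Counts on both frames are Poisson with expected-count offsets
(population × region-wide rate), so the modelled quantities are relative
risks with average ≈ 1:

* source prevalence: y_i ~ Po(E_i ρ_i),
  log ρ_i = β₁ + β₂ X_L(s_i) + z₁(s_i) + e_i
* target hospitalisation: M_k ~ Po(G_k ν_k),
  log ν_k = γ₁ + γ₂ ρ_k  — the relative prevalence enters on the *natural*
  scale, and log ρ_k = β₁ + β₂ x_k + z₁(t_k) + e_k
* air quality: x_k ~ N(η₁ + z₂(t_k), σ²ₓ), and the latent covariate at
  source centroids is X_L(s_i) = η₁ + z₂(s_i), deterministic given the
  current draw of (η₁, w₂).

z₁ (prevalence process) and z₂ (risk-factor process) are discrete process
convolutions over a shared regular grid of J points u_j:
z(s) = Σ_j κ(|s − u_j|/Δ) w_j, with Δ the grid spacing.  Kernel families:
normal exp(−d²/2α²), exponential exp(−d/η), and a two-dimensional Student-t
power law (1 + d²/(k·scale²))^(−(k+2)/2).  All kernels are standardised to
κ(0) = 1 and distances are measured in grid-spacing units; the kernel scale
and the grid-process variance are confounded if both are free, so the fitted
variants fix the kernel ("standard" form, scale 1) and estimate the process
variance.  Grid effects w_j are iid normal or Student-t (t(0, ν, σ²) with
σ² the squared scale; the heavy-tailed variants use ν = 5).  The four
standard variants are (normal | exponential kernel) × (normal | t₅ process),
with the same choice applied to both processes.

Residuals e are heteroscedastic, log V = δ₁ + δ₂·(E/Ē): the expected counts
are divided by their frame mean before entering the regression, so δ₂ is the
log-variance change per mean-sized area.  (With raw expected counts in the
hundreds, slope magnitudes of order 0.1 would produce astronomically large
variances; some such scaling is clearly needed and the frame mean is the
least arbitrary choice.  The scale is configurable.)

Latent target-frame prevalence counts would be Po(E_k ρ_k) draws carrying no
information beyond ρ_k; they are not sampled.

Priors: Normal(0, 1000) on β, γ, δ, η₁; Gamma(0.001, 0.001) on the three
precisions (grid processes and air-quality noise).  Both are configurable
via `PriorSpec`.

## Sampler

Estimation is adaptive random-walk Metropolis-within-Gibbs.  Scalar
coefficients move by random walk; grid effects move by single-site updates
with O(N+K) incremental cache updates; residual vectors move by vectorised
independent-site Metropolis; the precisions with Gamma full conditionals
(normal-process grid variances, air-quality variance) are drawn by conjugate
Gibbs, and the grid precisions under a t process by random walk on the log
scale.  Proposal scales adapt by a bounded Robbins–Monro recursion toward
0.44 acceptance during burn-in and are then frozen, so retained draws come
from a fixed kernel.  Per-chain seeds derive from the master seed by numpy
`SeedSequence` spawning; identical inputs give bitwise-identical draws.

The posterior of this model has several soft directions that plain
single-site sweeps cross very slowly, so the sampler adds dedicated joint
Metropolis moves, all symmetric and exact:

* intercept–field ridges (β₁ vs mean z₁, η₁ vs mean z₂): a coefficient
  shift paired with a compensating change of the whole w vector.  For β₁
  and β₂ the compensation is split between w₁ and the residuals by a small
  normal-equations solve, making the likelihood exactly invariant so only
  the priors decide acceptance;
* a (γ₁, γ₂) ridge move along the direction that keeps γ₁ + γ₂·mean(ρ)
  fixed, and a (γ₂, ρ-level) move that rescales γ₂ while shifting every
  target residual by the matching constant, leaving ν exactly invariant;
* a (δ₁, δ₂) ridge move (scaled offsets average one, so δ₁ + δ₂ is pinned
  while the difference is nearly flat), with an occasional ten-fold
  proposal-scale jump so the flat tail of the heteroscedasticity
  coefficients is traversed;
* global shift and rescale moves for each w vector, plus a block move in
  the low-singular-value subspace of the stacked kernel matrix, where the
  likelihood barely constrains w₁ and mixing is prior-driven;
* a near-conjugate block update of w₂: the x-stream likelihood in w₂ is
  Gaussian, so the whole vector is proposed from the x-stream + prior
  conditional and accepted with a Metropolis correction for the weak
  y-stream coupling (and for the process density under a t process).

One burn-in-only intervention deserves note.  Early in a run, with ρ ≈ 1
everywhere, the pair (γ₂, target-residual pattern) has two nearly symmetric
basins — the generating one, and a mirror basin with γ₂ of the wrong sign
and inflated residuals absorbing the hospitalisation signal.  The mirror
basin has far lower posterior density (~10² log units on typical synthetic
data) but is locally sticky, and chains choose a basin essentially at random
if the residuals are free from iteration one.  The sampler therefore keeps
e_target frozen at its (near-zero) initial value for the first half of
burn-in, so the target-frame risk pattern initially comes from the shared
field and the covariate, which identifies the basin from data.  Retained
draws always come from the unmodified kernel.

Convergence is assessed by the multi-chain potential scale reduction factor
(PSRF): W the mean within-chain variance, B/n the variance of chain means,
PSRF = sqrt(((n−1)/n·W + (1+1/m)·B/n)/W), floored at 1; the pipeline's
verdict threshold is the conventional 1.1.

## Model assessment

Fit is reported per observation stream because the three streams are not
commensurable.  Poisson streams use the saturated deviance
2 Σ[y log(y/μ) − (y − μ)] (zero at a perfect fit, 0·log 0 = 0); the Gaussian
stream uses −2 × log likelihood.  DIC = D̄ + pD with pD = D̄ − D(θ̄); the
plug-in deviance is evaluated at the posterior mean of the *fitted means*
(mean of E·ρ draws, mean of μₓ draws with mean σ²ₓ), not at parameter-wise
posterior means, which avoids the log-scale Jensen ambiguity; pD may come
out negative and is reported as computed.

## Risk classification

From retained draws of ρ_k: exceedance probabilities
p_k = Pr(ρ_k > 1 | y, M, x); hotspot flags p_k > 0.8 (strict, threshold
configurable, 0.9 also conventional); cluster-centre probabilities
C_k = E[J_k · (1/L_k) Σ_{l∈A_k} J_l] with J_k = I(ρ_k > 1) over the
adjacency set A_k, which satisfy C_k ≤ p_k; cluster flags C_k > 0.25
(attainable exactly when the area and at least one of up to four neighbours
jointly exceed).  For synthetic geographies the adjacency is symmetric
5-nearest-neighbour on centroids; real adjacency files are accepted as edge
lists.  Prevalence percentages are 100 × regional rate × ρ_k per draw, with
distributional summaries (mean, median, skewness, percentiles 1/5/95/99)
taken over the per-area posterior means.

## Synthetic data

The generator reproduces the structure of the motivating study region:
a 22 × 12 km region, 562 clustered neighbourhood centroids (parent–offspring
process, 14 parents, 1.2 km offspring spread) with ~1,500 residents each
(log-normal, σ_log = 0.25), 189 service-area centroids subsampled from the
neighbourhood locations and jittered 0.5 km (service areas sit among the
neighbourhoods they serve), and an 84-point regular grid at 2 km spacing.
Default structural coefficients sit at the posterior means reported for the
normal/normal variant of the motivating analysis: β = (−0.25, 0.31),
γ = (−1.82, 0.38), δ = (−3.37, 0.03) on the scaled-offset form; η₁ = 0;
var_w1 = var_w2 = 0.25, σ²ₓ = 0.01; regional prevalence rate 0.046 and
hospitalisation rate 0.008 (chosen so neighbourhood admission counts average
≈ 3, the magnitude implied by the reported per-area deviance scale).
Everything is seeded and bitwise reproducible.

One deliberate simplification: expected counts use the *configured* regional
rate, whereas in a real study the region-wide rate is computed from the data
(making relative risks average one by construction).  A single realisation
of the latent field therefore shifts the region's realised mean relative
risk away from one, and with it the intercept/field-mean split and the
realised mean prevalence percentage, by up to a few tenths on the log scale
between seeds.

What the generator does *not* emulate: real road/population rasters, actual
London geography, age/sex structure, spatially correlated grid effects, or
misreporting in the registers.  Passing tests therefore demonstrate that the
method recovers the data-generating process *of its own model class* at the
stated sizes — not that the model is correct for any real region.

## Test conditions and problem sizes

Test and acceptance runs use sizes chosen as the package's own compromise
between statistical resolution and a desk-scale compute budget:

* parameter recovery: 60 source / 150 target areas, 5 × 5 grid, ten
  replicates, one chain of 4,000 per replicate; equal-tailed 95% intervals
  cover the generating coefficients in ≥ 8/10 replicates and the posterior
  mean of γ₂ has the generating sign in ≥ 9/10;
* convergence: two chains of 5,000 on the default study-scale fixture
  (189/562/84), PSRF < 1.1 for all structural parameters.  At the reduced
  scale the heteroscedasticity coefficients are weakly identified on some
  datasets and the diagnostic honestly fluctuates; the full-size frame pins
  them down;
* calibration: simulation-based calibration at toy scale (16 source and 30
  target areas on a 4 × 2 km region, 6 grid points; see
  `prevconv.calibration.TOY_CONFIG`) with
  proper informative priors (coefficient sd 0.15, precisions Gamma(20, 4))
  shared by generation and fitting; 50 generate→fit cycles, ranks of β₂ and
  γ₂ among 24 thinned draws tested for uniformity by χ² at α = 0.01;
* model discrimination: y-stream DIC comparison between the normal-process
  and t₅-process variants on data generated under the former.  The
  information separating the two process families is intrinsically small —
  of order J × KL(N‖t₅) ≈ 0.02·J deviance units, against ~0.5–1 units of
  DIC Monte-Carlo noise per fit — so the discrimination fixture keeps a
  dense 7 × 7 grid (the signal scales with the number of data-informed grid
  effects) while reducing the area counts, gives the fields appreciable
  amplitude (var_w = 0.8; the process family is only visible when the
  fields are large), and lowers the reflexive slope to 0.2 so exp(γ₂ρ)
  stays numerically tame.  Even so this is a soft majority check (≥ 6/10),
  mirroring the motivating analysis where the variants differ by about one
  deviance unit in ~377 and per-stream winners disagree.

## Numerical choices and degenerate inputs

* ν = exp(γ₁ + γ₂ρ) can overflow for extreme ρ; proposals producing
  non-finite likelihood changes are rejected, and ν may legitimately
  underflow to zero for zero-count areas (deviance bookkeeping floors the
  mean at 1e-300, where the saturated deviance term is zero).
* The heteroscedasticity coefficients have a genuinely flat, curved ridge:
  δ₁ → −∞ with residuals → 0 changes the likelihood only through the lost
  over-dispersion fit, so under the diffuse prior their marginal posterior
  can be extremely wide when the data carry little over-dispersion
  information.  Proposal-direction weights involving 1/V are clipped, and
  adapted proposal scales are bounded, so excursions toward that region
  cannot permanently degrade other blocks.
* Strict inequalities at classification thresholds (flag iff probability >
  threshold), documented because boundary ties are measure-zero but
  test-relevant.
* Isolated areas (empty adjacency) receive cluster probability 0 with a
  warning rather than an error.
* The Student-t kernel's degrees of freedom are fixed (default 5,
  configurable), never estimated: no fitted variant uses the t kernel and
  joint estimation with the process variance would be poorly identified.

## Known limitations

* The reflexive link log ν = γ₁ + γ₂ρ on the natural ρ scale is explosive
  under large field variance; generator settings keep exp(γ₂ρ) finite, and
  users supplying their own data at very high relative risks should expect
  rejection-dominated behaviour of the hospitalisation block.
* e_target is weakly identified from the hospitalisation stream alone
  (one count per area); its prior and the shared δ regression carry much of
  the weight.
* DIC comparisons between kernel/process variants at desk scale are mostly
  noise (see above); they are machinery for the full-scale analysis, not a
  reliable small-sample selector.
* Coordinates are assumed planar km; no CRS handling.
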