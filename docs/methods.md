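# Methods

This note records the statistical models, the numerical choices behind the
sampler, what the synthetic-data generators do and do not emulate, and the
design decisions taken where more than one reasonable choice existed.

## Models

All models are location-scale hierarchical regressions: linear predictors
for the mean (location, identity link) and for the log residual SD (scale,
log link), with study-level varying effects allowed in either part.

**Meta-analytic family (`gaussian_known_variance`).** Each case `ij`
carries a known sampling variance `s²_ij` (for Fisher-z effect sizes,
`1/(n−3)`; `|r| ≥ 1` is rejected rather than clamped because the transform
is infinite there and clamping silently corrupts the variance). The
observation model is `z_ij ~ N(μ_ij, s²_ij + σ²_ij)`; `σ_ij` is absent in
the homoscedastic model (`m1_1`, which instead has a nested case-level
intercept with SD ω) and otherwise modelled on the log scale with a grain
covariate (`m1_2`), extent-category cell means without intercept (`m1_3`),
or study-varying intercepts with SD ζ (`m1_4`). `m1_2`/`m1_3` drop the
case-level intercept: σ and ω describe the same stratum of variation and
are not jointly identified.

**Lognormal family.** `S_ij ~ lognormal(μ_ij, σ²_ij)` for strictly positive
effort-standardized richness; the fragment-size covariate is natural-log
transformed and centred once on the full dataset; the centring constant is
frozen with the dataset so cross-validation folds never redefine the
covariate. The five presets grade from correlated location
intercept/slope with constant σ (`m2_1`) up to a single 4×4 MVN across all
four varying effects (`m2_5`). When a scale slope is present the scale
linear predictor is evaluated at each observation's covariate value, so σ
varies by fragment; the study index on σ in the simpler models reflects
study-varying intercepts only.

Observation log densities for the lognormal family are densities of `S`
itself (normal density of `log S` plus the `−log S` Jacobian). The Jacobian
term is constant across models for fixed data, so it does not affect model
ranking, but it makes reported elpd values proper data-scale densities.

## Priors

Defaults are weakly informative and overridable per role through
`PriorSet`:

* location intercept — Student-t(3, median(y), 2.5·1.4826·MAD(y)) (the MAD
  scale is floored at 0.4 so degenerate data keep a proper prior);
* location and scale slopes — Normal(0, 1);
* scale intercept / cell-means coefficients — Student-t(3, 0, 2.5) on the
  log-SD scale;
* all standard deviations (τ, ω, ζ, σ-blocks) — half-Student-t(3, 0, 2.5);
* correlation matrices — LKJ(η = 1), implemented exactly through its C-vine
  representation: the canonical partial correlation in column `j` of a
  `d×d` matrix has `(z+1)/2 ~ Beta(a_j, a_j)` with `a_j = η + (d−1−j)/2`,
  which induces `det(R)^{η−1}` with a closed-form normalizer (for `d = 3`,
  `η = 1` the normalizer is the elliptope volume π²/2, verified
  numerically).

The constant-σ lognormal model is parameterized through an intercept-only
scale predictor (`log σ = β₀^σ`) so every σ-bearing model shares one code
path; `σ_resid` is exposed as a derived quantity.

## Sampler

No probabilistic-programming backend is used: the posterior is sampled by a
built-in multinomial No-U-Turn sampler with dual-averaging step-size
adaptation (default target acceptance 0.95) and windowed diagonal
mass-matrix estimation, running on an unconstrained vector with analytic
gradients assembled by hand (and pinned by finite-difference tests for all
nine models).

Numerical choices that matter:

* **Non-centred varying effects.** Study effects enter as standardized
  draws scaled by `diag(s)·L` (L the correlation Cholesky factor), removing
  the funnel geometry of hierarchical scales.
* **Analytic case-effect marginalization.** The nested case-level
  intercepts of `m1_1` are one coordinate per observation; because the
  model is Gaussian with known variances they are integrated out exactly
  (observation variance gains ω²) and re-drawn per posterior draw from
  their conjugate Gaussian conditional. This shrinks the sampled dimension
  by the number of observations at zero approximation cost.
* **Transforms.** SDs are log-transformed; correlation matrices pass
  through `tanh`-CPCs; all change-of-variable terms are included and the
  identity `logpost(θ) = log_joint(natural(θ)) + Jacobians` is tested
  directly.
* **Initialization.** Starting points are prior-informed values jittered
  toward zero; up to 10 retries on a non-finite density. Divergences
  (energy error > 1000) are counted and reported, never silently dropped.
* **Determinism.** All randomness descends from one user seed through
  `numpy.random.SeedSequence` spawning (chains, folds, replicates,
  marginalization draws), so identical configurations reproduce identical
  draws on the same platform.
* Default MCMC settings are 4 chains × (1000 warmup + 1000 samples); the
  test-suite and acceptance studies use 1–2 chains with 120–300 warmup and
  150–300 sampling iterations at acceptance target 0.85 — the package's
  reduced desk-scale settings, stated with each study below. The SBC study
  uses the longer end of that range (200 warmup / 300 samples) because rank
  statistics need healthy per-parameter effective sample sizes.

Diagnostics (rank-normalized split R-hat, bulk ESS) come from ArviZ; a
single chain reports R-hat as unavailable rather than a number.

## Predictive evaluation and cross validation

`elpd_conditional` computes `log((1/S) Σ_s p(y_i | θ_s))` with log-sum-exp
stabilization, using each draw's fitted study effects. A held-out
observation is always a new case, so models with a case-level intercept
integrate it analytically (variance + ω²). `elpd_marginal` handles unseen
studies: per posterior draw, new-study effects are sampled (default 100
replicates per draw) from the population MVN implied by that draw's SDs and
correlations; densities are averaged over those replicates before the
across-draw average. Totals use `SE = sd(pointwise) · √N`; model
differences use the SE of the pointwise *paired* differences, which is what
"one standard error" must mean for comparability.

Stratified k-fold (default k = 10) spreads each study's cases over
cyclically consecutive folds from a seeded random start, so per-study fold
counts differ by at most one. Observations whose study is entirely absent
from a training fold (single-case studies) are scored marginally. For the
extent cell-means model, the assignment is re-drawn (≤ 20 sub-seeds) until
every training fold contains every extent bin; if that fails the fit
proceeds and the uncovered bin's coefficient follows its prior. Folds are
shared across models so pointwise differences stay paired.

Leave-one-group-out refits with each study held out and scores marginally.
`max_heldout` optionally restricts scoring to a seeded subset of studies
(identical across models) — the estimator is then the elpd on a random
study subsample, which preserves paired model comparisons at a fraction of
the refit cost; the simulation studies below use it and state the subset
size. The one-SE rule selects the least complex qualifying model
(complexity = count of free top-level parameters; ties break toward the
earlier model in the canonical numbering).

## Simulation-based calibration

`run_posterior_sbc` fits the model to the data, builds generating
distributions matched to the empirical posterior (independent normals for
location-type parameters; half-normals matched in *mean* to posterior SDs
— one-parameter families cannot match mean and SD simultaneously;
correlation matrices are drawn from their LKJ prior), then repeatedly
simulates datasets of the same size/shape/structure, refits, and records
the rank of each true top-level scalar among L = 99 thinned draws plus
central-interval coverage at 50% and 90%. `self_consistency=True` draws the
truth from the fitting priors themselves (which must then be explicit and
data-independent), the regime in which rank uniformity is exact in theory.
Refit failures are excluded and counted, never absorbed.

## Synthetic-data generators

`simulate_meta` mirrors the structure of a 101-study / ~204-effect-size
meta-analytic compilation: case counts per study from a zero-truncated
geometric (mean 2) to reproduce the few-cases-per-study skew, per-case
sample sizes uniform on [10, 300] driving `var_z = 1/(n−3)`, log grain
uniform over roughly eleven natural-log units, and extent categories
weighted toward small extents. `simulate_fragments` mirrors a 123-study /
~1500-fragment compilation with 4–30 fragments per study and lognormal-ish
fragment sizes spanning ~13 log units, centred after generation. Both are
pure functions of (design, seed) and return the realized ground truth.

What they do *not* emulate: publication bias, non-normal sampling error in
small-n correlations, measurement error in covariates, spatial or
phylogenetic dependence between studies, and taxon-dependent effect sizes
(taxon labels are decorative covariates). Passing recovery tests therefore
demonstrates correctness of the inference machinery under the stated
generative laws, not robustness to the messiness of real compilations.

## Study sizes used by the test suite and acceptance script

Chosen as the package's desk-scale defaults:

* density and elpd oracles — ≤ 5 studies / ≤ 15 observations, exact
  tolerances (1e-10, 1e-12; quadrature to 2 decimals);
* parameter recovery — m1_2 at truth (β₀ = 0.2, β₁ = 0.05, τ = 0.2,
  β₀^σ = −1.2, β₁^σ = −0.05), 80 studies × 3 cases, and m2_2 at truth
  (β₀ = 2.0, β₁ = 0.25, σ₀ᵢ = 0.4, σ₁ᵢ = 0.15, ρ = −0.3, β₀^σ = −0.7,
  σ₀ᵢ^σ = 0.4), 80 studies × 5 fragments; 20 replicates, plus matching runs
  at 320 studies for the √n error-scaling check;
* model discrimination — data from m1_4 at ζ = 0.8, 60 studies × 3 cases;
  LOGO scored on a seeded 10-study subset per replicate, 10 replicates;
* SBC self-consistency — m1_2 on 12 studies × 2 cases, 200 simulations,
  explicit normal/half-normal priors shared by generator and fit;
* replica pipeline — 101 studies / 204 effect sizes generated from m1_2
  with scale slope −0.03, round-tripped through the deposited column format.

## Known limitations

* The sampler is single-process; chains run sequentially.
* Marginal elpd is Monte-Carlo (no closed form once the scale has varying
  effects); its precision is governed by `re_draws`.
* PSIS/importance-sampling approximations to leave-one-out are deliberately
  not provided; refitting is the supported path.
* Cell-means scale models keep a fixed global category set; a category
  never observed anywhere in the data is reported at its prior.
* The one-SE rule's comparability threshold is exactly one paired-difference
  SE; other published variants (e.g. thresholds on information criteria)
  are out of scope.
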