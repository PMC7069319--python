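# Methods

## Scope and model families

The package benchmarks MCMC strategies on four Bayesian hierarchical model
families for species occurrence and abundance, each in a factorial of
{more hierarchical (+H), less hierarchical (−H)} × {latent states sampled,
latent states integrated} variants:

1. **Single-species multiseason (dynamic) occupancy.** Initial occupancy
   `z_{i,1} ~ Bern(ψ1)`, Markov transitions
   `z_{i,t+1} ~ Bern(z φ_t + (1−z) γ_t)`, detections
   `y_{itj} ~ Bern(z_{i,t} p_t)`. +H places year-specific `φ_t, γ_t, p_t` on
   the logit scale as `Normal(μ, σ)` random effects (7 top-level parameters:
   `ψ1` and three (μ, σ) pairs); −H uses constant rates (4 top-level).
2. **Multispecies single-season occupancy.** Occupancy and detection logits
   are linear in site/visit covariates with species-specific intercepts and
   slopes. The default covariate configuration is 4 occupancy + 4 detection
   slopes; +H draws all 10 coefficient families from community
   `Normal(μ_k, σ_k)` distributions (20 hyperparameters), −H shares the 10
   coefficients across species.
3. **Multispecies multiseason occupancy.** Per-species dynamic occupancy with
   covariate-dependent persistence, colonization and detection. Eleven
   coefficient families (persistence intercept + 3 slopes, colonization
   intercept + 3 slopes, detection intercept + 2 slopes) are
   species-specific, hierarchical in +H (22 hyperparameters); 16 parameters
   (initial-occupancy intercept + 5 slopes, 3 + 3 shared
   persistence/colonization slopes, 4 shared detection slopes) are always
   shared. Totals: 38 (+H) / 27 (−H).
4. **Zero-inflated N-mixture.** `suit_i ~ Bern(θ)`,
   `N_i ~ Pois(suit_i · λ_i)`, `y_{ij} ~ Binom(N_i, p_{ij})`, with
   `log λ` linear in 9 site covariates and `logit p` in 13 site/survey
   covariates (25 top-level with θ). +H adds site random effects on
   abundance and detection and a survey random effect on detection, with
   three sd hyperparameters (28 top-level).

The published design summaries pin the dimensions and, for the single-species
design, the detectability scenarios; they do not publish the exact covariate
lists of the original case studies. The covariate counts above are package
defaults chosen so the declared top-level parameter totals are exact
contracts (they are configurable in `ModelConfig`).

## Latent-state marginalization

Each family has a closed-form sum over its discrete latent states:

* **Single-season occupancy:**
  `log[ψ Π_j Bern(y_j|p_j) + (1−ψ) 1{no detections}]` per (species,) site.
* **Dynamic occupancy:** the two-state HMM forward recursion over seasons,
  carried entirely in log space with `logaddexp` (a 15-season visit product
  underflows in linear space). Transition rows are `(1−γ, γ)` from the empty
  state and `(1−φ, φ)` from the occupied state; the emission for an
  unoccupied season is an indicator of no detections.
* **Zero-inflated N-mixture:**
  `log[(1−θ) 1{all y=0} + θ Σ_N Pois(N|λ) Π_j Binom(y_j|N,p_j)]`. The
  summation range uses the exact conditional `N − y | y ~ Pois(λ(1−p))`:
  lower bound `min_j (y_j + Q(10⁻⁵))` floored at `max_j y_j`, upper bound
  `max_j (y_j + Q(1−10⁻⁵))`. Successive summands are obtained from the
  closed-form `N → N+1` ratio (no factorial recomputation) and accumulated
  by log-sum-exp. The suitability indicator is folded into the same
  expression, so the marginalized variant samples no discrete states at all.

Missing visits contribute a factor of one (they are skipped, never imputed).
Tests verify each marginal against brute-force enumeration at 1e-10 relative
tolerance, and probability normalization over all data outcomes on tiny
designs at 1e-8. The N-mixture normalization test supplies a wide explicit
range because the quantile rule itself truncates ~1e-5 of conditional mass —
that truncation is tested separately (≥ 1−1e-4 of a wide-range sum).

## Model representation and delta evaluation

A model is a list of named parameter arrays plus additive log-density terms
with explicit dependency lists (optionally element-wise, used for per-site
latent states). Updating one scalar re-evaluates only the affected terms;
the chain state caches per-term values so each proposal touches each
affected term once. `-inf` is the single sentinel for impossible states;
NaN from a term raises. Probability-scale parameters are sampled on their
natural scale with support enforcement by `-inf` rejection, keeping priors
exactly as stated rather than transforming to the logit scale.

In latent-sampled variants, any latent forced by the data (a detected
site-season implies occupancy; a positive count implies suitability) is
treated as data and not sampled, so realized sampled-latent counts are
data-dependent tallies reported by the simulators rather than fixed
constants.

## Samplers and adaptation

* **ARWMH** (scalar adaptive random-walk Metropolis–Hastings): normal
  proposal centered at the current value; scale multiplied by
  `exp(g (r − 0.44))` every 200 iterations, `g = adapt_count^{-0.8}`.
* **Slice** (scalar, stepping-out/shrinkage): slice level `log f(x₀) −
  Exp(1)`; initial width 1, expansion capped at 100 steps, contraction at
  1000 (then a numerical error with diagnostics); width adapts toward twice
  the mean absolute jump with the same diminishing gain. Intended for
  unimodal conditionals (the caller's responsibility).
* **Computational Gibbs** (binary/categorical): evaluates every support
  value, normalizes, samples the exact conditional.
* **Discrete slice** (unbounded non-negative integers, e.g. latent
  abundances): the slice procedure on the integer lattice.
* **block_RW**: joint multivariate-normal proposal `x + s L ε`; `s` adapts
  toward acceptance 0.234 and the proposal covariance toward the
  (regularized) empirical covariance once 1,000 samples have accumulated;
  loss of positive definiteness resets to a scaled identity with a warning.
* **block_AFSS** (automated-factor slice sampler): univariate slice updates
  along the eigenvectors of the accumulated empirical covariance, widths
  seeded at twice the square-root eigenvalues; factors are recomputed every
  1,000 iterations up to iteration 25,000 and then frozen, so the high
  per-iteration cost of the factor updates terminates.

The acceptance-rate targets (0.44 scalar, 0.234 block), window length 200,
and gain exponent 0.8 follow standard adaptive-MCMC practice; they are not
prescribed by the benchmark designs and are recorded in run output.
Adaptation is never disabled mid-run (benchmarks are single continuous
chains); diagnostics instead drop a configurable burn-in (default 10%).

Assignment strategies: `nimble_default` (ARWMH for continuous scalars,
computational Gibbs for binary/categorical, discrete slice for unbounded
integers), `jags_like` (slice for continuous scalars, computational Gibbs
for finite-support discrete, discrete slice for infinite-support discrete),
and the blocking strategies, which add year-wise (φ_t, γ_t) pairs
(single-species multiseason; the −H variant blocks the single scalar pair),
one intercepts+slopes block per species (multispecies families; −H falls
back to one block of the shared coefficients), or a single
abundance-intercept+slopes block (N-mixture), with everything else on
`nimble_default` rules. Year pairs are blocked on the sampled (natural
logit) scale. Hyperparameters stay scalar-sampled in blocked strategies.

## Priors and initialization

Nearly flat `Normal(0, 100²)` priors on location hyperparameters,
`Uniform(0, 100)` on sd hyperparameters, `Uniform(0, 1)` on
probability-scale scalars; the N-mixture family uses narrower
`Normal(0, 10²)` coefficient priors. Initial values are drawn from priors,
except that sds start at 1 and locations with prior sd > 10 are drawn from a
standard normal (a draw from a near-flat prior is an absurd starting point);
latent occupancy starts at a fair coin where free, abundances at the
observed maximum plus Poisson jitter, suitability at 1 to avoid
contradictory (unsuitable, N > 0) starts. Initialization redraws up to 100
times for a finite posterior, then raises.

## Efficiency metric and diagnostics

ESS uses the Geyer initial-monotone-positive-sequence truncation of the
autocovariance sum (FFT autocovariances via statsmodels); it has the AR(1)
closed-form oracle `ESS/n → (1−ρ)/(1+ρ)` and is cross-checked against an
independent library implementation in tests. Efficiency is ESS divided by
the sampling-loop wall time only (model building and initialization are
preparation, not algorithm); reports also carry hardware-independent
ESS/iteration, which is what automated comparisons assert — ESS/second is
reported but never thresholded. The minimum over monitored parameters
summarizes a run (ties broken lexicographically for determinism), and
`1000/efficiency` is rendered as days/min/s at one decimal. The Geweke
statistic compares the first 10% and last 50% window means with
spectral-density-at-zero variance estimates from the same truncated
autocovariance sum. Cross-formulation agreement is checked as
`|Δ posterior mean| / pooled sd` (flag threshold 3) plus two-sample
Kolmogorov–Smirnov statistics. Trace plots are for human review only; there
is no programmatic analogue of visual chain inspection.

## Synthetic data

The simulators draw from exactly the models the builders fit, at the four
designs' dimensions, and return the generating truth plus realized tallies
(possible detections, latents a sampled-latent chain must update).
Detectability scenarios for the single-species design are p = 0.73 (high)
and p = 0.27 (low); the remaining generating values are not pinned by the
design and are fixed once in the versioned `data/sim_defaults.json` fixture:
ψ1 = 0.6, φ = 0.7, γ = 0.15 — a mid-range initial occupancy with strong
persistence and modest colonization, typical of the bird surveys these
designs emulate. Covariates are simulated standard normal (standardized by
construction); community hyperparameters are moderate so occupancy and
detection stay away from 0/1.

What the simulators do *not* emulate: spatial covariate fields or
autocorrelation, phenology-dependent detection, observer effects, and the
specific covariate sets of the real bird/bee/great-tit studies. Passing
recovery and agreement tests therefore demonstrates correctness of the
samplers and likelihoods under the assumed models, not robustness to the
model misspecification real surveys entail.

## Problem sizes in the test suite

Full benchmark runs default to 300,000 iterations with no thinning; the
package's own test suite and the recovery script use scaled-down runs chosen
as the smallest sizes at which the properties under test are
well-identified: recovery of p at the full 100 × 15 × 5 design with 20,000
iterations (the detection probability is informed by 7,500 Bernoulli
outcomes, so its posterior sd ≈ 0.01 and a ±0.03 check is meaningful);
agreement and directional-efficiency checks at 25–30 sites, 5–6 seasons,
3 visits with 4,000–8,000 iterations; sampler invariance on closed-form toy
targets. The directional check asserts a majority over 3 seeded replicates
because per-iteration ESS comparisons at this scale retain Monte-Carlo
noise.

## Known limitations

* No conjugate (analytic) Gibbs sampling, Hamiltonian/NUTS, automated
  blocking search, multi-state (>2) occupancy HMMs, or open-population
  N-mixture dynamics.
* ESS and efficiency are parameterization-dependent; the package reports the
  monitored parameters on their sampled scale only.
* Single-chain runs by default; the agreement checks run multiple
  independent chains, but no R-hat style multi-chain diagnostic is provided.
* The marginalized N-mixture likelihood recomputes its summation bounds at
  every evaluation; for very large λ this is the dominant cost, which is
  precisely the regime where sampling the latent abundances can win.
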