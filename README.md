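# hiermcmc

An MCMC engine and benchmarking toolkit for the hierarchical models most
widely used to analyze species occurrence and abundance data: single-species
dynamic (multiseason) occupancy, multispecies single- and multiseason
occupancy, and zero-inflated N-mixture models. It is aimed at quantitative
ecologists and methodologists who want to understand — and measure — how MCMC
efficiency for these models depends on model formulation (more vs. less
hierarchical structure), how the discrete latent states are handled (sampled
vs. analytically integrated out), and the sampling strategy (univariate vs.
block samplers, different default assignment rules).

## The models and the computational question

Occupancy models separate true presence `z ∈ {0,1}` from imperfect detection:
within a closed season, visit-level detections are `y_j ~ Bern(z·p_j)` and
occupancy is `z ~ Bern(ψ)`. Dynamic occupancy adds Markov dynamics across
seasons with persistence `φ` and colonization `γ`:

    z_{t+1} | z_t ~ Bern(z_t φ_t + (1 − z_t) γ_t).

N-mixture models replace the binary state with a latent abundance
`N ~ Pois(λ)` observed through repeated counts `y_j ~ Binom(N, p_j)`; the
zero-inflated variant adds a suitability probability `θ` for structural
zeros. Fitted by MCMC, these models carry hundreds to thousands of discrete
latent dimensions. Each latent state can be *sampled* — or *integrated out*
analytically, so the chain updates only top-level parameters:

* single-season occupancy: sum over the two states,
  `ψ Π_j Bern(y_j|p_j) + (1 − ψ) 1{no detections}`;
* dynamic occupancy: a two-state hidden-Markov-model forward recursion
  through the seasons of a site;
* N-mixture: a sum over `N` bounded by extreme quantiles of
  `N − y | y ~ Pois(λ(1 − p))`, accumulated with the closed-form
  `N → N+1` term ratio.

The toolkit implements both formulations of every model, five sampler kinds
(adaptive random-walk Metropolis–Hastings, slice, computational Gibbs for
enumerable discrete states, integer-lattice slice for unbounded discrete
states, and two block samplers: adaptive multivariate random walk and the
automated-factor slice sampler), two default assignment conventions
(`nimble_default`, `jags_like`) plus per-model blocking plans, and the
benchmark metric

    efficiency(parameter) = ESS / seconds,   summarized by its minimum,

where ESS is the effective sample size (Geyer initial-monotone-sequence
estimator). `1000/efficiency` converts this to the waiting time for 1,000
effectively independent samples of the slowest-mixing parameter.

Everything runs on synthetic data from the built-in simulators, which emulate
the four survey designs (e.g. 100 sites × 15 years × 5 visits at high
p = 0.73 or low p = 0.27 detectability for the single-species design).

## Worked example

Simulate the single-species design, fit the latent-state-integrated
less-hierarchical model, and read off the efficiency report:

```sh
$ hiermcmc run --model-kind dynocc_single --nsite 10 --nyear 4 --nvisit 3 \
      --niter 2000 --out results/demo
min efficiency 535.1 ESS/s (0.1072 ESS/iter) at gamma; 1000 effective samples in 1.9 s
  {'kind': 'arwmh', 'target': 'psi1[0]', 'steps': 2000, 'scale': 0.501..., 'accept_rate': 0.278}
  ...
```

The chain updated four top-level parameters (`psi1`, `phi`, `gamma`, `p`) and
no latent states; colonization `gamma` mixed slowest, and at this efficiency
1,000 effectively independent draws of it take about 1.9 s. The same library
call in Python:

```python
import hiermcmc as hm

sim = hm.sim_dynocc(scenario="high", seed=42)       # p = 0.73 truth
cfg = hm.ModelConfig.for_kind("dynocc_single")
cfg.hierarchical, cfg.marginalize = False, True
model = hm.build_model(cfg, sim.data)
plan = hm.assign_samplers(model, "nimble_default")
res = hm.run_mcmc(model, plan, niter=20000, seed=43)
p = res.samples[2000:, list(res.columns).index("p")]
print(round(p.mean(), 4))                            # 0.7395 on this seed
```

The posterior mean of detection probability lands within a few hundredths of
the generating 0.73. `hiermcmc simulate` writes long-format CSV data with a
truth sidecar, and `hiermcmc report` collects per-run reports into a summary
table and minimum-efficiency bar charts grouped by model variant.

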