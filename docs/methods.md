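# Methods

## Model

The agent is an opponent actor-critic of the basal ganglia. One critic and
two actors learn from the same reward prediction error (RPE); a meta-critic
summarizes environmental reward richness and sets a dopamine-like gain on
the two actors' contributions to choice.

**Critic.** A single state value `V` is updated by a delta rule,
`V ← V + α_c (r − V)`, and its pre-update RPE `δ = r − V` drives all other
learning. The shared (state-value) form is deliberate: `V` converges to the
policy's average payoff, so an above-average action keeps generating
positive RPEs and a below-average action negative ones — the persistent,
sign-consistent signal the Hebbian actors need to differentiate. A per-arm
critic (`critic="per_arm"`) is provided for comparison; with it each arm's
RPE decays to zero mean as its own estimate converges, and the actors
receive almost no discriminative signal (on the 10-arm 0.9/0.8 task the
agent then stays at chance-level regret for any softmax temperature, out to
8000 trials). The critic starts at `v0 = 0.5` on Bernoulli tasks and at the
midpoint of the configured arm means on Gaussian tasks (0.75 for the
0.8-vs-0.7 task); starting inside the range of the reward statistics is
required for the sign-consistency mechanism to engage from trial one. A
`forced_sampling` flag instead warm-starts by pulling each arm once before
the softmax policy takes over.

**Actors.** `G(a)` ("Go") and `N(a)` ("NoGo") are updated only for the
chosen arm, multiplicatively: `G += ᾱ_G G δ`, `N += ᾱ_N N (−δ)`, with
hyperbolic annealing `ᾱ(t) = α / (1 + t/T)` in the completed-trial count
(`T = 100` by default; `ᾱ(0) = α`, halved at `t = T`). With the default
initialization `G = N = 1` the first update is exactly a standard actor
update. Weights are floored at `1e-6` — zero is absorbing under a
multiplicative rule and negative weights are meaningless — and carry no
upper cap. The legacy variant behind `FlawFlags` (initialization 0.5, hard
cap at 10, `T = 10`) reproduces a commonly criticized configuration in
which learning is effectively frozen after a few dozen trials.

**Meta-critic and dopamine gain.** A Beta(η, ζ) posterior, initialized
uniform (1, 1), counts positive versus non-positive RPEs (δ = 0 counts as
non-positive; on Bernoulli tasks with `V ∈ (0,1)` positive-RPE counting is
identical to reward counting). Let `m` and `s` be the posterior mean and
standard deviation. While the interval `m ± φ·s` still contains 0.5 the
gain is gated to ρ = 0 (richness not yet credible; φ = 1 by default).
Once credible, ρ saturates smoothly with richness:

    ρ = 2 / (1 + exp(−k (m − ½))) − 1,   ρ ∈ (−1, 1)

`k = 20` by default; `k = 0` disables modulation entirely. The smooth form
(rather than a hard clip of `k(m−½)` at ±1) is a deliberate design choice:
with `k = 20` any clipping form pins ρ to exactly 1 in reward-rich tasks,
which zeroes the NoGo gain `β_N = β(1−ρ)` and silently turns the full model
into its own G-only ablation. The logistic keeps both pathways engaged
(ρ ≈ 0.9993 rather than 1.0 at `m = 0.9`), preserving opponency while
retaining the intended saturation.

**Choice.** Propensities are `β_G G(a) − β_N N(a)` with `β_G = β(1+ρ)`,
`β_N = β(1−ρ)`; actions are drawn from a max-shifted softmax. β may be any
positive real — values below 1 matter for heavy-exploration tasks.

## Environments and what the generator does not emulate

Bernoulli and Gaussian stationary bandits with exact expected values, which
define per-trial expected regret `μ* − μ_a`. Reference tasks: the 10-arm
Bernoulli problem (0.9 vs nine 0.8 arms) and the 2-arm Gaussian problem
(means 0.8/0.7). The Gaussian σ is not dictated by the source material;
0.1 per arm is the default, giving heavily overlapping outcome
distributions while keeping the means separable. Shifted-mean presets move
both Gaussian means by ±0.4 with the 0.1 gap preserved. Two of the three
Bernoulli presets (`bernoulli_2arm`, `bernoulli_5arm`) are illustrative
stand-ins flagged "unverified condition". The generator covers only
stationary, single-context tasks with unit-magnitude or Gaussian rewards:
no nonstationarity, no contexts, no mixed probability/magnitude rewards.
Passing tests therefore say nothing about behavior under drift or
distributional reward structure.

## Benchmarking

Simulation `i` of a benchmark runs a fresh agent with seed `base_seed + i`;
results are exactly reproducible and independent of worker scheduling.
Reported: per-trial mean expected regret across simulations, its running
sum, a 95% normal CI band (`1.96·SD/√n`), and the across-simulation mean ±
CI of cumulative regret at horizon. Horizons default to 1000 trials
(Bernoulli) and 2000 trials (Gaussian; per-trial regret is stable well
before 2000 under the Gaussian preset). Per-trial curves are the default
plot; cumulative curves are stored alongside.

## Parameter search

The corrected protocol optimizes `[α_c, α_actor, β]` (actor rates tied)
over the box `[1e-3, 1] × [1e-3, 1] × [1e-3, 10]` with scipy's `shgo`
(simplicial homology, Sobol' sampling). The objective — mean cumulative
regret at horizon — uses common random numbers (one fixed base seed for
every candidate), making it deterministic and taming optimizer
inconsistency; the search is restarted from several base seeds (default 3)
and the dispersion of the returned optima is reported. Search-time
simulation counts default to 100 with final re-scoring recommended at 1000;
`k` and `φ` are excluded from the search. Results are a lower bound on
achievable performance (more constants could in principle be optimized, and
shgo on a stochastic surrogate carries no global-optimality guarantee).
`legacy_grid_search` reproduces the criticized protocol: exhaustive
evaluation over an explicit coarse grid whose β levels are confined to
[1, 10]. The shipped grid (α_c ∈ {.05, .1, .5}, α_actor ∈ {.05, .1, .5, 1},
β ∈ {1, 2, 5, 10}) is illustrative — the historical grid levels are not
recoverable — and any explicit grid can be supplied.

## Numerical and testing choices

* Softmax uses max-shifting; sampling inverts the cumulative weight sum
  with one uniform draw.
* δ = 0 routes to ζ for determinism; ties in expected values are recorded
  in `optimal_arms` (UCB ties break uniformly at random).
* Exactness tests allow ~1e-15 absolute slack for float associativity; the
  3-trial episode oracle is an independently hand-unrolled trace asserted
  at 1e-12.
* Heavy Monte-Carlo checks use fixed problem sizes chosen for desk-scale
  runs: Gaussian ablation comparisons at 1000/1000/500 simulations ×
  2000 trials; the 10-arm grid demonstration searches at 50 simulations per
  grid point with finalists re-scored at 500; the optimizer sanity check
  runs at 16 simulations × 500 trials. The acceptance script uses 400/300
  simulation variants of the same computations.

## Known limitations

* On the 10-arm 0.9/0.8 task at horizon 1000, discriminating the best arm
  reliably needs far more than 1000 samples, so early-committing policies
  (large effective softmax gain) outperform exploratory ones within this
  horizon; the bounded global search accordingly returns β > 1 here, and
  the simple exploratory set [0.25, 0.25, 0.25] does not beat the best
  restricted-grid configuration. The β-restriction demonstration shipped in
  `reproduce beta_demo` reports both numbers rather than presuming a
  direction.
* The k = 20 dopamine gain confers a small (~2%) cumulative-regret
  advantage over k = 0 on the Gaussian preset — the all-history Beta
  posterior retains the early surplus of positive RPEs, keeping ρ mildly
  positive; with enough simulations this tiny systematic difference is
  statistically detectable.
* The meta-critic has no forgetting, so ρ reflects lifetime rather than
  recent reward history; distributional (variance-sensitive) extensions of
  the meta-critic are out of scope.
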