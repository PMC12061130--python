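# opalstar

Opponent actor-critic (OpAL\*) bandit agents, regret benchmarking, and
global parameter optimization.

`opalstar` is a simulation toolkit for studying how an opponent actor-critic
model of the basal ganglia — with dopamine-modulated direct (D1/"Go") and
indirect (D2/"NoGo") pathways — solves multi-armed bandit problems, and for
comparing it against standard bandit algorithms under *equal* optimization
treatment. It is aimed at computational-neuroscience and reinforcement-
learning researchers who want reproducible regret curves, clean ablations
(meta-critic off, single-pathway choice), and a record of how parameter
search protocol can make or break a model comparison.

## The model

A critic tracks a state value by a delta rule, producing a reward prediction
error (RPE) on every trial:

    δ_t = r_t − V_t,        V_{t+1} = V_t + α_c δ_t

Two opponent actors hold per-action weights updated in opposite directions
by the same RPE, with a multiplicative Hebbian ("activity-dependent") term
and hyperbolically annealed learning rates ᾱ(t) = α / (1 + t/T):

    G_{t+1}(a) = G_t(a) + ᾱ_G(t) · G_t(a) · δ_t
    N_{t+1}(a) = N_t(a) + ᾱ_N(t) · N_t(a) · (−δ_t)

Because ``V`` tracks the policy's average outcome, actions that are better
than average keep producing positive RPEs: ``G`` comes to discriminate among
high-value actions and ``N`` among low-value ones. A meta-critic maintains a
Beta(η, ζ) posterior over the probability of positive RPEs; once its mean
``m`` is credibly away from 0.5, a dopamine signal

    ρ = 2 / (1 + exp(−k (m − ½))) − 1   ∈ (−1, 1)

tilts the softmax gains β_G = β(1+ρ), β_N = β(1−ρ), and actions are drawn
softmax over the propensities β_G G(a) − β_N N(a). Corrected conventions are
the defaults: G, N initialized at 1 (so the first update reduces to a
standard actor update), no upper weight cap, annealing constant T = 100.
The criticized legacy variant (init 0.5, cap at 10, T = 10) is available via
``FlawFlags`` for side-by-side comparison.

Environments are Bernoulli bandits (e.g. the 10-arm task with reward
probabilities 0.9 vs 0.8) and Gaussian bandits with overlapping outcome
distributions (means 0.8 vs 0.7, σ = 0.1). The benchmark statistic is the
mean expected regret μ* − μ_{a_t} per trial across seeded simulations —
lower is better.

## Worked example

Benchmark the full model against its ablations and UCB on the
overlapping-Gaussian task (triplet [α_c, α_actor, β] = [.01, .38, .25],
critic start V₀ = 0.75):

```python
from opalstar import *
from opalstar.opal_agent import OpALAgent
from opalstar.baseline_agents import make_g_only_opal, make_k_zero_opal

env = get_env_preset("gaussian_base")
params = get_param_preset("fig2", v0=0.75)
results = []
for label, factory in [
    ("opal_star", lambda: OpALAgent(params)),
    ("opal_k0", lambda: make_k_zero_opal(params)),
    ("opal_g_only", lambda: make_g_only_opal(params)),
    ("ucb", lambda: make_agent("ucb")),
]:
    res = run_benchmark(factory, env, horizon=2000, n_sims=200, base_seed=0)
    res.agent_name = label
    results.append(res)
print(compare_agents(results).to_string(index=False))
```

```
      agent           env  horizon  n_sims  cum_regret     ci_lo     ci_hi
  opal_star gaussian_base     2000     200     22.5390 22.048211 23.029789
    opal_k0 gaussian_base     2000     200     23.0890 22.597631 23.580369
opal_g_only gaussian_base     2000     200     31.9800 31.265496 32.694504
        ucb gaussian_base     2000     200     39.1265 38.855137 39.397863
```

Cumulative expected regret after 2000 trials (mean ± 95% CI across 200
seeded simulations). The full model and the meta-critic-disabled model (k=0)
are nearly indistinguishable — dopamine modulation buys little in this
setting — while removing the NoGo pathway from choice (`opal_g_only`) costs
about 40% more regret: the opponent actors, not the dopamine signal, carry
the advantage here. Per-trial regret falls from ≈0.023 (first 500 trials) to
≈0.006 (trials 1500–2000), i.e. performance has stabilized well within the
horizon.

## Command line

```bash
opalstar list-presets
opalstar run config.yaml --outdir results/run
opalstar optimize --env bernoulli_10arm --n-sims 100
opalstar reproduce fig2 --n-sims 1000
opalstar reproduce beta_demo          # sub-unity softmax vs restricted grid
```

Each run writes per-trial CSVs, a comparison table, PNG regret curves, and a
manifest (config + seeds + version) sufficient to recreate the outputs.

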