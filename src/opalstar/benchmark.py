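"""Seeded Monte-Carlo benchmarking of agent x environment pairs.

The benchmark statistic is the mean expected instantaneous regret at each
trial across many independent simulations ("lower is better"), together with
its cumulative sum and a 95% normal-approximation confidence band.  Every
simulation ``i`` runs a fresh agent with seed ``base_seed + i``, so results
are fully determined by (agent parameters, environment, horizon, n_sims,
base_seed) and are invariant to how simulations are scheduled across
workers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .environments import BanditEnvironment
from .opal_agent import TrialRecord

__all__ = ["EpisodeTrace", "BenchmarkResult", "run_episode", "run_benchmark", "compare_agents"]


@dataclass
class EpisodeTrace:
    """Per-trial record of one simulated run."""

    arm: np.ndarray
    reward: np.ndarray
    delta: np.ndarray
    rho: np.ndarray
    expected_regret: np.ndarray
    seed: int
    agent_name: str
    env_name: str

    @property
    def horizon(self) -> int:
        return int(self.arm.shape[0])


@dataclass
class BenchmarkResult:
    """Aggregated regret curves across simulations for one agent/environment.

    ``mean_regret[t]`` is the arithmetic mean across simulations of the
    expected regret of the arm chosen at trial ``t``; ``cum_regret`` is its
    running sum.  ``ci_lo``/``ci_hi`` bound the per-trial mean at 95%
    (1.96 * SD / sqrt(n_sims)).  ``final_cum_mean``/``final_cum_ci`` give the
    across-simulation mean and half-width of cumulative regret at horizon.
    """

    mean_regret: np.ndarray
    cum_regret: np.ndarray
    ci_lo: np.ndarray
    ci_hi: np.ndarray
    final_cum_mean: float
    final_cum_sd: float
    n_sims: int
    horizon: int
    base_seed: int
    agent_name: str
    env_name: str

    @property
    def final_cum_ci(self) -> tuple[float, float]:
        half = 1.96 * self.final_cum_sd / np.sqrt(self.n_sims)
        return (self.final_cum_mean - half, self.final_cum_mean + half)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial": np.arange(self.horizon),
                "mean_regret": self.mean_regret,
                "cum_regret": self.cum_regret,
                "ci_lo": self.ci_lo,
                "ci_hi": self.ci_hi,
            }
        )


def run_episode(agent, env: BanditEnvironment, horizon: int, seed: int) -> EpisodeTrace:
    """One seeded episode: fresh rng, agent reset, ``horizon`` trials."""
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    rng = np.random.default_rng(seed)
    agent.reset(env)
    arm = np.empty(horizon, dtype=int)
    reward = np.empty(horizon, dtype=float)
    delta = np.empty(horizon, dtype=float)
    rho = np.empty(horizon, dtype=float)
    regret = np.empty(horizon, dtype=float)
    step = agent.step
    for t in range(horizon):
        rec: TrialRecord = step(env, rng)
        arm[t] = rec.arm
        reward[t] = rec.reward
        delta[t] = rec.delta
        rho[t] = rec.rho
        regret[t] = rec.expected_regret
    return EpisodeTrace(
        arm, reward, delta, rho, regret, seed, getattr(agent, "name", "agent"), env.name
    )


def run_benchmark(
    agent_factory: Callable[[], object],
    env: BanditEnvironment,
    horizon: int,
    n_sims: int,
    base_seed: int,
    n_jobs: int = 1,
) -> BenchmarkResult:
    """Mean regret curves over ``n_sims`` fresh-agent simulations.

    Simulation ``i`` uses seed ``base_seed + i``; ``n_jobs`` only changes the
    scheduling, never the numbers.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")

    def one(i: int) -> np.ndarray:
        return run_episode(agent_factory(), env, horizon, base_seed + i).expected_regret

    if n_jobs != 1:
        from joblib import Parallel, delayed

        rows = Parallel(n_jobs=n_jobs)(delayed(one)(i) for i in range(n_sims))
        regrets = np.vstack(rows)
    else:
        regrets = np.empty((n_sims, horizon), dtype=float)
        for i in range(n_sims):
            regrets[i] = one(i)

    mean = regrets.mean(axis=0)
    sd = regrets.std(axis=0, ddof=1) if n_sims > 1 else np.zeros(horizon)
    half = 1.96 * sd / np.sqrt(n_sims)
    final = regrets.sum(axis=1)
    agent_name = getattr(agent_factory(), "name", "agent")
    return BenchmarkResult(
        mean_regret=mean,
        cum_regret=np.cumsum(mean),
        ci_lo=mean - half,
        ci_hi=mean + half,
        final_cum_mean=float(final.mean()),
        final_cum_sd=float(final.std(ddof=1)) if n_sims > 1 else 0.0,
        n_sims=n_sims,
        horizon=horizon,
        base_seed=base_seed,
        agent_name=agent_name,
        env_name=env.name,
    )


def compare_agents(results: Sequence[BenchmarkResult]) -> pd.DataFrame:
    """Tabulate cumulative regret at horizon (mean +/- 95% CI) per agent.

    All results must share the environment and horizon; row order follows the
    input order.
    """
    if not results:
        raise ValueError("no results to compare")
    env_names = {r.env_name for r in results}
    horizons = {r.horizon for r in results}
    if len(env_names) > 1 or len(horizons) > 1:
        raise ValueError(
            f"results must share env and horizon (got envs {env_names}, horizons {horizons})"
        )
    rows = []
    for r in results:
        lo, hi = r.final_cum_ci
        rows.append(
            {
                "agent": r.agent_name,
                "env": r.env_name,
                "horizon": r.horizon,
                "n_sims": r.n_sims,
                "cum_regret": r.final_cum_mean,
                "ci_lo": lo,
                "ci_hi": hi,
            }
        )
    return pd.DataFrame(rows)
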