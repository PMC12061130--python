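"""Comparison and ablation agents sharing the OpAL* step interface.

Every agent exposes ``reset(env)`` and ``step(env, rng) -> TrialRecord`` so
the benchmark layer is agent-agnostic.  Included:

* softmax Q-learning and UCB1 — the standard bandit baselines;
* G-only OpAL* (N pathway excluded from choice) and k=0 OpAL* (dopamine
  modulation disabled) — the two ablations of interest;
* the fully "flawed" legacy OpAL* variant;
* a uniform-random agent and an oracle best-arm agent, which bracket every
  learning agent's regret from above and below.

External agents (e.g. the "dynamic" neural model reported elsewhere with its
best policy parameter pi = -0.791, whose equations are not part of this
package) can be plugged in through :func:`register_agent` as long as they
satisfy the same reset/step contract.
"""

from __future__ import annotations

import math
from typing import Callable

import numpy as np

from .environments import BanditEnvironment, draw_outcome
from .opal_agent import OpALAgent, OpALParams, TrialRecord, make_flawed_params

__all__ = [
    "QSoftmaxAgent",
    "UCBAgent",
    "UniformRandomAgent",
    "OracleBestAgent",
    "make_g_only_opal",
    "make_k_zero_opal",
    "make_flawed_opal",
    "AGENT_REGISTRY",
    "register_agent",
    "make_agent",
]


def _softmax_draw(x: np.ndarray, rng: np.random.Generator) -> int:
    w = np.exp(x - x.max())
    cum = np.cumsum(w)
    arm = int(np.searchsorted(cum, rng.random() * cum[-1], side="right"))
    return min(arm, x.shape[0] - 1)


class QSoftmaxAgent:
    """Per-arm Q-learning with a softmax policy over ``beta * Q``."""

    name = "q_softmax"

    def __init__(self, alpha: float = 0.1, beta: float = 1.0, q0: float = 0.5) -> None:
        if not 0.0 < alpha <= 1.0:
            raise ValueError("alpha must be in (0, 1]")
        if beta <= 0.0:
            raise ValueError("beta must be positive")
        self.alpha = alpha
        self.beta = beta
        self.q0 = q0
        self.Q: np.ndarray | None = None
        self.t = 0

    def reset(self, env: BanditEnvironment) -> None:
        self.Q = np.full(env.n_arms, self.q0, dtype=float)
        self.t = 0

    def step(self, env: BanditEnvironment, rng: np.random.Generator) -> TrialRecord:
        arm = _softmax_draw(self.beta * self.Q, rng)
        reward = draw_outcome(env, arm, rng)
        delta = reward - self.Q[arm]
        self.Q[arm] += self.alpha * delta
        rec = TrialRecord(self.t, arm, reward, float(delta), 0.0, env.regret(arm))
        self.t += 1
        return rec


class UCBAgent:
    """UCB1: pull each arm once, then maximize mean + c*sqrt(2 ln t / n_a)."""

    name = "ucb"

    def __init__(self, c: float = 1.0) -> None:
        self.c = c
        self.counts: np.ndarray | None = None
        self.means: np.ndarray | None = None
        self.t = 0

    def reset(self, env: BanditEnvironment) -> None:
        self.counts = np.zeros(env.n_arms, dtype=int)
        self.means = np.zeros(env.n_arms, dtype=float)
        self.t = 0

    def _choose(self, rng: np.random.Generator) -> int:
        if self.t < self.counts.shape[0]:
            return self.t  # warm start in index order
        bonus = self.c * np.sqrt(2.0 * math.log(self.t) / self.counts)
        score = self.means + bonus
        best = np.flatnonzero(score == score.max())
        if best.shape[0] == 1:
            return int(best[0])
        return int(best[rng.integers(best.shape[0])])

    def step(self, env: BanditEnvironment, rng: np.random.Generator) -> TrialRecord:
        arm = self._choose(rng)
        reward = draw_outcome(env, arm, rng)
        delta = reward - self.means[arm]
        self.counts[arm] += 1
        self.means[arm] += delta / self.counts[arm]
        rec = TrialRecord(self.t, arm, reward, float(delta), 0.0, env.regret(arm))
        self.t += 1
        return rec


class UniformRandomAgent:
    """Chooses uniformly at random; the never-learns upper bracket."""

    name = "uniform_random"

    def __init__(self) -> None:
        self.t = 0

    def reset(self, env: BanditEnvironment) -> None:
        self.t = 0

    def step(self, env: BanditEnvironment, rng: np.random.Generator) -> TrialRecord:
        arm = int(rng.integers(env.n_arms))
        reward = draw_outcome(env, arm, rng)
        rec = TrialRecord(self.t, arm, reward, 0.0, 0.0, env.regret(arm))
        self.t += 1
        return rec


class OracleBestAgent:
    """Always pulls an optimal arm; achieves expected regret exactly 0."""

    name = "oracle_best"

    def __init__(self) -> None:
        self.t = 0
        self.arm = 0

    def reset(self, env: BanditEnvironment) -> None:
        self.t = 0
        self.arm = env.best_arm

    def step(self, env: BanditEnvironment, rng: np.random.Generator) -> TrialRecord:
        reward = draw_outcome(env, self.arm, rng)
        rec = TrialRecord(self.t, self.arm, reward, 0.0, 0.0, env.regret(self.arm))
        self.t += 1
        return rec


def make_g_only_opal(params: OpALParams, freeze_n: bool = False) -> OpALAgent:
    """OpAL* whose choice uses only the G pathway.

    By default N keeps learning but is ignored at choice (the minimal
    intervention); ``freeze_n=True`` additionally stops N updates.
    """
    agent = OpALAgent(params, g_only=True, freeze_n=freeze_n)
    agent.name = "opal_g_only"
    return agent


def make_k_zero_opal(params: OpALParams) -> OpALAgent:
    """OpAL* with dopamine modulation disabled (k forced to 0, rho == 0)."""
    from dataclasses import replace

    agent = OpALAgent(replace(params, k=0.0))
    agent.name = "opal_k0"
    return agent


def make_flawed_opal(params: OpALParams) -> OpALAgent:
    agent = OpALAgent(make_flawed_params(params))
    agent.name = "opal_flawed"
    return agent


AGENT_REGISTRY: dict[str, Callable[..., object]] = {
    "opal_star": lambda params=None, **kw: OpALAgent(params or OpALParams(), **kw),
    "opal_g_only": lambda params=None, **kw: make_g_only_opal(params or OpALParams(), **kw),
    "opal_k0": lambda params=None, **kw: make_k_zero_opal(params or OpALParams()),
    "opal_flawed": lambda params=None, **kw: make_flawed_opal(params or OpALParams()),
    "q_softmax": lambda **kw: QSoftmaxAgent(**kw),
    "ucb": lambda **kw: UCBAgent(**kw),
    "uniform_random": lambda **kw: UniformRandomAgent(),
    "oracle_best": lambda **kw: OracleBestAgent(),
}


def register_agent(name: str, factory: Callable[..., object]) -> None:
    """Register an external agent factory under ``name`` (reset/step contract)."""
    AGENT_REGISTRY[name] = factory


def make_agent(name: str, **kwargs):
    try:
        factory = AGENT_REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown agent {name!r}; available: {sorted(AGENT_REGISTRY)}"
        ) from None
    return factory(**kwargs)
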