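"""The OpAL* opponent actor-critic agent.

OpAL* models striatal reinforcement learning with a critic and two opponent
actors.  The critic maintains a state value ``V`` updated by a delta rule;
its prediction error (RPE) ``delta = r - V`` drives two sets of per-action
actor weights in opposite directions: the Go weights ``G`` (D1 pathway) grow
with positive RPEs while the NoGo weights ``N`` (D2 pathway) grow with
negative RPEs.  The default critic is a single state value shared across
arms, the classic actor-critic arrangement: because ``V`` tracks the policy's
average outcome, the better arm keeps producing RPEs that are consistently
positive and the worse arms consistently negative, which is exactly the
signal the Hebbian actors need.  (A per-arm critic variant is available via
``critic="per_arm"``; note that each arm's RPE then decays to zero mean as
its value estimate converges, starving the actors of discriminative signal.)
The updates are Hebbian, i.e. multiplied by the current weight itself:

    G[a] += alpha_G(t) * G[a] * delta
    N[a] += alpha_N(t) * N[a] * (-delta)

With the corrected initialization ``G = N = 1`` the very first update reduces
to a standard actor update; the recursion then makes ``G`` specialize in
discriminating among high-reward actions and ``N`` among low-reward ones.
Actor learning rates anneal hyperbolically with trial count (constant ``T``,
default 100), and weights are floored at a tiny positive bound but carry no
upper cap.

A meta-critic tracks the probability of positive RPEs with a Beta
distribution (counts ``eta``, ``zeta``).  When its posterior mean ``m`` is
credibly away from 0.5 the dopamine signal rises or falls smoothly with
reward richness, ``rho = 2*expit(k*(m - 0.5)) - 1`` in (-1, 1), tilting the
softmax gains toward the better-suited actor: choice propensities are
``beta*(1+rho)*G[a] - beta*(1-rho)*N[a]``.  The saturating form keeps both
gains strictly positive, so opponency is modulated but never abolished.

``flaw_flags`` reproduce a commonly criticized legacy variant (weights
initialized at 0.5, capped at 10, annealing constant 10) for side-by-side
comparison with the corrected model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np

from .environments import BanditEnvironment, draw_outcome

__all__ = [
    "FlawFlags",
    "OpALParams",
    "OpALState",
    "TrialRecord",
    "init_state",
    "critic_update",
    "actor_update",
    "anneal_rate",
    "meta_critic_update",
    "compute_rho",
    "action_propensities",
    "select_action",
    "opal_step",
    "OpALAgent",
]


class TrialRecord(NamedTuple):
    """One trial of any bandit agent (shared across agent types)."""

    t: int
    arm: int
    reward: float
    delta: float
    rho: float
    expected_regret: float


@dataclass(frozen=True)
class FlawFlags:
    """Switches reproducing the criticized legacy implementation.

    ``init_half`` starts G/N at 0.5 instead of 1; ``cap_at_10`` clamps actor
    weights at 10 after every update; ``T_equals_10`` anneals with T=10
    instead of 100.
    """

    init_half: bool = False
    cap_at_10: bool = False
    T_equals_10: bool = False

    @property
    def any(self) -> bool:
        return self.init_half or self.cap_at_10 or self.T_equals_10


@dataclass(frozen=True)
class OpALParams:
    """All OpAL* constants.

    alpha_c : critic learning rate, in (0, 1]
    alpha_g, alpha_n : actor learning rates, in (0, 1] (equal when mirroring
        the three-parameter optimization protocol)
    beta : softmax temperature, any positive real (values < 1 are essential
        for heavy-exploration tasks)
    k : dopamine-modulation strength, >= 0 (k=0 disables modulation)
    phi : meta-critic confidence multiplier, >= 0
    T : annealing constant for actor learning rates, > 0
    v0 : critic initialization; ``None`` selects 0.5 on Bernoulli tasks and
        the midpoint of the arm means on Gaussian tasks
    gn0 : actor initialization (1.0 in the corrected model)
    weight_floor : small positive lower bound keeping G/N strictly positive
    critic : ``"shared"`` (one state value, default) or ``"per_arm"``
    flaws : legacy-variant switches (see :class:`FlawFlags`)
    """

    alpha_c: float = 0.1
    alpha_g: float = 0.1
    alpha_n: float = 0.1
    beta: float = 1.0
    k: float = 20.0
    phi: float = 1.0
    T: float = 100.0
    v0: float | None = None
    gn0: float = 1.0
    weight_floor: float = 1e-6
    critic: str = "shared"
    flaws: FlawFlags = field(default_factory=FlawFlags)

    def __post_init__(self) -> None:
        if self.critic not in ("shared", "per_arm"):
            raise ValueError(f"critic must be 'shared' or 'per_arm', got {self.critic!r}")
        for nm in ("alpha_c", "alpha_g", "alpha_n"):
            v = getattr(self, nm)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{nm}={v} must be in (0, 1]")
        if not self.beta > 0.0:
            raise ValueError(f"beta={self.beta} must be positive")
        if self.k < 0.0 or self.phi < 0.0:
            raise ValueError("k and phi must be non-negative")
        if not self.T > 0.0:
            raise ValueError("T must be positive")
        if not 0.0 < self.weight_floor < 1.0:
            raise ValueError("weight_floor must be a small positive number")

    @property
    def effective_T(self) -> float:
        return 10.0 if self.flaws.T_equals_10 else self.T

    @property
    def effective_gn0(self) -> float:
        return 0.5 if self.flaws.init_half else self.gn0

    @classmethod
    def from_triplet(cls, triplet, **kwargs) -> "OpALParams":
        """Build params from a [critic lr, actor lr, softmax beta] triplet."""
        ac, aa, b = triplet
        return cls(alpha_c=ac, alpha_g=aa, alpha_n=aa, beta=b, **kwargs)


@dataclass
class OpALState:
    """Evolving agent quantities: critic, actors, meta-critic, trial count.

    ``V`` holds one entry for a shared state-value critic, or one entry per
    arm for the per-arm variant; :meth:`value` hides the difference.
    """

    V: np.ndarray
    G: np.ndarray
    N: np.ndarray
    eta: float
    zeta: float
    t: int
    rho: float

    def value(self, arm: int) -> float:
        """Critic value relevant to ``arm`` under either critic layout."""
        return float(self.V[arm] if self.V.shape[0] > 1 else self.V[0])


def init_state(params: OpALParams, n_arms: int, v0: float) -> OpALState:
    gn0 = params.effective_gn0
    n_critic = n_arms if params.critic == "per_arm" else 1
    return OpALState(
        V=np.full(n_critic, v0, dtype=float),
        G=np.full(n_arms, gn0, dtype=float),
        N=np.full(n_arms, gn0, dtype=float),
        eta=1.0,  # uniform Beta(1, 1) prior => rho = 0 before any data
        zeta=1.0,
        t=0,
        rho=0.0,
    )


def resolve_v0(params: OpALParams, env: BanditEnvironment) -> float:
    """Default critic start: 0.5 for Bernoulli, midpoint of means for Gaussian."""
    if params.v0 is not None:
        return float(params.v0)
    if env.kind == "bernoulli":
        return 0.5
    return float(env.expected_values.mean())


def critic_update(
    state: OpALState, arm: int, reward: float, params: OpALParams
) -> tuple[OpALState, float]:
    """Delta-rule critic update; returns the pre-update RPE ``delta``.

    With the shared critic the single state value is updated; with the
    per-arm critic only ``V[arm]`` changes.
    """
    if not math.isfinite(reward):
        raise ValueError(f"non-finite reward {reward}")
    idx = arm if state.V.shape[0] > 1 else 0
    delta = reward - state.V[idx]
    state.V[idx] += params.alpha_c * delta
    return state, float(delta)


def anneal_rate(alpha: float, t: int, T: float) -> float:
    """Hyperbolically annealed learning rate ``alpha / (1 + t/T)``."""
    return alpha / (1.0 + t / T)


def actor_update(state: OpALState, arm: int, delta: float, params: OpALParams) -> OpALState:
    """Multiplicative Hebbian update of the chosen arm's G and N weights."""
    if not math.isfinite(delta):
        raise ValueError(f"non-finite delta {delta}")
    T = params.effective_T
    ag = anneal_rate(params.alpha_g, state.t, T)
    an = anneal_rate(params.alpha_n, state.t, T)
    g = state.G[arm] + ag * state.G[arm] * delta
    n = state.N[arm] + an * state.N[arm] * (-delta)
    floor = params.weight_floor
    if params.flaws.cap_at_10:
        g = min(g, 10.0)
        n = min(n, 10.0)
    state.G[arm] = g if g > floor else floor
    state.N[arm] = n if n > floor else floor
    return state


def meta_critic_update(state: OpALState, delta: float) -> OpALState:
    """Count the RPE sign in the Beta tracker; delta=0 counts as non-positive."""
    if delta > 0.0:
        state.eta += 1.0
    else:
        state.zeta += 1.0
    state.t += 1
    return state


def compute_rho(state: OpALState, params: OpALParams) -> float:
    """Dopamine modulation from the Beta posterior over positive-RPE probability.

    ``rho`` is zero while the posterior mean's ``phi``-scaled standard
    deviation interval still contains 0.5 (environment richness not yet
    credible); otherwise it saturates smoothly with richness,
    ``2/(1 + exp(-k*(m - 0.5))) - 1``, staying strictly inside (-1, 1) so
    both softmax gains remain positive and opponency is preserved.
    ``k = 0`` always yields 0.
    """
    if params.k == 0.0:
        return 0.0
    e, z = state.eta, state.zeta
    total = e + z
    m = e / total
    s = math.sqrt(e * z / (total * total * (total + 1.0)))
    if m - params.phi * s <= 0.5 <= m + params.phi * s:
        return 0.0
    return 2.0 / (1.0 + math.exp(-params.k * (m - 0.5))) - 1.0


def action_propensities(
    state: OpALState, params: OpALParams, g_only: bool = False
) -> np.ndarray:
    """Opponent combination ``beta_G*G - beta_N*N`` with rho-tilted gains.

    ``g_only`` removes the N pathway from choice (ablation), leaving
    ``beta_G*G`` alone.
    """
    bg = params.beta * (1.0 + state.rho)
    if g_only:
        return bg * state.G
    bn = params.beta * (1.0 - state.rho)
    return bg * state.G - bn * state.N


def select_action(propensities: np.ndarray, rng: np.random.Generator) -> int:
    """Softmax draw over propensities, max-shifted for numerical stability."""
    x = np.asarray(propensities, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite propensity")
    w = np.exp(x - x.max())
    cum = np.cumsum(w)
    arm = int(np.searchsorted(cum, rng.random() * cum[-1], side="right"))
    return min(arm, x.shape[0] - 1)


def opal_step(
    state: OpALState,
    env: BanditEnvironment,
    params: OpALParams,
    rng: np.random.Generator,
    g_only: bool = False,
    freeze_n: bool = False,
) -> tuple[OpALState, TrialRecord]:
    """One full OpAL* trial.

    Order: recompute rho -> propensities -> softmax choice -> outcome ->
    critic update (yields delta) -> actor update -> meta-critic update.
    """
    state.rho = compute_rho(state, params)
    props = action_propensities(state, params, g_only=g_only)
    arm = select_action(props, rng)
    reward = draw_outcome(env, arm, rng)
    t = state.t
    state, delta = critic_update(state, arm, reward, params)
    if freeze_n:
        saved_n = state.N[arm]
        state = actor_update(state, arm, delta, params)
        state.N[arm] = saved_n
    else:
        state = actor_update(state, arm, delta, params)
    state = meta_critic_update(state, delta)
    return state, TrialRecord(t, arm, reward, delta, state.rho, env.regret(arm))


class OpALAgent:
    """Stateful wrapper exposing the common ``reset``/``step`` agent interface.

    Parameters
    ----------
    params:
        Agent constants.
    g_only:
        Ablation: choice ignores the N pathway (N keeps learning unless
        ``freeze_n`` is also set).
    freeze_n:
        Stronger ablation variant: N weights are never updated.
    forced_sampling:
        Warm start pulling each arm once, in index order, before the softmax
        policy takes over (updates still applied on the forced pulls).
    """

    name = "opal_star"

    def __init__(
        self,
        params: OpALParams,
        g_only: bool = False,
        freeze_n: bool = False,
        forced_sampling: bool = False,
    ) -> None:
        self.params = params
        self.g_only = g_only
        self.freeze_n = freeze_n
        self.forced_sampling = forced_sampling
        self.state: OpALState | None = None

    def reset(self, env: BanditEnvironment) -> None:
        self.state = init_state(self.params, env.n_arms, resolve_v0(self.params, env))

    def step(self, env: BanditEnvironment, rng: np.random.Generator) -> TrialRecord:
        state, params = self.state, self.params
        if self.forced_sampling and state.t < env.n_arms:
            arm = state.t
            state.rho = compute_rho(state, params)
            reward = draw_outcome(env, arm, rng)
            t = state.t
            state, delta = critic_update(state, arm, reward, params)
            if not self.freeze_n:
                state = actor_update(state, arm, delta, params)
            else:
                saved_n = state.N[arm]
                state = actor_update(state, arm, delta, params)
                state.N[arm] = saved_n
            state = meta_critic_update(state, delta)
            return TrialRecord(t, arm, reward, delta, state.rho, env.regret(arm))
        self.state, rec = opal_step(
            state, env, params, rng, g_only=self.g_only, freeze_n=self.freeze_n
        )
        return rec


def make_flawed_params(params: OpALParams) -> OpALParams:
    """All legacy flaws switched on (init 0.5, cap at 10, T=10)."""
    return replace(params, flaws=FlawFlags(init_half=True, cap_at_10=True, T_equals_10=True))
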