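"""Multi-armed bandit environments with ground-truth expected values.

Two stationary environment families are supported:

* **Bernoulli** bandits — each arm pays 1.0 with probability ``p_a`` and 0.0
  otherwise.  The canonical hard case here is a 10-arm task with one arm at
  reward probability 0.9 and nine competitors at 0.8, which demands heavy
  exploration to identify the best arm.
* **Gaussian** bandits — each arm pays a draw from ``Normal(mu_a, sigma_a)``.
  The canonical case is two arms with means 0.8 vs 0.7 whose outcome
  distributions overlap substantially.

Rewards are always real-valued (Bernoulli outcomes are encoded as 0.0/1.0) so
both families share a single reward pathway.  Every environment caches the
true per-arm expected values, which define the expected instantaneous regret
``mu_star - E[reward | arm]`` used by the benchmark layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "BanditEnvironment",
    "make_bernoulli_env",
    "make_gaussian_env",
    "draw_outcome",
    "expected_regret",
    "ENV_PRESETS",
    "get_env_preset",
]


@dataclass(frozen=True)
class BanditEnvironment:
    """A stationary multi-armed bandit task.

    Attributes
    ----------
    kind:
        ``"bernoulli"`` or ``"gaussian"``.
    expected_values:
        True per-arm mean rewards (``p_a`` for Bernoulli, ``mu_a`` for
        Gaussian); the ground truth for regret.
    probs:
        Per-arm success probabilities (Bernoulli only).
    means, sigmas:
        Per-arm Normal parameters (Gaussian only).
    name:
        Optional human-readable label used in results and manifests.
    """

    kind: str
    expected_values: np.ndarray
    probs: np.ndarray | None = None
    means: np.ndarray | None = None
    sigmas: np.ndarray | None = None
    name: str = ""
    # Arms tied with the best arm (affects regret ground truth when non-unique).
    optimal_arms: tuple[int, ...] = field(default=())

    @property
    def n_arms(self) -> int:
        return int(self.expected_values.shape[0])

    @property
    def best_value(self) -> float:
        return float(self.expected_values.max())

    @property
    def best_arm(self) -> int:
        """Lowest-index optimal arm (ties recorded in ``optimal_arms``)."""
        return self.optimal_arms[0]

    def _check_arm(self, arm: int) -> None:
        if not 0 <= arm < self.n_arms:
            raise IndexError(f"arm {arm} out of range for {self.n_arms}-arm environment")

    def draw(self, arm: int, rng: np.random.Generator) -> float:
        """Sample one reward from ``arm``'s outcome distribution."""
        self._check_arm(arm)
        if self.kind == "bernoulli":
            return 1.0 if rng.random() < self.probs[arm] else 0.0
        return float(self.means[arm] + self.sigmas[arm] * rng.standard_normal())

    def regret(self, arm: int) -> float:
        """Expected instantaneous regret of pulling ``arm``; >= 0, 0 iff optimal."""
        self._check_arm(arm)
        return self.best_value - float(self.expected_values[arm])


def _finalize(kind, expected, name, **extra) -> BanditEnvironment:
    expected = np.asarray(expected, dtype=float)
    best = expected.max()
    optimal = tuple(int(a) for a in np.flatnonzero(expected == best))
    return BanditEnvironment(
        kind=kind, expected_values=expected, name=name, optimal_arms=optimal, **extra
    )


def make_bernoulli_env(probabilities: Sequence[float], name: str = "") -> BanditEnvironment:
    """Build a Bernoulli bandit from per-arm success probabilities.

    Parameters
    ----------
    probabilities:
        At least two values, each in [0, 1].  Arm ``a`` pays 1.0 with
        probability ``probabilities[a]`` and 0.0 otherwise.
    """
    probs = np.asarray(probabilities, dtype=float)
    if probs.ndim != 1 or probs.shape[0] < 2:
        raise ValueError("a bandit needs at least 2 arms")
    for a, p in enumerate(probs):
        if not (np.isfinite(p) and 0.0 <= p <= 1.0):
            raise ValueError(f"arm {a}: probability {p} not in [0, 1]")
    return _finalize("bernoulli", probs, name, probs=probs)


def make_gaussian_env(
    means: Sequence[float], sigmas: Sequence[float] | float, name: str = ""
) -> BanditEnvironment:
    """Build a Gaussian bandit from per-arm means and standard deviations.

    ``sigmas`` may be a scalar, which is broadcast to every arm.
    """
    mu = np.asarray(means, dtype=float)
    if mu.ndim != 1 or mu.shape[0] < 2:
        raise ValueError("a bandit needs at least 2 arms")
    sig = np.broadcast_to(np.asarray(sigmas, dtype=float), mu.shape).copy()
    if mu.shape != sig.shape:
        raise ValueError("means and sigmas must have matching lengths")
    if not np.all(np.isfinite(mu)):
        raise ValueError("non-finite mean")
    for a, s in enumerate(sig):
        if not (np.isfinite(s) and s > 0.0):
            raise ValueError(f"arm {a}: sigma {s} must be strictly positive")
    return _finalize("gaussian", mu, name, means=mu, sigmas=sig)


def draw_outcome(env: BanditEnvironment, arm: int, rng: np.random.Generator) -> float:
    """Sample a single reward; identical rng state yields an identical sample."""
    return env.draw(arm, rng)


def expected_regret(env: BanditEnvironment, arm: int) -> float:
    """True expected regret of ``arm``: best-arm mean minus this arm's mean."""
    return env.regret(arm)


def _bernoulli_10arm() -> BanditEnvironment:
    return make_bernoulli_env([0.9] + [0.8] * 9, name="bernoulli_10arm")


# Named task presets.  The 10-arm 0.9-vs-0.8 Bernoulli condition and the
# 0.8-vs-0.7 Gaussian condition are the reference tasks; the second and third
# Bernoulli presets are illustrative stand-ins (unverified condition) kept
# fully editable through configs.  The shifted Gaussian presets move both
# means by +/-0.4 while keeping the 0.1 gap and the default sigma of 0.1.
ENV_PRESETS: dict[str, dict] = {
    "bernoulli_10arm": {
        "kind": "bernoulli",
        "probabilities": [0.9] + [0.8] * 9,
        "note": "10-arm task, one 0.9 arm vs nine 0.8 arms",
    },
    "bernoulli_2arm": {
        "kind": "bernoulli",
        "probabilities": [0.9, 0.8],
        "note": "unverified condition: illustrative 2-arm stand-in",
    },
    "bernoulli_5arm": {
        "kind": "bernoulli",
        "probabilities": [0.9, 0.8, 0.8, 0.8, 0.8],
        "note": "unverified condition: illustrative 5-arm stand-in",
    },
    "gaussian_base": {
        "kind": "gaussian",
        "means": [0.8, 0.7],
        "sigmas": [0.1, 0.1],
        "note": "overlapping Gaussian outcomes, mu 0.8 vs 0.7",
    },
    "gaussian_low": {
        "kind": "gaussian",
        "means": [0.4, 0.3],
        "sigmas": [0.1, 0.1],
        "note": "means shifted down by 0.4, same 0.1 gap",
    },
    "gaussian_high": {
        "kind": "gaussian",
        "means": [1.2, 1.1],
        "sigmas": [0.1, 0.1],
        "note": "means shifted up by 0.4, same 0.1 gap",
    },
}


def get_env_preset(name: str) -> BanditEnvironment:
    """Instantiate a named environment preset."""
    try:
        spec = ENV_PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown environment preset {name!r}; available: {sorted(ENV_PRESETS)}"
        ) from None
    if spec["kind"] == "bernoulli":
        return make_bernoulli_env(spec["probabilities"], name=name)
    return make_gaussian_env(spec["means"], spec["sigmas"], name=name)
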