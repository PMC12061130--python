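"""Named parameter presets.

Each triplet is ordered [critic learning rate, actor learning rate (shared
across G and N), softmax temperature beta], matching the three-parameter
optimization protocol.  ``k`` and ``phi`` are held at 20 and 1 throughout.

The three ``fig1_*`` triplets pair with the three Bernoulli benchmark
conditions; ``fig2`` is the Gaussian-task triplet (used with critic start
V0 = 0.75 on the 0.8-vs-0.7 task); ``beta_demo`` is the simple all-0.25 set
demonstrating that a softmax temperature below 1 is needed to explore a
10-arm task effectively.
"""

from __future__ import annotations

from .opal_agent import OpALParams

__all__ = ["PARAM_PRESETS", "get_param_preset"]

PARAM_PRESETS: dict[str, tuple[float, float, float]] = {
    "fig1_a": (0.01, 0.01, 0.5),
    "fig1_b": (0.44, 0.19, 0.44),
    "fig1_c": (0.02, 0.5, 0.13),
    "fig2": (0.01, 0.38, 0.25),
    "beta_demo": (0.25, 0.25, 0.25),
}


def get_param_preset(name: str, **kwargs) -> OpALParams:
    """Instantiate :class:`OpALParams` from a named triplet.

    Extra keyword arguments (``v0``, ``k`` ...) override defaults.
    """
    try:
        triplet = PARAM_PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown parameter preset {name!r}; available: {sorted(PARAM_PRESETS)}"
        ) from None
    return OpALParams.from_triplet(triplet, **kwargs)
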