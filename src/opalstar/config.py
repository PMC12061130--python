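"""Run configuration: schema, validation, loading, and execution.

A run config (YAML or JSON) declares environments, agents, the horizon,
simulation count and base seed, and is validated against
:data:`RUN_CONFIG_SCHEMA` before any computation.  Every output directory
receives a manifest (full config + seeds + package version) sufficient to
recreate it exactly.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import __version__
from .baseline_agents import AGENT_REGISTRY, make_agent
from .benchmark import BenchmarkResult, compare_agents, run_benchmark
from .environments import (
    ENV_PRESETS,
    BanditEnvironment,
    get_env_preset,
    make_bernoulli_env,
    make_gaussian_env,
)
from .opal_agent import FlawFlags, OpALParams
from .presets import PARAM_PRESETS, get_param_preset

__all__ = ["RunConfig", "RUN_CONFIG_SCHEMA", "load_config", "run_from_config"]

# Published schema (JSON-Schema style, draft-07 subset) for run configs.
RUN_CONFIG_SCHEMA: dict[str, Any] = {
    "type": "object",
    "required": ["environments", "agents"],
    "properties": {
        "environments": {
            "type": "array",
            "minItems": 1,
            "items": {
                "type": "object",
                "properties": {
                    "preset": {"type": "string"},
                    "kind": {"enum": ["bernoulli", "gaussian"]},
                    "probabilities": {"type": "array", "items": {"type": "number"}},
                    "means": {"type": "array", "items": {"type": "number"}},
                    "sigmas": {"type": "array", "items": {"type": "number"}},
                    "name": {"type": "string"},
                },
            },
        },
        "agents": {
            "type": "array",
            "minItems": 1,
            "items": {
                "type": "object",
                "required": ["name"],
                "properties": {
                    "name": {"enum": sorted(AGENT_REGISTRY)},
                    "preset": {"enum": sorted(PARAM_PRESETS)},
                    "triplet": {"type": "array", "items": {"type": "number"}},
                    "params": {"type": "object"},
                    "label": {"type": "string"},
                },
            },
        },
        "horizon": {"type": "integer", "minimum": 1},
        "n_sims": {"type": "integer", "minimum": 1},
        "base_seed": {"type": "integer"},
        "plot": {"type": "boolean"},
    },
}


class ConfigError(ValueError):
    """Raised when a run config fails schema validation; lists offending keys."""


@dataclass
class RunConfig:
    environments: list[dict]
    agents: list[dict]
    horizon: int = 1000
    n_sims: int = 100
    base_seed: int = 0
    plot: bool = True
    raw: dict = field(default_factory=dict)


def _validate(data: dict) -> list[str]:
    errors: list[str] = []
    if not isinstance(data, dict):
        return ["config root must be a mapping"]
    for key in ("environments", "agents"):
        items = data.get(key)
        if not isinstance(items, list) or not items:
            errors.append(f"{key}: required non-empty list")
            continue
        for i, item in enumerate(items):
            if not isinstance(item, dict):
                errors.append(f"{key}[{i}]: must be a mapping")
    for key in ("horizon", "n_sims"):
        if key in data and (not isinstance(data[key], int) or data[key] < 1):
            errors.append(f"{key}: must be a positive integer")
    if "base_seed" in data and not isinstance(data["base_seed"], int):
        errors.append("base_seed: must be an integer")
    for i, spec in enumerate(data.get("agents", []) if isinstance(data.get("agents"), list) else []):
        if isinstance(spec, dict):
            if "name" not in spec:
                errors.append(f"agents[{i}].name: required")
            elif spec["name"] not in AGENT_REGISTRY:
                errors.append(
                    f"agents[{i}].name: unknown agent {spec['name']!r} "
                    f"(available: {sorted(AGENT_REGISTRY)})"
                )
            if "preset" in spec and spec["preset"] not in PARAM_PRESETS:
                errors.append(f"agents[{i}].preset: unknown preset {spec['preset']!r}")
    for i, spec in enumerate(
        data.get("environments", []) if isinstance(data.get("environments"), list) else []
    ):
        if isinstance(spec, dict):
            if "preset" in spec:
                if spec["preset"] not in ENV_PRESETS:
                    errors.append(f"environments[{i}].preset: unknown preset {spec['preset']!r}")
            elif spec.get("kind") == "bernoulli":
                if "probabilities" not in spec:
                    errors.append(f"environments[{i}].probabilities: required for bernoulli")
            elif spec.get("kind") == "gaussian":
                if "means" not in spec:
                    errors.append(f"environments[{i}].means: required for gaussian")
            else:
                errors.append(f"environments[{i}]: needs 'preset' or a valid 'kind'")
    return errors


def load_config(source: str | Path | dict) -> RunConfig:
    """Load and validate a YAML/JSON run config (path, text, or mapping)."""
    if isinstance(source, dict):
        data = source
    else:
        path = Path(source)
        text = path.read_text() if path.exists() else str(source)
        data = yaml.safe_load(text)
    errors = _validate(data)
    if errors:
        raise ConfigError("invalid run config:\n  " + "\n  ".join(errors))
    return RunConfig(
        environments=data["environments"],
        agents=data["agents"],
        horizon=data.get("horizon", 1000),
        n_sims=data.get("n_sims", 100),
        base_seed=data.get("base_seed", 0),
        plot=data.get("plot", True),
        raw=data,
    )


def build_environment(spec: dict) -> BanditEnvironment:
    if "preset" in spec:
        return get_env_preset(spec["preset"])
    name = spec.get("name", spec["kind"])
    if spec["kind"] == "bernoulli":
        return make_bernoulli_env(spec["probabilities"], name=name)
    sigmas = spec.get("sigmas", 0.1)
    return make_gaussian_env(spec["means"], sigmas, name=name)


def build_agent_factory(spec: dict):
    """Turn an agent config block into a zero-arg fresh-agent factory."""
    name = spec["name"]
    label = spec.get("label", name)
    overrides = dict(spec.get("params", {}))
    if name.startswith("opal"):
        flaw_kwargs = overrides.pop("flaw_flags", None)
        extra = {}
        for key in ("g_only", "freeze_n", "forced_sampling"):
            if key in overrides:
                extra[key] = overrides.pop(key)
        if flaw_kwargs:
            overrides["flaws"] = FlawFlags(**flaw_kwargs)
        if "preset" in spec:
            params = get_param_preset(spec["preset"], **overrides)
        elif "triplet" in spec:
            params = OpALParams.from_triplet(spec["triplet"], **overrides)
        else:
            params = OpALParams(**overrides)

        def factory():
            agent = make_agent(name, params=params, **extra)
            agent.name = label
            return agent

    else:

        def factory():
            agent = make_agent(name, **overrides)
            agent.name = label
            return agent

    return factory, label


def run_from_config(config: RunConfig, outdir: str | Path) -> Path:
    """Execute every agent x environment pair and write CSVs, manifest, plots."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    all_results: dict[str, list[BenchmarkResult]] = {}
    for env_spec in config.environments:
        env = build_environment(env_spec)
        results = []
        for agent_spec in config.agents:
            factory, label = build_agent_factory(agent_spec)
            res = run_benchmark(
                factory, env, config.horizon, config.n_sims, config.base_seed
            )
            res.agent_name = label
            frame = res.to_frame()
            frame.insert(0, "agent", label)
            frame.to_csv(outdir / f"{env.name or 'env'}__{label}.csv", index=False)
            results.append(res)
        compare_agents(results).to_csv(outdir / f"{env.name or 'env'}__comparison.csv", index=False)
        all_results[env.name or "env"] = results
        if config.plot:
            from .plotting import plot_benchmark

            plot_benchmark(results, outdir / f"{env.name or 'env'}.png", title=env.name)
    manifest = {
        "config": config.raw,
        "base_seed": config.base_seed,
        "horizon": config.horizon,
        "n_sims": config.n_sims,
        "package_version": __version__,
        "elapsed_seconds": round(time.time() - t0, 3),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return outdir
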