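"""Regret-curve figures: mean regret vs trial with 95% CI bands."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .benchmark import BenchmarkResult

__all__ = ["plot_benchmark", "plot_panels"]


def plot_benchmark(
    results: Sequence[BenchmarkResult],
    path: str | Path,
    title: str = "",
    cumulative: bool = False,
    ax=None,
):
    """One panel of per-trial (default) or cumulative mean regret per agent."""
    own_fig = ax is None
    if own_fig:
        fig, ax = plt.subplots(figsize=(5, 3.5))
    for res in results:
        x = range(res.horizon)
        if cumulative:
            ax.plot(x, res.cum_regret, label=res.agent_name)
        else:
            ax.plot(x, res.mean_regret, label=res.agent_name, lw=1)
            ax.fill_between(x, res.ci_lo, res.ci_hi, alpha=0.2)
    ax.set_xlabel("trial")
    ax.set_ylabel("cumulative regret" if cumulative else "mean regret (lower is better)")
    if title:
        ax.set_title(title)
    ax.legend(fontsize=8)
    if own_fig:
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return ax


def plot_panels(
    panels: dict[str, Sequence[BenchmarkResult]],
    path: str | Path,
    cumulative: bool = False,
):
    """Side-by-side panels (one per condition), shared y-axis."""
    n = len(panels)
    fig, axes = plt.subplots(1, n, figsize=(4 * n, 3.2), sharey=True)
    if n == 1:
        axes = [axes]
    for ax, (name, results) in zip(axes, panels.items()):
        plot_benchmark(results, path, title=name, cumulative=cumulative, ax=ax)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
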