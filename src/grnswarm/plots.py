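"""Figure helpers for the standard experiment outputs.

All functions take the in-memory result objects and return a matplotlib
figure; pass ``path`` to save a PNG instead of showing it.  Uses the Agg
backend implicitly when no display is present.
"""

from __future__ import annotations

from typing import Dict, Optional, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .metrics import MetricsSeries, summarize_boxplot, visit_histogram


def _finish(fig, path):
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_energy_boxes(batch: Sequence[MetricsSeries], step_grid: Sequence[int],
                      title: str = "Average energy level", path=None):
    """Box summary of the population's average energy across replicates."""
    table = summarize_boxplot(batch, step_grid)
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.fill_between(table["step"], table["min"], table["max"], alpha=0.2,
                    label="range")
    ax.fill_between(table["step"], table["q1"], table["q3"], alpha=0.4,
                    label="quartiles")
    ax.plot(table["step"], table["median"], lw=2, label="median")
    ax.set_xlabel("time step")
    ax.set_ylabel("average energy level")
    ax.set_title(title)
    ax.legend()
    return _finish(fig, path)


def plot_competition(series: MetricsSeries, path=None):
    """Population sizes of both controller types plus the food count."""
    fig, ax = plt.subplots(figsize=(7, 4))
    for kind, pops in series.pop_by_kind.items():
        ax.plot(series.step, pops, label=f"{kind} population")
    ax2 = ax.twinx()
    ax2.plot(series.step, series.food_count, color="green", alpha=0.6,
             label="food sources")
    ax.set_xlabel("time step")
    ax.set_ylabel("population size")
    ax2.set_ylabel("food sources")
    lines, labels = ax.get_legend_handles_labels()
    l2, lb2 = ax2.get_legend_handles_labels()
    ax.legend(lines + l2, labels + lb2, loc="upper right")
    return _finish(fig, path)


def plot_visit_histogram(visit_matrices: Sequence[np.ndarray], path=None,
                         title: str = "Cell visit counts"):
    """Number of cells per cumulative visit count, pooled over replicates."""
    hist = visit_histogram(visit_matrices)
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.bar(list(hist.keys()), list(hist.values()), width=1.0)
    ax.set_xlabel("number of robot visits")
    ax.set_ylabel("number of cells")
    ax.set_yscale("log")
    ax.set_title(title)
    return _finish(fig, path)


def plot_gain_rate(series_by_label: Dict[str, MetricsSeries], path=None):
    """10-step energy-gain traces, with food resets marked."""
    fig, ax = plt.subplots(figsize=(7, 4))
    for label, s in series_by_label.items():
        ax.plot(s.step, s.gain10, label=label, alpha=0.8)
        for t in s.step[s.resets]:
            ax.axvline(t, color="grey", alpha=0.2, lw=0.8)
    ax.set_xlabel("time step")
    ax.set_ylabel("energy gain per 10 steps")
    ax.legend()
    return _finish(fig, path)
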