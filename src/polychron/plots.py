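"""Minimal plotting helpers for sweep results (bar charts with run error bars)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .experiments import SweepResult

__all__ = ["plot_success_bars", "plot_spike_fraction_hist"]


def plot_success_bars(
    result: SweepResult, x_col: str, path: str | Path, title: str = ""
) -> None:
    """Bar chart of mean success % per configuration, error bars = std over runs."""
    summary = result.summary()
    fig, ax = plt.subplots(figsize=(6, 4))
    x = summary[x_col].astype(str)
    ax.bar(x, summary["mean_success_pct"], yerr=summary["std_success_pct"], capsize=4)
    ax.set_xlabel(x_col)
    ax.set_ylabel("successful recall (%)")
    ax.set_ylim(0, 105)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_spike_fraction_hist(
    patterns: pd.DataFrame, path: str | Path, by: str = "n_neurons"
) -> None:
    """Histogram of per-pattern spike-recall fractions, one panel per group."""
    groups = list(patterns.groupby(by))
    fig, axes = plt.subplots(
        1, len(groups), figsize=(3 * len(groups), 3), squeeze=False
    )
    for ax, (key, df) in zip(axes[0], groups):
        ax.hist(df["spike_fraction"], bins=20, range=(0, 1))
        ax.set_title(f"{by}={key}")
        ax.set_xlabel("fraction of spikes recalled")
    axes[0][0].set_ylabel("patterns")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
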