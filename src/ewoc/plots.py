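"""Plotting helpers for simulation summaries.

Regenerates the standard comparison layouts — one panel per operating
characteristic, designs side by side within each scenario — from the
long-format summary table written by the simulation batch.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")  # headless by default; callers may switch backends
import matplotlib.pyplot as plt
import pandas as pd


def plot_metric(long_df: pd.DataFrame, metric: str, ax=None):
    """Grouped bar chart of one metric by scenario and design.

    ``long_df`` is the output of :func:`ewoc.simulate.summaries_to_long`.
    """
    sub = long_df[long_df["metric"] == metric]
    if sub.empty:
        raise ValueError(f"metric {metric!r} not present in summary table")
    wide = sub.pivot(index="scenario", columns="design", values="value")
    if ax is None:
        _, ax = plt.subplots(figsize=(1.2 + 1.1 * len(wide), 3.2))
    wide.plot.bar(ax=ax, width=0.8)
    ax.set_ylabel(metric)
    ax.set_xlabel("scenario")
    ax.legend(title="design", fontsize="small")
    return ax


def plot_summary_grid(long_df: pd.DataFrame,
                      metrics: tuple[str, ...] = ("accuracy_median",
                                                  "accuracy_next_dose",
                                                  "mean_bias_next_dose",
                                                  "rmse_next_dose",
                                                  "mean_dlts",
                                                  "violation_pct"),
                      path: str | None = None):
    """One panel per metric; optionally save the figure to ``path``."""
    present = [m for m in metrics
               if not long_df[long_df["metric"] == m].empty]
    fig, axes = plt.subplots(len(present), 1,
                             figsize=(8, 3.0 * len(present)), squeeze=False)
    for ax, metric in zip(axes.ravel(), present):
        plot_metric(long_df, metric, ax=ax)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig
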