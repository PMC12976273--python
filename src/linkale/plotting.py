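"""Plots for explanation curves and study results (cosmetic, untested)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .ale import ALEProfile
from .synthetic import GroundTruthCurve


def plot_profiles(
    profiles: list[ALEProfile],
    path: str | Path,
    ground_truth: GroundTruthCurve | None = None,
    aggregate_exact: ALEProfile | None = None,
    aggregate_approximate: ALEProfile | None = None,
) -> None:
    """Single-run curves (hue = number of predictions) plus aggregates.

    Aggregated exact is drawn in red and aggregated approximate in blue,
    single runs in a colormap keyed to their prediction counts.
    """
    fig, ax = plt.subplots(figsize=(6, 4))
    if profiles:
        budgets = [p.bin_counts.sum() for p in profiles]
        norm = matplotlib.colors.LogNorm(max(min(budgets), 1), max(max(budgets), 2))
        cmap = matplotlib.colormaps["viridis"]
        for p, b in zip(profiles, budgets):
            ax.plot(p.bin_edges[1:], p.values, color=cmap(norm(b)), alpha=0.5, lw=1)
        sm = matplotlib.cm.ScalarMappable(norm=norm, cmap=cmap)
        fig.colorbar(sm, ax=ax, label="predictions per curve")
    if aggregate_exact is not None:
        ax.plot(aggregate_exact.bin_edges[1:], aggregate_exact.values,
                color="red", lw=2, label="aggregated exact")
    if aggregate_approximate is not None:
        ax.plot(aggregate_approximate.bin_edges[1:], aggregate_approximate.values,
                color="blue", lw=2, label="aggregated approximate")
    if ground_truth is not None:
        ax.plot(ground_truth.bin_edges, ground_truth.values, "k--", lw=1.5,
                label="ground truth")
    ax.set_xlabel("feature value")
    ax.set_ylabel("accumulated local effect")
    if ax.get_legend_handles_labels()[0]:
        ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_rmse_vs_m(table, path: str | Path) -> None:
    """Mean RMSE-to-ground-truth versus m, one panel per architecture."""
    archs = sorted(table["architecture"].unique())
    fig, axes = plt.subplots(1, len(archs), figsize=(5 * len(archs), 4),
                             squeeze=False)
    for ax, arch in zip(axes[0], archs):
        sub = table[table["architecture"] == arch]
        for method, color in [("exact", "red"), ("approximate", "blue")]:
            g = sub[sub["method"] == method].groupby("m")["rmse_ground_truth"]
            mean, sd = g.mean(), g.std()
            ax.errorbar(mean.index, mean.values, yerr=sd.values, color=color,
                        marker="o", capsize=3, label=method)
        ax.set_xscale("log", base=2)
        ax.set_xlabel("m (modified nodes)")
        ax.set_ylabel("RMSE to ground truth")
        ax.set_title(arch)
        ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
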