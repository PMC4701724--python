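"""Diagnostic plots: series overlays, hindcast/forecast metric pairs,
PCA biplot, and the quantile-comparison heat table.

Plots are a side product; stored tables are never clamped even when the
plot axes are.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .metrics import METRIC_CODES
from .pipeline import PCAResult, QuantileComparison
from .timeseries import SkillTable, TimeSeries

CATEGORY_COLORS = {"biomass": "tab:blue", "landings": "tab:orange",
                   "indicator": "tab:green"}


def plot_series_overlay(
    obs: TimeSeries, mod: TimeSeries, path, forecast_start: int | None = None
) -> None:
    fig, ax = plt.subplots(figsize=(7, 3.5))
    color = CATEGORY_COLORS.get(obs.category, "tab:gray")
    ax.plot(obs.years, obs.values, "o-", color=color, label="observed", ms=3)
    ax.plot(mod.years, mod.values, "-", color=color, alpha=0.5, label="modeled")
    if forecast_start is not None:
        ax.axvspan(forecast_start, max(obs.years.max(), mod.years.max()),
                   color="0.9", zorder=0)
    ax.set_title(obs.series_id)
    ax.set_xlabel("year")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_metric_pairs(
    table: SkillTable,
    category: str,
    path,
    hindcast_period: str = "full_hindcast",
    forecast_period: str = "forecast",
    clamp: tuple[float, float] | None = (-2.0, 2.0),
) -> None:
    """Hindcast-vs-forecast scatter, one panel per metric.  ``clamp``
    limits the axes only; the underlying values are untouched."""
    f = table.frame
    fig, axes = plt.subplots(2, 4, figsize=(12, 6))
    for ax, metric in zip(axes.flat, METRIC_CODES):
        sub = f[(f.category == category) & (f.metric == metric)]
        h = sub[sub.period == hindcast_period].set_index("series_id")["value"]
        fc = sub[sub.period == forecast_period].set_index("series_id")["value"]
        common = h.index.intersection(fc.index)
        ax.scatter(h.loc[common], fc.loc[common], s=12,
                   color=CATEGORY_COLORS.get(category, "tab:gray"))
        ax.axline((0, 0), slope=1, color="0.7", lw=0.8)
        if clamp is not None:
            ax.set_xlim(clamp)
            ax.set_ylim(clamp)
        ax.set_title(metric, fontsize=9)
        ax.set_xlabel("hindcast", fontsize=8)
        ax.set_ylabel("forecast", fontsize=8)
    axes.flat[-1].axis("off")
    fig.suptitle(f"{category}: hindcast vs forecast skill")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_pca_biplot(result: PCAResult, path, title: str = "") -> None:
    fig, ax = plt.subplots(figsize=(6, 6))
    scores = result.scores
    loadings = result.loadings
    ax.scatter(scores["PC1"], scores["PC2"], s=10, color="black")
    for name, row in scores.iterrows():
        ax.annotate(str(name), (row["PC1"], row["PC2"]), fontsize=6, alpha=0.7)
    scale = np.abs(scores[["PC1", "PC2"]].to_numpy()).max() or 1.0
    for name, row in loadings.iterrows():
        ax.annotate(
            "", xy=(row["PC1"] * scale, row["PC2"] * scale), xytext=(0, 0),
            arrowprops=dict(arrowstyle="->", color="red", lw=1),
        )
        ax.annotate(str(name), (row["PC1"] * scale, row["PC2"] * scale),
                    color="red", fontsize=8)
    ve = result.variance_explained
    ax.set_xlabel(f"PC1 ({100 * ve[0]:.1f}%)")
    ax.set_ylabel(f"PC2 ({100 * ve[1]:.1f}%)")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


_CLASS_COLORS = {"below_40": "#f4a6b8", "mid_40_60": "#f5e663",
                 "above_60": "#8fd18f"}


def plot_comparison_table(comparison: QuantileComparison, path) -> None:
    cells = comparison.cells
    pivot = cells.pivot(index=["category", "series_id"], columns="metric",
                        values="class")
    pivot = pivot.reindex(columns=[m for m in METRIC_CODES if m in pivot.columns])
    pivot.index = [f"{cat}:{sid}" for cat, sid in pivot.index]
    rgb = np.ones(pivot.shape + (3,))
    for i, (_, row) in enumerate(pivot.iterrows()):
        for j, cls in enumerate(row):
            if isinstance(cls, str):
                rgb[i, j] = matplotlib.colors.to_rgb(_CLASS_COLORS[cls])
    fig, ax = plt.subplots(figsize=(1 + 0.6 * pivot.shape[1],
                                    1 + 0.25 * pivot.shape[0]))
    ax.imshow(rgb, aspect="auto")
    ax.set_xticks(range(pivot.shape[1]), pivot.columns, fontsize=8)
    ax.set_yticks(range(pivot.shape[0]), pivot.index, fontsize=6)
    ax.set_title("forecast skill vs hindcast quantiles")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
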