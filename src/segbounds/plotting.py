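"""Figures: metric box plots, rank heat map, MDS scatter, profile overlays.

Each function draws onto a provided or fresh matplotlib Axes and returns it,
so figures compose into panels.  Nothing here feeds back into any
computation.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")  # headless by default; callers can switch backends first
import matplotlib.pyplot as plt
import pandas as pd

from .analysis import ComparisonTable
from .io import Annotation
from .profiles import kde_curve

_GROUP_COLORS = {"AV": "tab:red", "A": "tab:orange", "V": "tab:blue",
                 "P": "tab:purple", "W": "tab:green"}


def plot_distance_boxes(table: ComparisonTable, ax: plt.Axes | None = None) -> plt.Axes:
    """Horizontal box plots of per-piece distances, one row per comparison."""
    ax = ax or plt.subplots(figsize=(6, 4))[1]
    values = table.values.dropna()
    ax.boxplot([values[c].to_numpy() for c in values.columns],
               tick_labels=list(values.columns), vert=False)
    ax.set_xlabel("uOT distance" if table.metric == "uot" else "1 - F_alpha")
    return ax


def plot_rank_heatmap(ranks: pd.DataFrame, ax: plt.Axes | None = None) -> plt.Axes:
    """Per-piece comparison ranks: darker means smaller distance."""
    ax = ax or plt.subplots(figsize=(10, 3))[1]
    im = ax.imshow(ranks.to_numpy().T, aspect="auto", cmap="viridis_r")
    ax.set_yticks(range(len(ranks.columns)), ranks.columns)
    ax.set_xticks(range(len(ranks.index)), ranks.index, rotation=90, fontsize=6)
    ax.figure.colorbar(im, ax=ax, label="rank (1 = smallest distance)")
    return ax


def plot_mds(coords: pd.DataFrame, ax: plt.Axes | None = None) -> plt.Axes:
    """Scatter of the 2-D MDS embedding, coloured by grouped condition."""
    ax = ax or plt.subplots(figsize=(5, 5))[1]
    for group, sub in coords.groupby("group"):
        ax.scatter(sub["dim1"], sub["dim2"], s=12,
                   color=_GROUP_COLORS.get(group, "gray"), label=group)
    ax.legend(title="condition")
    ax.set_xlabel("dim 1")
    ax.set_ylabel("dim 2")
    return ax


def plot_profiles(
    pooled: Mapping[str, Sequence[Annotation]],
    duration_s: float,
    bandwidth_s: float = 0.5,
    removed_times: Sequence[float] = (),
    ax: plt.Axes | None = None,
) -> plt.Axes:
    """KDE boundary profiles per grouped condition for one piece.

    Audio-bearing groups (AV, A) draw as solid lines, visual-only groups as
    shaded areas; vertical dashed lines mark boundaries destroyed by the
    transport computation.
    """
    ax = ax or plt.subplots(figsize=(8, 3))[1]
    for group, annotations in pooled.items():
        if not annotations:
            continue
        curve = kde_curve(annotations, duration_s, bandwidth_s)
        color = _GROUP_COLORS.get(group, "gray")
        if group in ("AV", "A"):
            ax.plot(curve.times, curve.density, color=color, label=group)
        else:
            ax.fill_between(curve.times, curve.density, color=color, alpha=0.35, label=group)
    for t in removed_times:
        ax.axvline(t, linestyle="--", color="k", linewidth=0.8)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("boundary density")
    ax.legend()
    return ax
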