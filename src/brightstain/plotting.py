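"""Plot helpers for the profiling outputs (matplotlib, Agg-safe)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def plot_group_correlation_heatmap(group_means: pd.DataFrame, ax=None):
    """Heatmap of mean Spearman r, (compartment, feature_type) × channel."""
    table = group_means["mean_r"].reset_index().pivot_table(
        index=["compartment", "feature_type"], columns="channel", values="mean_r")
    if ax is None:
        _, ax = plt.subplots(figsize=(1.2 * len(table.columns) + 3,
                                      0.4 * len(table) + 2))
    im = ax.imshow(table.to_numpy(float), vmin=-1, vmax=1, cmap="RdBu_r", aspect="auto")
    ax.set_xticks(range(len(table.columns)), table.columns)
    ax.set_yticks(range(len(table)), [f"{c} / {t}" for c, t in table.index])
    for i in range(table.shape[0]):
        for j in range(table.shape[1]):
            v = table.iloc[i, j]
            if np.isfinite(v):
                ax.text(j, i, f"{v:.2f}", ha="center", va="center", fontsize=8)
    ax.figure.colorbar(im, ax=ax, label="mean Spearman r")
    ax.set_title("Predicted vs ground-truth feature correlation")
    return ax


def plot_embedding(coords: pd.DataFrame, labels: pd.Series, ax=None):
    """Scatter of 2-D profile embedding colored by a categorical label."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    for value in pd.unique(labels):
        mask = (labels == value).to_numpy()
        ax.scatter(coords.iloc[mask, 0], coords.iloc[mask, 1], s=14, label=str(value))
    ax.set_xlabel(coords.columns[0])
    ax.set_ylabel(coords.columns[1])
    ax.legend(frameon=False, fontsize=8)
    return ax
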