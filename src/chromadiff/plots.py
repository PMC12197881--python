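"""Figure rendering for the benchmark analyses (biplot, heatmaps, fits)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .evalstats import PCAResult

_COLORS = {
    "euclidean": "tab:red",
    "cie76lab": "tab:green",
    "cie76luv": "tab:blue",
    "cie94": "tab:orange",
    "cie00": "tab:brown",
    "cmc": "tab:purple",
}


def plot_biplot(result: PCAResult, path: str | Path) -> Path:
    """Score scatter colored by metric with loading arrows overlaid."""
    fig, ax = plt.subplots(figsize=(6, 5))
    for m in pd.unique(result.labels):
        pts = result.scores[result.labels == m]
        ax.scatter(pts[:, 0], pts[:, 1], s=18, label=m, color=_COLORS.get(m))
    span = np.abs(result.scores).max() or 1.0
    for name, (lx, ly) in zip(result.feature_names, result.loadings):
        ax.annotate(
            "", xy=(lx * span, ly * span), xytext=(0, 0),
            arrowprops=dict(arrowstyle="->", color="gray"),
        )
        ax.text(lx * span * 1.08, ly * span * 1.08, name, color="gray", fontsize=8)
    evr = result.explained_variance_ratio
    ax.set_xlabel(f"PC1 ({evr[0]:.0%})")
    ax.set_ylabel(f"PC2 ({evr[1]:.0%})")
    ax.legend(fontsize=8)
    ax.set_title("PCA biplot of error-matrix histogram statistics")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_heatmap(corr: pd.DataFrame, path: str | Path, title: str = "") -> Path:
    fig, ax = plt.subplots(figsize=(5, 4.4))
    im = ax.imshow(corr.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(corr.columns)), corr.columns, rotation=45, ha="right")
    ax.set_yticks(range(len(corr.index)), corr.index)
    for i in range(len(corr.index)):
        for j in range(len(corr.columns)):
            ax.text(j, i, f"{corr.iat[i, j]:.2f}", ha="center", va="center", fontsize=7)
    fig.colorbar(im, ax=ax, label="Pearson r")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
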