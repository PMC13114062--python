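"""Diagnostic figures: GA subset-size evolution, duration curves,
Jaccard heatmap, per-feature group boxplots."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .containers import FeatureMatrix
from .selection import SelectionResult

__all__ = ["plot_ga_evolution", "plot_duration_curves", "plot_jaccard_heatmap",
           "plot_feature_boxplots"]


def plot_ga_evolution(result: SelectionResult, path) -> None:
    """Best/mean subset size and best fitness across GA generations."""
    gens = np.arange(len(result.best_size_history))
    fig, ax1 = plt.subplots(figsize=(6, 4))
    ax1.plot(gens, result.best_size_history, "o-", label="best subset size")
    ax1.plot(gens, result.mean_size_history, "s--", label="population mean size")
    ax1.set_xlabel("generation")
    ax1.set_ylabel("subset size")
    ax2 = ax1.twinx()
    ax2.plot(gens, result.best_fitness_history, "r-", alpha=0.6, label="best fitness")
    ax2.set_ylabel("fitness")
    ax1.legend(loc="upper right")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_duration_curves(sweep: pd.DataFrame, path) -> None:
    fig, ax = plt.subplots(figsize=(6, 4))
    for model, grp in sweep.groupby("model"):
        ax.plot(grp["minutes"], grp["accuracy"], "o-", label=model)
    ax.set_xlabel("recording duration (min)")
    ax.set_ylabel("CV accuracy")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_jaccard_heatmap(matrix: np.ndarray, path) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(matrix, vmin=0, vmax=1, cmap="viridis")
    ax.set_xlabel("fold")
    ax.set_ylabel("fold")
    fig.colorbar(im, ax=ax, label="Jaccard similarity")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_feature_boxplots(features: FeatureMatrix, names: list[str], path) -> None:
    """Per-class boxplots of the requested features (e.g. the top-MI ones)."""
    n = len(names)
    fig, axes = plt.subplots(1, n, figsize=(3 * n, 3.5), squeeze=False)
    y = features.labels
    for ax, name in zip(axes[0], names):
        j = features.feature_names.index(name)
        ax.boxplot([features.values[y == 0, j], features.values[y == 1, j]],
                   tick_labels=["control", "patient"])
        ax.set_title(name, fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
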