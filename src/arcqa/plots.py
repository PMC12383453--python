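"""Figure helpers: correlation heatmap/dendrogram, scatter/residuals, curves, PDPs."""

from __future__ import annotations

import numpy as np

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
from scipy.cluster.hierarchy import dendrogram

from .feature_selection import CorrelationMatrix, FeatureClusters

__all__ = [
    "plot_correlation_heatmap", "plot_dendrogram", "plot_regression",
    "plot_curves", "plot_pdp_grid",
]


def plot_correlation_heatmap(corr: CorrelationMatrix, path) -> None:
    fig, ax = plt.subplots(figsize=(8, 7))
    im = ax.imshow(corr.values, vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(corr.features)), corr.features, rotation=90, fontsize=7)
    ax.set_yticks(range(len(corr.features)), corr.features, fontsize=7)
    fig.colorbar(im, ax=ax, label="Spearman $r_s$")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_dendrogram(clusters: FeatureClusters, features: list[str], path) -> None:
    fig, ax = plt.subplots(figsize=(8, 4))
    dendrogram(clusters.linkage_matrix, labels=features, ax=ax,
               color_threshold=clusters.threshold, leaf_font_size=7)
    ax.axhline(clusters.threshold, ls="--", c="grey", lw=0.8)
    ax.set_ylabel("linkage height")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_regression(measured: np.ndarray, predicted: np.ndarray, path) -> None:
    """Scatter plot and residual histogram side by side."""
    measured = np.asarray(measured, float)
    predicted = np.asarray(predicted, float)
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(10, 4))
    ax1.scatter(measured, predicted, s=6, alpha=0.4)
    lims = [min(measured.min(), predicted.min()), 100.0]
    ax1.plot(lims, lims, "k--", lw=0.8)
    ax1.axhline(predicted.mean(), c="C1", lw=0.8)
    ax1.set_xlabel("measured GPR (%)")
    ax1.set_ylabel("predicted GPR (%)")
    ax2.hist(measured - predicted, bins=40)
    ax2.set_xlabel("residual: measured $-$ predicted (%)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_curves(curves: dict, path) -> None:
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(10, 4))
    ax1.plot(curves["roc"]["fpr"], curves["roc"]["tpr"],
             label=f"AUC = {curves['auc']:.2f}")
    ax1.plot([0, 1], [0, 1], "k--", lw=0.8, label="chance")
    ax1.set_xlabel("1 - specificity")
    ax1.set_ylabel("sensitivity")
    ax1.legend()
    ax2.plot(curves["pr"]["recall"], curves["pr"]["precision"],
             label=f"AP = {curves['ap']:.2f}")
    ax2.axhline(curves["baseline_ap"], ls="--", c="k", lw=0.8, label="prevalence")
    ax2.set_xlabel("recall")
    ax2.set_ylabel("precision")
    ax2.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_pdp_grid(pdps: dict[str, dict], path) -> None:
    n = len(pdps)
    if n == 0:
        raise ValueError("no PDP curves to plot")
    ncols = min(n, 2)
    nrows = (n + ncols - 1) // ncols
    fig, axes = plt.subplots(nrows, ncols, figsize=(5 * ncols, 3.2 * nrows),
                             squeeze=False)
    for ax, (name, pdp) in zip(axes.ravel(), pdps.items()):
        ax.plot(pdp["grid"], pdp["mean_prediction"])
        ax.set_xlabel(name)
        ax.set_ylabel("mean predicted GPR (%)")
    for ax in axes.ravel()[n:]:
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
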