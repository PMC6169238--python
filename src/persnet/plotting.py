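"""Diagnostic figures: persistence diagrams, dendrograms, k-selection curves.

All functions write to a file path (Agg backend); they are conveniences for
inspecting a run, not part of the numerical pipeline.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from scipy.cluster import hierarchy

from .clustering import Dendrogram, KSelectionResult
from .homology import PersistenceDiagram

__all__ = ["plot_diagram", "plot_dendrogram", "plot_k_selection"]


def plot_diagram(
    diagram: PersistenceDiagram, path: "str | Path", title: str = ""
) -> None:
    """Birth/death scatter with the diagonal; H0 as dots, H1 as triangles."""
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    finite_max = 1.0
    for dim, marker, color in ((0, "o", "black"), (1, "^", "red")):
        pts = diagram.points(dim)
        if len(pts):
            finite_max = max(finite_max, float(pts.max()))
            ax.scatter(pts[:, 0], pts[:, 1], marker=marker, s=18,
                       color=color, label=f"$H_{dim}$", alpha=0.7)
    lim = finite_max * 1.05
    ax.plot([0, lim], [0, lim], color="grey", lw=0.8)
    ax.set_xlim(0, lim)
    ax.set_ylim(0, lim)
    ax.set_xlabel("birth")
    ax.set_ylabel("death")
    ax.legend(loc="lower right")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_dendrogram(tree: Dendrogram, path: "str | Path") -> None:
    fig, ax = plt.subplots(figsize=(max(6, 0.3 * tree.n_leaves), 4))
    hierarchy.dendrogram(tree.linkage, labels=list(tree.labels), ax=ax,
                         leaf_rotation=90)
    ax.set_ylabel("Ward merge height")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_k_selection(ksel: KSelectionResult, path: "str | Path") -> None:
    """WSS and BIC against k, with the selected k marked."""
    fig, axes = plt.subplots(1, 2, figsize=(8, 3.5))
    axes[0].plot(ksel.k_grid, ksel.wss_curve, "o-")
    axes[0].set_xlabel("k")
    axes[0].set_ylabel("within sum of squares")
    axes[1].plot(ksel.k_grid, ksel.bic_curve, "o-")
    axes[1].axvline(ksel.k_selected, color="red", ls="--", lw=0.8,
                    label=f"selected k={ksel.k_selected}")
    axes[1].set_xlabel("k")
    axes[1].set_ylabel("BIC")
    axes[1].legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
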