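"""Vector-figure output: discretized correlation heatmaps and PCA maps."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .coordination import SignatureResult
from .pca import PCAResult


def plot_discretized_heatmap(sig: SignatureResult, path: str | Path,
                             show_labels: bool | None = None) -> None:
    """Write the hierarchically ordered discretized matrix as a vector
    heatmap (PDF/SVG by extension). Blue = anticorrelated, white = none,
    red = correlated."""
    order = sig.dendrogram_order
    disc = sig.discretized[np.ix_(order, order)]
    genes = [sig.matrix_genes[i] for i in order]
    n = len(genes)
    if show_labels is None:
        show_labels = n <= 60
    fig, ax = plt.subplots(figsize=(max(4, n * 0.12), max(4, n * 0.12)))
    ax.imshow(disc, cmap="bwr", vmin=-1, vmax=1, interpolation="nearest")
    if show_labels:
        ax.set_xticks(range(n), genes, rotation=90, fontsize=5)
        ax.set_yticks(range(n), genes, fontsize=5)
    else:
        ax.set_xticks([])
        ax.set_yticks([])
    title = f"anchor {sig.anchor}" if sig.anchor else "transferred signature"
    ax.set_title(f"{title} | n={sig.n_cells} cells | |rho|>={sig.rho_threshold:g}")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_pca_scatter(pca: PCAResult, path: str | Path, colors=None) -> None:
    """PC1/PC2 scatter with explained-variance percentages in the axis
    labels; ``colors`` is an optional per-cell vector."""
    fig, ax = plt.subplots(figsize=(5, 4))
    sc = ax.scatter(pca.scores[:, 0], pca.scores[:, 1], c=colors, s=18,
                    cmap="viridis")
    if colors is not None:
        fig.colorbar(sc, ax=ax, shrink=0.8)
    ev = pca.explained_fraction
    ax.set_xlabel(f"PC1 ({100 * ev[0]:.2f}%)")
    if len(ev) > 1:
        ax.set_ylabel(f"PC2 ({100 * ev[1]:.2f}%)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
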