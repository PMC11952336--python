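"""Static matplotlib views of embeddings and decompositions.

Deliberately minimal: a scatter of genotypes on two diffusion axes colored
by phenotype, and a bar chart of variance by interaction order.  Interactive
or rasterized rendering of very large maps is out of scope; export the
node/edge tables instead.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .decomposition import VarianceDecomposition
from .evolution import Embedding
from .space import Landscape

__all__ = ["plot_embedding", "plot_variance_by_order"]


def plot_embedding(embedding: Embedding, landscape: Landscape,
                   axes: tuple[int, int] = (1, 2), path=None,
                   point_size: float = 4.0):
    """Scatter genotypes on two diffusion axes, colored by phenotype."""
    ax1, ax2 = axes
    for ax in axes:
        if not 1 <= ax <= embedding.n_axes:
            raise ValueError(f"diffusion axis {ax} out of range")
    fig, ax = plt.subplots(figsize=(6, 5))
    order = np.argsort(landscape.values)  # draw fittest on top
    sc = ax.scatter(embedding.coords[order, ax1 - 1],
                    embedding.coords[order, ax2 - 1],
                    c=landscape.values[order], s=point_size, cmap="viridis",
                    linewidths=0)
    fig.colorbar(sc, ax=ax, label=landscape.label or "phenotype")
    ax.set_xlabel(f"Diffusion axis {ax1}")
    ax.set_ylabel(f"Diffusion axis {ax2}")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_variance_by_order(dec: VarianceDecomposition, path=None):
    """Percent of variance explained by each epistatic order (k >= 1)."""
    pct = dec.percent_by_order[1:]
    orders = np.arange(1, len(pct) + 1)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.bar(orders, pct, color="steelblue")
    ax.plot(orders, np.cumsum(pct), "o-", color="grey", label="cumulative")
    ax.set_xlabel("interaction order k")
    ax.set_ylabel("% of variance")
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
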