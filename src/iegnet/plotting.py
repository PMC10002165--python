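"""Optional, purely cosmetic figures (heatmaps, network drawings).

All analysis surfaces are file-based numbers; figures are flag-gated in
the pipeline so headless runs never need a display.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np


def _plt():
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    return plt


def correlation_heatmap(cm, order=None, path: str | Path | None = None, ax=None):
    """Diverging heatmap of a correlation matrix, optionally reordered
    by the hierarchical-clustering display order."""
    plt = _plt()
    rois = list(cm.rois)
    idx = [rois.index(r) for r in (order or rois)]
    R = np.asarray(cm.r)[np.ix_(idx, idx)]
    labels = [rois[i] for i in idx]
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 7))
    im = ax.imshow(R, vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(labels)), labels, rotation=90, fontsize=5)
    ax.set_yticks(range(len(labels)), labels, fontsize=5)
    ax.set_title(f"Pearson r — {cm.group}" if cm.group else "Pearson r")
    ax.figure.colorbar(im, ax=ax, shrink=0.8)
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def network_figure(net, path: str | Path | None = None, ax=None):
    """Spring-layout drawing of a thresholded network, nodes colored by
    degree, edges colored by correlation sign."""
    import networkx as nx

    plt = _plt()
    G = net.graph
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 7))
    pos = nx.spring_layout(G, seed=0)
    degrees = [G.degree(v) for v in G.nodes]
    colors = ["#b2182b" if d["weight"] >= 0 else "#2166ac"
              for _, _, d in G.edges(data=True)]
    nx.draw_networkx(
        G, pos, ax=ax, node_color=degrees, cmap="viridis",
        edge_color=colors, node_size=250, font_size=6, width=0.8,
    )
    ax.set_axis_off()
    if net.source_group:
        ax.set_title(f"Thresholded network — {net.source_group}")
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
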