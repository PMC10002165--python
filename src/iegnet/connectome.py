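"""Per-group correlation matrices and significance-thresholded networks.

Within each treatment group, co-expression across animals is summarized
by the Pearson correlation of every ROI pair; each coefficient gets a
two-sided p-value from the exact t transform t = r sqrt((n-2)/(1-r^2))
with n-2 degrees of freedom.  A brain network keeps the ROI pairs with
p below the threshold (0.05 by default, deliberately uncorrected: the
working point trades sensitivity against specificity), with the signed
correlation as edge weight; ROIs left without any retained edge are
dropped from the node list.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform

from .data import ExpressionTable
from . import metrics as _metrics

__all__ = [
    "CorrelationMatrix",
    "BrainNetwork",
    "pearson_matrix",
    "correlation_pvalues",
    "significance_r_threshold",
    "build_network",
    "hierarchical_order",
    "ConnectomeModel",
    "ConnectomeResults",
]


@dataclass
class CorrelationMatrix:
    """Symmetric Pearson r matrix with paired p-values and sample size.

    Constant-valued ROI columns make every pair involving them
    undefined; those entries are NaN and flagged in ``undefined``.
    The diagonal is 1 by convention (p = 1).
    """

    rois: list[str]
    r: np.ndarray
    p: np.ndarray
    n: int
    group: str | None = None
    undefined: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        m = len(self.rois)
        if self.r.shape != (m, m) or self.p.shape != (m, m):
            raise ValueError("correlation/p matrices must be square over the ROIs")
        if self.undefined is None:
            self.undefined = ~np.isfinite(self.r) & ~np.eye(m, dtype=bool)

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        return (
            pd.DataFrame(self.r, index=self.rois, columns=self.rois),
            pd.DataFrame(self.p, index=self.rois, columns=self.rois),
        )

    def write_csv(self, r_path: str | Path, p_path: str | Path) -> None:
        rf, pf = self.to_frames()
        rf.to_csv(r_path)
        pf.to_csv(p_path)


def correlation_pvalues(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p-values for Pearson r via the exact t transform (df = n-2)."""
    r = np.asarray(r, dtype=float)
    df = n - 2
    if df < 1:
        raise ValueError(f"need n >= 3 animals for correlation p-values, got n={n}")
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / (1.0 - r**2))
        t = np.where(np.isclose(np.abs(r), 1.0), np.inf, np.abs(t))
    p = 2.0 * stats.t.sf(t, df)
    return np.where(np.isnan(r), np.nan, np.clip(p, 0.0, 1.0))


def significance_r_threshold(n: int, threshold_p: float = 0.05) -> float:
    """|r| above which the two-sided p at df = n-2 falls below threshold_p."""
    df = n - 2
    if df < 1:
        raise ValueError("need n >= 3")
    t_crit = stats.t.isf(threshold_p / 2.0, df)
    return float(t_crit / np.sqrt(df + t_crit**2))


def pearson_matrix(table: ExpressionTable) -> CorrelationMatrix:
    """All-pairs Pearson correlation of one group's expression table.

    Constant columns (zero variance across animals) yield undefined
    correlations: NaN entries, flagged, excluded from edge candidates.
    """
    X = table.values
    n, m = X.shape
    sd = X.std(axis=0, ddof=1)
    constant = sd == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.corrcoef(X, rowvar=False)
    r = np.asarray(r, dtype=float)
    r = np.clip(r, -1.0, 1.0)
    r[constant, :] = np.nan
    r[:, constant] = np.nan
    np.fill_diagonal(r, 1.0)
    p = correlation_pvalues(r, n)
    np.fill_diagonal(p, 1.0)
    undefined = np.zeros((m, m), dtype=bool)
    undefined[constant, :] = True
    undefined[:, constant] = True
    np.fill_diagonal(undefined, False)
    return CorrelationMatrix(
        rois=list(table.rois), r=r, p=p, n=n, group=table.group, undefined=undefined
    )


@dataclass
class BrainNetwork:
    """Significance-thresholded, weighted, undirected ROI graph.

    Nodes are the ROIs retaining at least one significant edge; each
    edge carries the signed correlation as ``weight`` and its p-value.
    """

    graph: nx.Graph
    threshold_p: float
    source_group: str | None = None
    rois_all: list[str] = field(default_factory=list)

    @property
    def nodes(self) -> list[str]:
        order = {roi: i for i, roi in enumerate(self.rois_all)}
        return sorted(self.graph.nodes, key=lambda x: order.get(x, len(order)))

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_frame(self) -> pd.DataFrame:
        rows = [
            (u, v, d["weight"], d["p"]) for u, v, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["source", "target", "weight", "p"])

    def write_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self.graph, path)

    def write_edgelist(self, path: str | Path) -> None:
        """Cytoscape-compatible weighted edge list (source, target, weight, p)."""
        self.edge_frame().to_csv(path, index=False)


def build_network(cm: CorrelationMatrix, threshold_p: float = 0.05) -> BrainNetwork:
    """Keep ROI pairs with p < threshold_p; drop ROIs left isolated.

    Negative-weight edges are retained — anticorrelations are part of
    the connectivity pattern, not noise.
    """
    m = len(cm.rois)
    G = nx.Graph()
    iu, ju = np.triu_indices(m, k=1)
    keep = (cm.p[iu, ju] < threshold_p) & ~cm.undefined[iu, ju]
    for i, j in zip(iu[keep], ju[keep]):
        G.add_edge(
            cm.rois[i], cm.rois[j], weight=float(cm.r[i, j]), p=float(cm.p[i, j])
        )
    return BrainNetwork(
        graph=G,
        threshold_p=threshold_p,
        source_group=cm.group,
        rois_all=list(cm.rois),
    )


def hierarchical_order(cm: CorrelationMatrix, method: str = "average") -> list[str]:
    """Dendrogram leaf order from agglomerative clustering on 1 - r.

    Average linkage by default (the linkage is a display choice and is
    recorded in run manifests).  Undefined correlations must be
    resolved by dropping the offending ROI before ordering.
    """
    if np.asarray(cm.undefined).any():
        bad = [cm.rois[i] for i in np.unique(np.nonzero(cm.undefined)[0])]
        raise ValueError(
            f"undefined correlations involving {bad}; drop these ROIs before ordering"
        )
    D = 1.0 - cm.r
    D = (D + D.T) / 2.0
    np.fill_diagonal(D, 0.0)
    Z = linkage(squareform(D, checks=False), method=method)
    return [cm.rois[i] for i in leaves_list(Z)]


class ConnectomeModel:
    """Model object: one group's expression connectome.

    ``ConnectomeModel(table).fit()`` estimates the Pearson correlation
    matrix, thresholds it into a network, and summarizes the network's
    graph metrics.
    """

    def __init__(self, table: ExpressionTable, threshold_p: float = 0.05):
        self.table = table
        self.threshold_p = threshold_p

    def fit(self) -> "ConnectomeResults":
        corr = pearson_matrix(self.table)
        network = build_network(corr, self.threshold_p)
        panel = _metrics.network_metrics(
            network, cm=corr if not corr.undefined.any() else None
        )
        try:
            order = hierarchical_order(corr)
        except ValueError:
            order = None
        return ConnectomeResults(
            model=self, corr=corr, network=network, metrics=panel, display_order=order
        )


@dataclass
class ConnectomeResults:
    """Fitted connectome: correlation matrix, network, metric panel."""

    model: ConnectomeModel
    corr: CorrelationMatrix
    network: BrainNetwork
    metrics: _metrics.NetworkMetrics
    display_order: list[str] | None

    def summary(self) -> str:
        m = self.metrics
        gs = "n/a" if m.global_strength is None else f"{m.global_strength:.3f}"
        return "\n".join(
            [
                f"Connectome for group {self.corr.group!r} "
                f"(n = {self.corr.n} animals, {len(self.corr.rois)} ROIs, "
                f"edge threshold p < {self.network.threshold_p})",
                f"  nodes retained:           {m.n_nodes}",
                f"  edges retained:           {m.n_edges}",
                f"  network density:          {m.density:.3f}",
                f"  characteristic path len.: {m.characteristic_path_length:.3f}",
                f"  connected components:     {m.n_components}",
                f"  clustering coefficient:   {m.clustering_coefficient:.3f}",
                f"  global strength (full r): {gs}",
            ]
        )
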