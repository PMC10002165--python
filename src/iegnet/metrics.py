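"""Global and per-node graph measures of thresholded expression networks.

Conventions (all deliberate, see docs/methods.md):

* Network density is the ordered-pair ratio E / (N(N-1)).  A complete
  undirected graph therefore has density 0.5, not 1.0 — this is the
  convention under which the published node/edge/density triples are
  internally consistent, and it is kept prominently documented.
* Path length, clustering, components and betweenness are computed on
  the unweighted thresholded graph: edge weights (correlations) carry
  sign, and negative weights have no shortest-path semantics.
* Characteristic path length averages over connected node pairs only,
  so disconnected graphs still get a finite value.
* Global strength is the sum of |r| over all unordered ROI pairs of the
  full (unthresholded) correlation matrix — the whole-network statistic
  used by the permutation comparison; a thresholded variant is a flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np

__all__ = [
    "NetworkMetrics",
    "network_density",
    "characteristic_path_length",
    "clustering_coefficient",
    "connected_components",
    "node_centralities",
    "global_strength",
    "network_metrics",
]


def _as_graph(net) -> nx.Graph:
    """Accept a BrainNetwork (wraps .graph) or a bare networkx graph."""
    if isinstance(net, nx.Graph):
        return net
    return net.graph


def network_density(n_nodes: int, n_edges: int) -> float:
    """Edge count over ordered node pairs: E / (N(N-1))."""
    if n_nodes < 2:
        raise ValueError(f"density needs at least 2 nodes, got {n_nodes}")
    return n_edges / (n_nodes * (n_nodes - 1))


def characteristic_path_length(net) -> float:
    """Mean unweighted shortest-path length over connected node pairs.

    Pairs in different components are excluded, so graphs with several
    components still have a finite value.  A graph without edges has no
    connected pair and raises.
    """
    G = _as_graph(net)
    if G.number_of_edges() == 0:
        raise ValueError("characteristic path length is undefined without edges")
    total = 0
    count = 0
    for comp in nx.connected_components(G):
        if len(comp) < 2:
            continue
        sub = G.subgraph(comp)
        for _, dists in nx.all_pairs_shortest_path_length(sub):
            total += sum(dists.values())
            count += len(dists) - 1  # exclude the zero self-distance
    return total / count


def clustering_coefficient(net, variant: str = "average") -> float:
    """Mean local clustering coefficient (default) or global transitivity.

    Nodes of degree < 2 contribute 0 to the average-local variant.
    """
    G = _as_graph(net)
    if variant == "average":
        if G.number_of_nodes() == 0:
            raise ValueError("clustering coefficient of an empty graph")
        local = nx.clustering(G)
        return sum(local.values()) / len(local)
    if variant == "transitivity":
        return nx.transitivity(G)
    raise ValueError(f"unknown clustering variant {variant!r}")


def connected_components(net) -> tuple[int, list[set]]:
    """Component count and node partition over retained nodes."""
    G = _as_graph(net)
    parts = [set(c) for c in nx.connected_components(G)]
    return len(parts), parts


def node_centralities(net, normalized: bool = False) -> tuple[dict, dict]:
    """Per-node degree and betweenness centrality.

    Betweenness is the sum over node pairs of the fraction of shortest
    paths through the node; unnormalized by default, the normalized
    variant divides by (N-1)(N-2)/2.
    """
    G = _as_graph(net)
    degree = dict(G.degree())
    betweenness = nx.betweenness_centrality(G, normalized=normalized)
    return degree, betweenness


def global_strength(cm, thresholded: bool = False, threshold_p: float = 0.05) -> float:
    """Sum of |r| over unordered off-diagonal ROI pairs.

    Operates on the full correlation matrix by default (the
    network-comparison statistic); ``thresholded=True`` restricts the
    sum to pairs significant at ``threshold_p``.
    """
    r = np.asarray(cm.r, dtype=float)
    mask = ~np.eye(len(r), dtype=bool)
    if thresholded:
        mask &= np.asarray(cm.p) < threshold_p
    vals = r[mask]
    if np.isnan(vals).any():
        raise ValueError("global strength is undefined with undefined correlations")
    return float(np.abs(vals).sum() / 2)


@dataclass
class NetworkMetrics:
    """Global and per-node summary of one thresholded network."""

    n_nodes: int
    n_edges: int
    density: float
    characteristic_path_length: float
    n_components: int
    clustering_coefficient: float
    degree: dict
    betweenness: dict
    global_strength: float | None = None

    def to_dict(self) -> dict:
        return {
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "density": self.density,
            "characteristic_path_length": self.characteristic_path_length,
            "n_components": self.n_components,
            "clustering_coefficient": self.clustering_coefficient,
            "global_strength": self.global_strength,
            "degree": dict(self.degree),
            "betweenness": dict(self.betweenness),
        }


def network_metrics(net, cm=None) -> NetworkMetrics:
    """Assemble the full metric panel for one network.

    Degenerate graphs get NaN where a measure is undefined (density
    below 2 nodes, path length without edges).  ``cm`` adds the global
    strength of the source correlation matrix.
    """
    G = _as_graph(net)
    n, e = G.number_of_nodes(), G.number_of_edges()
    density = network_density(n, e) if n >= 2 else math.nan
    cpl = characteristic_path_length(G) if e > 0 else math.nan
    clustering = clustering_coefficient(G) if n > 0 else math.nan
    n_comp, _ = connected_components(G)
    degree, betweenness = node_centralities(G)
    gs = global_strength(cm) if cm is not None else None
    return NetworkMetrics(
        n_nodes=n,
        n_edges=e,
        density=density,
        characteristic_path_length=cpl,
        n_components=n_comp,
        clustering_coefficient=clustering,
        degree=degree,
        betweenness=betweenness,
        global_strength=gs,
    )
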