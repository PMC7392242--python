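"""Node centralities, components and edge summaries for weighted
partial-correlation networks.

Edges carry length ``1 / |rho|`` (the convention in weighted psychometric
networks: stronger association = shorter path). Strength is the sum of
absolute incident weights; closeness the inverse total shortest distance;
betweenness the Brandes count of shortest paths through a node over
unordered pairs, with equal-length ties split fractionally. Centralities are
z-scored across all nodes of the network (n-1 SD) for comparability.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .datasets import EDGE_TOL, PcorNetwork
from .exceptions import ValidationError

__all__ = [
    "strength", "shortest_paths", "betweenness", "closeness",
    "connected_components", "global_strength", "edge_summary",
    "edge_weight_correlation", "centrality_report", "CentralityReport",
]


def _graph(network: PcorNetwork, tol: float = EDGE_TOL) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(network.nodes)
    for a, b, w in network.edges(tol):
        g.add_edge(a, b, weight=abs(w), length=1.0 / abs(w))
    return g


def strength(network: PcorNetwork) -> pd.Series:
    """Per-node sum of absolute incident edge weights (0 for isolates)."""
    s = np.abs(network.weights).sum(axis=0)
    return pd.Series(s, index=list(network.nodes), name="strength")


def _distance_matrix(network: PcorNetwork) -> np.ndarray:
    """All-pairs shortest distances on edge lengths 1/|rho| (Dijkstra)."""
    from scipy.sparse.csgraph import dijkstra

    w = np.abs(network.weights)
    with np.errstate(divide="ignore"):
        lengths = np.where(w > EDGE_TOL, 1.0 / np.where(w > EDGE_TOL, w, 1.0), 0.0)
    return dijkstra(lengths, directed=False)


def shortest_paths(network: PcorNetwork) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All-pairs shortest distances and shortest-path multiplicities.

    Distances use edge length ``1/|rho|`` (Dijkstra); unreachable pairs are
    infinite. The multiplicity matrix counts distinct shortest paths per
    pair (0 when unreachable, 1 on the diagonal).
    """
    g = _graph(network)
    nodes = list(network.nodes)
    p = len(nodes)
    dist = _distance_matrix(network)
    mult = np.zeros((p, p))
    np.fill_diagonal(mult, 1.0)
    for i, src in enumerate(nodes):
        for j, tgt in enumerate(nodes):
            if i != j and np.isfinite(dist[i, j]):
                paths = list(nx.all_shortest_paths(g, src, tgt, weight="length"))
                mult[i, j] = len(paths)
    return (pd.DataFrame(dist, index=nodes, columns=nodes),
            pd.DataFrame(mult, index=nodes, columns=nodes))


def betweenness(network: PcorNetwork) -> pd.Series:
    """Number of shortest paths between other node pairs passing through each
    node (unordered pairs; fractional credit for ties)."""
    g = _graph(network)
    bt = nx.betweenness_centrality(g, weight="length", normalized=False)
    return pd.Series({n: bt[n] for n in network.nodes}, name="betweenness")


def closeness(network: PcorNetwork, mode: str = "within_component") -> pd.Series:
    """Inverse of the summed shortest distances from a node to the others.

    ``within_component`` sums only the finite distances (nodes in the same
    component); an isolated node gets 0. ``all_nodes_zero_if_disconnected``
    assigns 0 to any node that cannot reach every other node, which treats
    the infinite between-component distance literally.
    """
    if mode not in ("within_component", "all_nodes_zero_if_disconnected"):
        raise ValidationError(f"unknown closeness mode {mode!r}")
    d = _distance_matrix(network)
    out = {}
    for i, node in enumerate(network.nodes):
        row = np.delete(d[i], i)
        if mode == "all_nodes_zero_if_disconnected" and not np.all(np.isfinite(row)):
            out[node] = 0.0
            continue
        finite = row[np.isfinite(row)]
        total = finite.sum()
        out[node] = 1.0 / total if total > 0 else 0.0
    return pd.Series(out, name="closeness")


def connected_components(network: PcorNetwork) -> list[frozenset]:
    """Partition of the nodes by nonzero-edge reachability."""
    g = _graph(network)
    return sorted((frozenset(c) for c in nx.connected_components(g)),
                  key=lambda c: (len(c), sorted(c)))


def global_strength(network: PcorNetwork) -> float:
    """Sum of absolute edge weights over the upper triangle."""
    return float(np.abs(network.upper_triangle()).sum())


def edge_summary(network: PcorNetwork, tol: float = EDGE_TOL) -> tuple[int, int, int]:
    """(edge count, positive count, negative count) at the zero tolerance."""
    ut = network.upper_triangle()
    return (int(np.sum(np.abs(ut) > tol)), int(np.sum(ut > tol)), int(np.sum(ut < -tol)))


def edge_weight_correlation(n1: PcorNetwork, n2: PcorNetwork) -> float:
    """Pearson correlation of the two networks' vectorized upper triangles.

    All node pairs enter, absent edges contributing 0; this measures
    agreement over the full matrix, shared structural zeros included.
    """
    if n1.nodes != n2.nodes:
        raise ValidationError("networks must share the same node order")
    a, b = n1.upper_triangle(), n2.upper_triangle()
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValidationError("edge-weight correlation undefined for a constant network")
    return float(np.corrcoef(a, b)[0, 1])


def _zscore(values: np.ndarray) -> np.ndarray:
    sd = values.std(ddof=1)
    if sd == 0:
        return np.zeros_like(values)
    return (values - values.mean()) / sd


@dataclass(frozen=True)
class CentralityReport:
    """Raw and z-scored strength/closeness/betweenness per node."""

    raw: pd.DataFrame
    z: pd.DataFrame

    @property
    def nodes(self) -> list[str]:
        return list(self.raw.index)


def centrality_report(network: PcorNetwork,
                      closeness_mode: str = "within_component") -> CentralityReport:
    """All three centrality indices, raw and z-scored across the full node
    set (z-scoring over all nodes, not per component, matches the published
    standardized tables)."""
    raw = pd.DataFrame({
        "strength": strength(network),
        "closeness": closeness(network, mode=closeness_mode),
        "betweenness": betweenness(network),
    })
    z = raw.apply(lambda col: _zscore(col.to_numpy()), axis=0)
    z = pd.DataFrame(z, index=raw.index, columns=raw.columns)
    return CentralityReport(raw=raw, z=z)
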