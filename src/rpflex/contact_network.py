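"""Pocket contact networks and their cross-model variability.

The fragment of RNA tertiary structure that forms a pocket is turned into a
graph: pocket-lining nucleotides are nodes and two nodes are joined when the
residues are non-adjacent in sequence (separation ≥ 2, so covalent
neighbours never count) and their closest heavy atoms are strictly closer
than 8 Å.

Four standard metrics summarize each model's network — average degree
<k> = 2L/N, average clustering coefficient <C>, diameter dmax and average
shortest-path length <d> — and their population standard deviations across a
group's m models measure how much the interaction pattern rearranges.
Multiplying each σ by the group's flexibility score Q gives the combined
scores (Q·σ<k>, Q·σ<C>, Q·σdmax, Q·σ<d>) used to weigh local against
long-range interaction changes.

Path-based metrics are computed on the largest connected component when the
graph is disconnected (infinite distances would poison the σ's); the result
carries a flag when that truncation happened.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .structure_io import StructureModel

__all__ = [
    "PocketNetwork",
    "NetworkFlexibility",
    "build_network",
    "network_metrics",
    "ensemble_network_flexibility",
]

ResidueID = tuple[str, int, str]


@dataclass
class PocketNetwork:
    """Contact graph of one model's pocket-lining nucleotides."""

    graph: nx.Graph
    model_index: int = 1

    @property
    def N(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def L(self) -> int:
        return self.graph.number_of_edges()


@dataclass
class NetworkFlexibility:
    per_model: dict[str, list[float]]  # metric name -> one value per model
    sigma: dict[str, float]  # σ<k>, σ<C>, σdmax, σ<d>
    combined: dict[str, float]  # Q·σ for each metric
    Q: float
    disconnected_models: list[int] = field(default_factory=list)


def build_network(
    model: StructureModel,
    nodes: list[ResidueID],
    cutoff: float = 8.0,
    min_seq_sep: int = 2,
    model_index: int = 1,
) -> PocketNetwork:
    """Heavy-atom contact graph over the given nucleotides of one model.

    Edge (u, v) iff sequence separation ≥ ``min_seq_sep`` and the minimum
    heavy-atom distance is strictly below ``cutoff`` Å.
    """
    index = {r.id: r for r in model.residues}
    missing = [rid for rid in nodes if rid not in index]
    if missing:
        raise ValueError(f"nodes not in model: {missing}")
    if len(nodes) < 2:
        warnings.warn("degenerate network: fewer than 2 nodes", stacklevel=2)

    graph = nx.Graph()
    graph.add_nodes_from(nodes)
    coords = {}
    trees = {}
    for rid in nodes:
        xyz = np.array([a.coords for a in index[rid].heavy_atoms()])
        coords[rid] = xyz
        trees[rid] = cKDTree(xyz) if xyz.size else None
    for a in range(len(nodes)):
        for b in range(a + 1, len(nodes)):
            u, v = nodes[a], nodes[b]
            if u[0] == v[0] and abs(u[1] - v[1]) < min_seq_sep:
                continue
            if trees[u] is None or coords[v].size == 0:
                continue
            dmin = trees[u].query(coords[v], k=1)[0].min()
            if dmin < cutoff:  # strictly below 8 Å
                graph.add_edge(u, v)
    return PocketNetwork(graph=graph, model_index=model_index)


def network_metrics(
    net: PocketNetwork,
) -> tuple[float, float, float, float]:
    """(<k>, <C>, dmax, <d>) of one network.

    <k> = 2L/N; <C> averages the per-node clustering coefficient with
    C_i = 0 for nodes of degree < 2; dmax and <d> use unweighted shortest
    paths on the largest connected component.
    """
    g = net.graph
    if g.number_of_nodes() < 1:
        raise ValueError("empty network")
    avg_degree = 2 * g.number_of_edges() / g.number_of_nodes()
    avg_clustering = float(np.mean(list(nx.clustering(g).values())))

    if g.number_of_nodes() == 1:
        return avg_degree, avg_clustering, 0.0, 0.0
    if nx.is_connected(g):
        comp = g
    else:
        comp = g.subgraph(max(nx.connected_components(g), key=len))
    if comp.number_of_nodes() < 2:
        dmax, avg_path = 0.0, 0.0
    else:
        dmax = float(nx.diameter(comp))
        avg_path = float(nx.average_shortest_path_length(comp))
    return avg_degree, avg_clustering, dmax, avg_path


METRIC_NAMES = ("avg_degree", "avg_clustering", "diameter", "avg_path_length")


def ensemble_network_flexibility(
    nets: list[PocketNetwork],
    Q: float,
) -> NetworkFlexibility:
    """Cross-model σ of each network metric and the Q·σ combined scores."""
    if len(nets) < 3:
        raise ValueError("need at least m = 3 networks")
    per_model: dict[str, list[float]] = {name: [] for name in METRIC_NAMES}
    disconnected = []
    for net in nets:
        values = network_metrics(net)
        for name, value in zip(METRIC_NAMES, values):
            per_model[name].append(value)
        if net.N and not nx.is_connected(net.graph) and net.N > 1:
            disconnected.append(net.model_index)
    sigma = {
        name: float(np.std(vals, ddof=0))
        for name, vals in per_model.items()
    }
    combined = {name: Q * s for name, s in sigma.items()}
    if disconnected:
        warnings.warn(
            f"disconnected networks in models {disconnected}; path metrics "
            "restricted to the largest component",
            stacklevel=2,
        )
    return NetworkFlexibility(
        per_model=per_model,
        sigma=sigma,
        combined=combined,
        Q=Q,
        disconnected_models=disconnected,
    )
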