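"""Module-level network (nodes = modules, edges = connectivity scores) and
its topology: density, characteristic path length, clustering coefficient
and small-worldness.

The connectivity score (CS) between two modules defaults to the absolute
Pearson correlation of their eigengenes (bounded in [0, 1], symmetric); an
alternative uses the mean inter-module adjacency.  Edges enter the module
graph when CS passes a threshold.  Small-worldness is measured as
``sigma = (C / C_rand) / (L / L_rand)`` against an ensemble of seeded
Erdos-Renyi G(n, m) graphs with matched node and edge counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .network import CoexpressionNetwork, ModulePartition

logger = logging.getLogger(__name__)

__all__ = [
    "ModuleGraph",
    "TopologyFeatures",
    "connectivity_score",
    "connectivity_matrix",
    "build_module_graph",
    "topology_features",
    "graph_topology",
]


@dataclass
class TopologyFeatures:
    n_nodes: int
    n_edges: int
    density: float
    characteristic_path_length: float
    clustering_coefficient: float
    small_world_sigma: float | None = None

    def to_dict(self) -> dict:
        return {
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "density": self.density,
            "characteristic_path_length": self.characteristic_path_length,
            "clustering_coefficient": self.clustering_coefficient,
            "small_world_sigma": self.small_world_sigma,
        }


@dataclass
class ModuleGraph:
    """Simple undirected graph over module labels with CS edge weights."""

    graph: nx.Graph

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_list(self) -> pd.DataFrame:
        rows = [
            {"module_1": u, "module_2": v, "cs": d.get("weight", np.nan)}
            for u, v, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["module_1", "module_2", "cs"])


def connectivity_score(
    eigengenes: pd.DataFrame,
    q1: str,
    q2: str,
    method: str = "eigengene",
    network: CoexpressionNetwork | None = None,
    partition: ModulePartition | None = None,
) -> float:
    """Connectivity score between two modules, in [0, 1] and symmetric.

    ``method="eigengene"``: absolute Pearson correlation of the module
    eigengenes.  ``method="adjacency"``: mean adjacency between the two
    modules' gene sets (requires ``network`` and ``partition``).
    """
    if q1 == q2:
        raise ValueError(f"connectivity score of a module with itself ({q1}) is not defined")
    if method == "eigengene":
        for q in (q1, q2):
            if q not in eigengenes.columns:
                raise KeyError(f"module {q} has no eigengene")
        r = np.corrcoef(eigengenes[q1], eigengenes[q2])[0, 1]
        return float(abs(r))
    if method == "adjacency":
        if network is None or partition is None:
            raise ValueError("adjacency method requires a network and a partition")
        i1 = network.gene_index(partition.genes_in(q1))
        i2 = network.gene_index(partition.genes_in(q2))
        return float(network.adjacency[np.ix_(i1, i2)].mean())
    raise ValueError(f"unknown connectivity-score method: {method!r}")


def connectivity_matrix(
    eigengenes: pd.DataFrame,
    modules: Sequence[str] | None = None,
    method: str = "eigengene",
    network: CoexpressionNetwork | None = None,
    partition: ModulePartition | None = None,
) -> pd.DataFrame:
    """Symmetric CS matrix (NaN diagonal) over the given modules."""
    if modules is None:
        modules = list(eigengenes.columns)
    cs = pd.DataFrame(np.nan, index=modules, columns=modules, dtype=float)
    for q1, q2 in combinations(modules, 2):
        v = connectivity_score(eigengenes, q1, q2, method=method, network=network, partition=partition)
        cs.loc[q1, q2] = cs.loc[q2, q1] = v
    return cs


def build_module_graph(
    dems: Sequence[str],
    cs: pd.DataFrame,
    edge_threshold: float = 0.3,
    sizes: Mapping[str, int] | None = None,
) -> ModuleGraph:
    """Threshold the CS matrix into a simple undirected module graph.

    An edge (q1, q2) is present iff ``cs >= edge_threshold``; node
    attribute ``size`` records the module gene count when provided.
    """
    if len(dems) == 0:
        raise ValueError("DEM list is empty")
    if not 0.0 <= edge_threshold:
        raise ValueError(f"edge_threshold must be non-negative, got {edge_threshold}")
    g = nx.Graph()
    for q in dems:
        g.add_node(q, size=int(sizes[q]) if sizes is not None else None)
    for q1, q2 in combinations(dems, 2):
        w = cs.loc[q1, q2]
        if np.isfinite(w) and w >= edge_threshold:
            g.add_edge(q1, q2, weight=float(w))
    return ModuleGraph(g)


def _mean_shortest_path(g: nx.Graph) -> tuple[float, int]:
    """Mean shortest-path length over reachable unordered pairs.

    Returns ``(cpl, n_unreachable_pairs)``; NaN when no pair is reachable.
    """
    n = g.number_of_nodes()
    total_pairs = n * (n - 1) // 2
    total = 0.0
    reached = 0
    for source, lengths in nx.all_pairs_shortest_path_length(g):
        for target, d in lengths.items():
            if target != source:
                total += d
                reached += 1
    reached //= 2  # each unordered pair counted twice
    total /= 2.0
    unreachable = total_pairs - reached
    if reached == 0:
        return float("nan"), unreachable
    return total / reached, unreachable


def topology_features(
    g: nx.Graph | ModuleGraph,
    small_world: bool = False,
    n_random: int = 20,
    seed: int = 0,
) -> TopologyFeatures:
    """Topology feature vector of a simple undirected graph.

    Density is ``m / (n (n-1) / 2)``; the characteristic path length (CPL)
    averages shortest-path lengths over reachable unordered pairs
    (unreachable pairs are excluded with a logged count); the clustering
    coefficient averages local clustering with degree-<2 nodes contributing
    zero.  With ``small_world=True``, sigma is computed against
    ``n_random`` seeded Erdos-Renyi G(n, m) graphs.
    """
    if isinstance(g, ModuleGraph):
        g = g.graph
    n = g.number_of_nodes()
    if n < 2:
        raise ValueError(f"topology features need >= 2 nodes, got {n}")
    m = g.number_of_edges()
    density = m / (n * (n - 1) / 2)
    cpl, unreachable = _mean_shortest_path(g)
    if unreachable:
        logger.warning("%d unreachable pair(s) excluded from CPL", unreachable)
    clustering = float(np.mean(list(nx.clustering(g).values()))) if n else float("nan")

    sigma = None
    if small_world:
        c_rand, l_rand = [], []
        for i in range(n_random):
            r = nx.gnm_random_graph(n, m, seed=seed + i)
            c_rand.append(np.mean(list(nx.clustering(r).values())))
            l_r, _ = _mean_shortest_path(r)
            l_rand.append(l_r)
        c_bar = float(np.nanmean(c_rand))
        l_bar = float(np.nanmean(l_rand))
        if c_bar > 0 and l_bar > 0 and np.isfinite(cpl):
            sigma = float((clustering / c_bar) / (cpl / l_bar))
        else:
            logger.warning("small-world sigma undefined for this graph (degenerate baseline)")
            sigma = float("nan")
    return TopologyFeatures(
        n_nodes=n,
        n_edges=m,
        density=float(density),
        characteristic_path_length=float(cpl),
        clustering_coefficient=clustering,
        small_world_sigma=sigma,
    )


def graph_topology(mg: ModuleGraph, **kwargs) -> TopologyFeatures:
    return topology_features(mg.graph, **kwargs)
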