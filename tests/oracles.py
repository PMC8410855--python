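"""Independent brute-force oracles used by the tests.

These deliberately avoid the library's own code paths (and networkx's
aggregate metrics): graph quantities are recomputed from the edge set by
explicit enumeration and hand-rolled BFS.
"""

from __future__ import annotations

from itertools import combinations


def bf_density(nodes: list, edges: set[frozenset]) -> float:
    n = len(nodes)
    possible = n * (n - 1) // 2
    return len(edges) / possible if possible else float("nan")


def _bfs_distances(start, adj: dict) -> dict:
    dist = {start: 0}
    frontier = [start]
    while frontier:
        nxt = []
        for u in frontier:
            for v in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    nxt.append(v)
        frontier = nxt
    return dist


def bf_cpl(nodes: list, edges: set[frozenset]) -> float:
    """Mean shortest-path length over reachable unordered pairs (NaN if none)."""
    adj = {u: set() for u in nodes}
    for e in edges:
        u, v = tuple(e)
        adj[u].add(v)
        adj[v].add(u)
    total, count = 0.0, 0
    for u, v in combinations(nodes, 2):
        dist = _bfs_distances(u, adj)
        if v in dist:
            total += dist[v]
            count += 1
    return total / count if count else float("nan")


def bf_clustering(nodes: list, edges: set[frozenset]) -> float:
    """Mean local clustering; nodes of degree < 2 contribute zero."""
    adj = {u: set() for u in nodes}
    for e in edges:
        u, v = tuple(e)
        adj[u].add(v)
        adj[v].add(u)
    if not nodes:
        return float("nan")
    total = 0.0
    for u in nodes:
        neigh = list(adj[u])
        d = len(neigh)
        if d < 2:
            continue
        links = sum(1 for a, b in combinations(neigh, 2) if frozenset((a, b)) in edges)
        total += 2.0 * links / (d * (d - 1))
    return total / len(nodes)


def graph_to_sets(g) -> tuple[list, set[frozenset]]:
    """networkx graph -> (node list, frozenset edge set)."""
    return list(g.nodes), {frozenset((u, v)) for u, v in g.edges}
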