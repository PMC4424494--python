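"""Independent brute-force oracles used by the tests.

Everything here enumerates paths exhaustively over explicit edge lists —
no calls into the package's own path machinery or into graph-library
shortest-path code — so oracle and implementation can disagree.
"""

from __future__ import annotations

import random
from itertools import count


def random_edge_list(
    rng: random.Random, n_nodes: int, edge_prob: float = 0.3
) -> list[tuple[str, str]]:
    """A random directed graph as an explicit edge list (no self-loops)."""
    names = [f"N{i:02d}" for i in range(n_nodes)]
    return [
        (u, v)
        for u in names
        for v in names
        if u != v and rng.random() < edge_prob
    ]


def adjacency(edges: list[tuple[str, str]]) -> dict[str, list[str]]:
    adj: dict[str, list[str]] = {}
    for u, v in edges:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, [])
    return adj


def enumerate_simple_paths(
    edges: list[tuple[str, str]], source: str, target: str
) -> list[tuple[str, ...]]:
    """All simple directed paths from source to target, by DFS."""
    adj = adjacency(edges)
    if source not in adj or target not in adj:
        return []
    out: list[tuple[str, ...]] = []

    def dfs(node: str, path: list[str]) -> None:
        if node == target:
            out.append(tuple(path))
            return
        for nxt in adj[node]:
            if nxt not in path:
                path.append(nxt)
                dfs(nxt, path)
                path.pop()

    dfs(source, [source])
    return out


def brute_shortest_paths(
    edges: list[tuple[str, str]], source: str, target: str
) -> list[tuple[str, ...]]:
    """All tied minimum-length simple paths, lexicographically sorted."""
    if source == target:
        return [(source,)]
    simple = enumerate_simple_paths(edges, source, target)
    if not simple:
        return []
    best = min(len(p) for p in simple)
    return sorted(p for p in simple if len(p) == best)


def brute_distance(
    edges: list[tuple[str, str]], source: str, target: str
) -> int | None:
    tied = brute_shortest_paths(edges, source, target)
    return len(tied[0]) - 1 if tied else None


def brute_betweenness(
    edges: list[tuple[str, str]],
) -> tuple[dict[str, float], dict[tuple[str, str], float]]:
    """Unnormalised node and edge betweenness by exhaustive enumeration.

    Each ordered pair (s, t) with s != t contributes, to every
    intermediate node (and to every edge) lying on its shortest paths, the
    fraction of tied shortest paths passing through it.
    """
    adj = adjacency(edges)
    nodes = sorted(adj)
    node_btw = {v: 0.0 for v in nodes}
    edge_btw = {e: 0.0 for e in edges}
    for s in nodes:
        for t in nodes:
            if s == t:
                continue
            tied = brute_shortest_paths(edges, s, t)
            if not tied:
                continue
            sigma = len(tied)
            for path in tied:
                for v in path[1:-1]:
                    node_btw[v] += 1.0 / sigma
                for e in zip(path, path[1:]):
                    edge_btw[e] += 1.0 / sigma
    return node_btw, edge_btw


def is_cut_node_for_pair(
    edges: list[tuple[str, str]], node: str, source: str, target: str
) -> bool:
    """True iff ``node`` lies on every simple source->target path (and at
    least one exists) — removal then abrogates the pair."""
    simple = enumerate_simple_paths(edges, source, target)
    return bool(simple) and all(node in p for p in simple)
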