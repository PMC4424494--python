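"""Shortest-path machinery over the signalling network.

All path computations use unit edge weights (breadth-first distances); the
sign of an interaction is metadata and never blocks traversal.  Where
several shortest routes tie, the canonical one is the lexicographically
smallest node sequence, so every reported path is reproducible.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx

from .network import SignallingNetwork

__all__ = [
    "PathResult",
    "PathSet",
    "all_pairs_connectivity",
    "all_shortest_paths",
    "extract_s2t_subnetwork",
    "parse_arrow_path",
    "shortest_path",
    "source_target_paths",
]

_ARROW_SPLIT = re.compile(r"\s*-\s*>\s*|\s*->\s*")


@dataclass(frozen=True)
class PathResult:
    """An ordered node sequence realising a directed route.

    ``edge_types[i]`` holds the interaction type(s) of the edge from
    ``nodes[i]`` to ``nodes[i+1]`` (multiple types joined with ``|``).
    """

    nodes: tuple[str, ...]
    edge_types: tuple[str, ...] = ()

    @property
    def source(self) -> str:
        return self.nodes[0]

    @property
    def target(self) -> str:
        return self.nodes[-1]

    @property
    def length(self) -> int:
        return len(self.nodes) - 1

    def to_arrow(self) -> str:
        """Serialise in the curated-table arrow dialect ``A- > B- > C``."""
        return "- > ".join(self.nodes)

    def to_json_dict(self) -> dict:
        return {
            "source": self.source,
            "target": self.target,
            "length": self.length,
            "nodes": list(self.nodes),
            "edge_types": list(self.edge_types),
        }


def parse_arrow_path(text: str) -> tuple[str, ...]:
    """Split an arrow-dialect path string (``A- > B`` or ``A->B``) into ids."""
    parts = tuple(p.strip() for p in _ARROW_SPLIT.split(text.strip()) if p.strip())
    if len(parts) < 1:
        raise ValueError(f"not a path string: {text!r}")
    return parts


def _path_result(network: SignallingNetwork, nodes: Sequence[str]) -> PathResult:
    types = tuple(
        "|".join(network.edge_types(u, v)) for u, v in zip(nodes, nodes[1:])
    )
    return PathResult(nodes=tuple(nodes), edge_types=types)


def _check_nodes(network: SignallingNetwork, *ids: str) -> None:
    unknown = [i for i in ids if i not in network]
    if unknown:
        raise KeyError(f"unknown node id(s): {', '.join(unknown)}")


def shortest_path(
    network: SignallingNetwork, source: str, target: str
) -> PathResult | None:
    """Canonical shortest directed path, or ``None`` if target unreachable.

    Among tied minimal-length routes the lexicographically smallest node
    sequence wins; ``source == target`` yields the zero-length path.
    Self-loops never participate (the zero-length path always beats them).
    """
    _check_nodes(network, source, target)
    if source == target:
        return PathResult(nodes=(source,))
    g = network.graph
    dist_to_target = nx.single_source_shortest_path_length(
        g.reverse(copy=False), target
    )
    if source not in dist_to_target:
        return None
    # greedy walk: always step to the smallest successor that stays on a
    # shortest route; yields the lexicographically smallest tied sequence
    nodes = [source]
    current = source
    while current != target:
        d = dist_to_target[current]
        current = min(
            u for u in g.successors(current) if dist_to_target.get(u, -1) == d - 1
        )
        nodes.append(current)
    return _path_result(network, nodes)


def all_shortest_paths(
    network: SignallingNetwork, source: str, target: str
) -> list[PathResult]:
    """All tied shortest paths, lexicographically ordered; [] if unreachable."""
    _check_nodes(network, source, target)
    if source == target:
        return [PathResult(nodes=(source,))]
    try:
        tied = sorted(tuple(p) for p in nx.all_shortest_paths(network.graph, source, target))
    except nx.NetworkXNoPath:
        return []
    return [_path_result(network, p) for p in tied]


def all_pairs_connectivity(
    network: SignallingNetwork,
) -> tuple[dict[tuple[str, str], int], int]:
    """Directed distances for all ordered pairs (u, v), u != v, plus the
    count of pairs at finite distance (the all-vs-all path count)."""
    distances: dict[tuple[str, str], int] = {}
    for u, dists in nx.all_pairs_shortest_path_length(network.graph):
        for v, d in dists.items():
            if u != v:
                distances[(u, v)] = d
    return distances, len(distances)


@dataclass
class PathSet:
    """Shortest routes from a source set to a target set.

    ``connected_pairs`` counts ordered (s, t) pairs at finite distance
    (s != t); ``frequency`` counts, per node, the stored shortest paths it
    appears in.
    """

    sources: tuple[str, ...]
    targets: tuple[str, ...]
    paths: list[PathResult]
    connected_pairs: int
    frequency: dict[str, int] = field(default_factory=dict)

    @property
    def path_count(self) -> int:
        return len(self.paths)

    def to_tsv(self) -> str:
        lines = ["source\ttarget\tlength\tpath"]
        for p in self.paths:
            lines.append(f"{p.source}\t{p.target}\t{p.length}\t{p.to_arrow()}")
        return "\n".join(lines) + "\n"


def source_target_paths(
    network: SignallingNetwork,
    sources: Iterable[str],
    targets: Iterable[str],
    mode: str = "canonical_per_pair",
) -> PathSet:
    """Enumerate shortest routes for every ordered (source, target) pair.

    ``canonical_per_pair`` keeps one lexicographic path per connected pair;
    ``all_tied`` keeps every tied shortest path.  Pairs with s == t are
    skipped (no self-loop traversal).
    """
    if mode not in ("canonical_per_pair", "all_tied"):
        raise ValueError(f"unknown mode: {mode!r}")
    src = tuple(sources)
    tgt = tuple(targets)
    _check_nodes(network, *src, *tgt)
    paths: list[PathResult] = []
    connected = 0
    for s in src:
        for t in tgt:
            if s == t:
                continue
            if mode == "canonical_per_pair":
                p = shortest_path(network, s, t)
                if p is not None:
                    connected += 1
                    paths.append(p)
            else:
                tied = all_shortest_paths(network, s, t)
                if tied:
                    connected += 1
                    paths.extend(tied)
    frequency: dict[str, int] = {}
    for p in paths:
        for n in p.nodes:
            frequency[n] = frequency.get(n, 0) + 1
    return PathSet(
        sources=src,
        targets=tgt,
        paths=paths,
        connected_pairs=connected,
        frequency=frequency,
    )


def extract_s2t_subnetwork(
    network: SignallingNetwork, paths: PathSet
) -> SignallingNetwork:
    """Union of all nodes and edges lying on the computed paths, with the
    query's designations carried over.

    Raises a consistency error if a path references an edge the network
    does not contain (i.e. the paths were computed elsewhere).
    """
    sub = SignallingNetwork(
        sources=[s for s in paths.sources if any(p.source == s for p in paths.paths)],
        targets=[t for t in paths.targets if any(p.target == t for p in paths.paths)],
    )
    for p in paths.paths:
        for n in p.nodes:
            sub.add_node(network.descriptor(n))
        for u, v in zip(p.nodes, p.nodes[1:]):
            if not network.graph.has_edge(u, v):
                raise ValueError(
                    f"path edge {u} -> {v} is not part of the network"
                )
            for t in network.edge_types(u, v):
                sub.add_edge(u, v, t)
    return sub
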