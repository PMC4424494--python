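"""The directed typed signalling graph and its topology metrics.

A :class:`SignallingNetwork` wraps a :class:`networkx.DiGraph` whose nodes
carry :class:`~pigmentnet.interactions.NodeDescriptor` attributes and whose
edges carry an ordered tuple of interaction types.  Duplicate curated rows
for the same ordered (source, target) pair merge into one edge whose type
set is the union, so the node and edge counts are |nodes| and |unique
ordered pairs|.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import networkx as nx

from .interactions import InteractionRecord, NodeDescriptor, classify_node

__all__ = [
    "SignallingNetwork",
    "TopologyReport",
    "build_network",
    "centrality",
    "degree_profile",
    "identify_hubs",
]


class SignallingNetwork:
    """Directed typed graph over node descriptors, with optional
    source/target designations (the chosen triggers/receptors and
    phenotypic end processes)."""

    def __init__(
        self,
        graph: nx.DiGraph | None = None,
        sources: Sequence[str] = (),
        targets: Sequence[str] = (),
    ) -> None:
        self.graph: nx.DiGraph = graph if graph is not None else nx.DiGraph()
        self.sources: tuple[str, ...] = tuple(sources)
        self.targets: tuple[str, ...] = tuple(targets)

    # -- container protocol -------------------------------------------------
    @property
    def node_count(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def edge_count(self) -> int:
        return self.graph.number_of_edges()

    def __contains__(self, node_id: str) -> bool:
        return node_id in self.graph

    def nodes(self) -> Iterator[str]:
        return iter(self.graph.nodes)

    def descriptor(self, node_id: str) -> NodeDescriptor:
        try:
            return self.graph.nodes[node_id]["descriptor"]
        except KeyError:
            raise KeyError(f"unknown node: {node_id!r}") from None

    def edges(self) -> Iterator[tuple[str, str, tuple[str, ...]]]:
        """Edges in insertion order (stable across write/parse round trips)."""
        ordered = sorted(
            self.graph.edges(data=True), key=lambda e: e[2].get("order", 0)
        )
        for u, v, data in ordered:
            yield u, v, data["types"]

    def edge_types(self, u: str, v: str) -> tuple[str, ...]:
        return self.graph.edges[u, v]["types"]

    def successors(self, node_id: str) -> Iterator[str]:
        return self.graph.successors(node_id)

    def copy(self) -> "SignallingNetwork":
        return SignallingNetwork(self.graph.copy(), self.sources, self.targets)

    def with_designations(
        self, sources: Sequence[str], targets: Sequence[str]
    ) -> "SignallingNetwork":
        unknown = [n for n in (*sources, *targets) if n not in self.graph]
        if unknown:
            raise KeyError(f"unknown designation id(s): {', '.join(unknown)}")
        return SignallingNetwork(self.graph, sources, targets)

    def is_weakly_connected(self) -> bool:
        return self.node_count > 0 and nx.is_weakly_connected(self.graph)

    def add_node(self, descriptor: NodeDescriptor) -> None:
        if descriptor.id not in self.graph:
            self.graph.add_node(descriptor.id, descriptor=descriptor)

    def add_edge(self, u: str, v: str, itype: str) -> None:
        """Insert an edge, merging the type into an existing edge's set."""
        for n in (u, v):
            if n not in self.graph:
                self.add_node(classify_node(n))
        if self.graph.has_edge(u, v):
            types = self.graph.edges[u, v]["types"]
            if itype not in types:
                self.graph.edges[u, v]["types"] = types + (itype,)
        else:
            seq = self.graph.graph.get("edge_seq", 0)
            self.graph.graph["edge_seq"] = seq + 1
            self.graph.add_edge(u, v, types=(itype,), order=seq)

    def equal_structure(self, other: "SignallingNetwork") -> bool:
        """Equality on node ids, compartments, edge set and edge type sets."""
        if set(self.graph.nodes) != set(other.graph.nodes):
            return False
        for n in self.graph.nodes:
            if self.descriptor(n).compartment != other.descriptor(n).compartment:
                return False
        if set(self.graph.edges) != set(other.graph.edges):
            return False
        return all(
            set(self.edge_types(u, v)) == set(other.edge_types(u, v))
            for u, v in self.graph.edges
        )


def build_network(
    records: Iterable[InteractionRecord],
    descriptors: Iterable[NodeDescriptor] = (),
) -> SignallingNetwork:
    """Assemble a :class:`SignallingNetwork` from parsed records.

    Duplicate (source, target) rows merge their types; self-loops are kept
    (they never shorten a path) and isolated nodes listed only in
    ``descriptors`` are retained.
    """
    net = SignallingNetwork()
    for desc in descriptors:
        net.add_node(desc)
    for rec in records:
        net.add_edge(rec.node_a, rec.node_b, rec.interaction_type)
    return net


def degree_profile(network: SignallingNetwork) -> dict[str, tuple[int, int]]:
    """Per-node (in_degree, out_degree) over unique ordered pairs."""
    g = network.graph
    return {n: (g.in_degree(n), g.out_degree(n)) for n in g.nodes}


@dataclass
class TopologyReport:
    """Topology metrics of one network: per-node degrees, betweenness,
    closeness, radiality and reach; per-edge betweenness; and network-level
    counts, finite diameter and the hub list."""

    node_count: int
    edge_count: int
    diameter: int
    per_node: dict[str, dict[str, float]]
    per_edge: dict[tuple[str, str], float]
    hubs: list[str] = field(default_factory=list)

    def node_rows(self) -> list[tuple]:
        cols = (
            "in_degree",
            "out_degree",
            "betweenness",
            "closeness",
            "radiality",
            "reachable_count",
        )
        return [(n, *[self.per_node[n][c] for c in cols]) for n in self.per_node]


def _finite_diameter(lengths: Mapping[str, Mapping[str, int]]) -> int:
    longest = 0
    for dists in lengths.values():
        for d in dists.values():
            if d > longest:
                longest = d
    return longest


def centrality(
    network: SignallingNetwork,
    hub_rule: Mapping[str, float] | None = None,
) -> TopologyReport:
    """Compute the directed topology metrics.

    Betweenness (node and edge) is unnormalised Brandes betweenness with
    tied shortest paths splitting pair contributions equally.  Closeness of
    ``v`` is the reachable-set variant ``(r/(n-1)) * (r/sum of distances)``
    with ``r`` the number of nodes reachable from ``v``; radiality of ``v``
    is ``sum over reachable w of (diameter + 1 - d(v, w)) / (n - 1)``.
    Nodes that reach nothing score 0 on both.
    """
    g = network.graph
    n = g.number_of_nodes()
    lengths = {v: dict(nx.single_source_shortest_path_length(g, v)) for v in g.nodes}
    for v in g.nodes:
        lengths[v].pop(v, None)  # self-distance excluded from reach
    diam = _finite_diameter(lengths)

    btw = nx.betweenness_centrality(g, normalized=False) if n else {}
    ebtw = nx.edge_betweenness_centrality(g, normalized=False) if n else {}

    per_node: dict[str, dict[str, float]] = {}
    for v in g.nodes:
        reach = lengths[v]
        r = len(reach)
        total = sum(reach.values())
        closeness = (r / (n - 1)) * (r / total) if r and n > 1 else 0.0
        radiality = (
            sum(diam + 1 - d for d in reach.values()) / (n - 1) if r and n > 1 else 0.0
        )
        per_node[v] = {
            "in_degree": g.in_degree(v),
            "out_degree": g.out_degree(v),
            "betweenness": btw.get(v, 0.0),
            "closeness": closeness,
            "radiality": radiality,
            "reachable_count": r,
        }

    report = TopologyReport(
        node_count=n,
        edge_count=g.number_of_edges(),
        diameter=diam,
        per_node=per_node,
        per_edge={(u, v): w for (u, v), w in ebtw.items()},
    )
    report.hubs = identify_hubs(network, hub_rule or {"top_fraction": 0.1})
    return report


def identify_hubs(
    network: SignallingNetwork, rule: Mapping[str, float]
) -> list[str]:
    """Rank nodes by total degree and apply a hub rule.

    ``rule`` is ``{"top_fraction": f}`` (0 < f <= 1, keep the top ceil(f*n)
    nodes) or ``{"min_total_degree": k}`` (k >= 1).  Ties break
    lexicographically by id.
    """
    g = network.graph
    ranked = sorted(g.nodes, key=lambda v: (-(g.in_degree(v) + g.out_degree(v)), v))
    if "top_fraction" in rule:
        f = rule["top_fraction"]
        if not 0 < f <= 1:
            raise ValueError(f"top_fraction must be in (0, 1], got {f}")
        import math

        return ranked[: math.ceil(f * len(ranked))]
    if "min_total_degree" in rule:
        k = rule["min_total_degree"]
        if k < 1:
            raise ValueError(f"min_total_degree must be >= 1, got {k}")
        return [v for v in ranked if g.in_degree(v) + g.out_degree(v) >= k]
    raise ValueError("hub rule must contain 'top_fraction' or 'min_total_degree'")
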