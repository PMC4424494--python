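"""Writers for interaction tables and Cytoscape-readable graph formats."""

from __future__ import annotations

import io as _io
import json
from typing import IO

import networkx as nx

from .interactions import ParserOptions, parse_interaction_table
from .network import SignallingNetwork, TopologyReport, build_network

__all__ = [
    "read_network",
    "write_network",
    "write_topology_report_json",
    "write_topology_report_tsv",
]

EDGE_TABLE_HEADER = "Node A\tNode B\tInteraction type A->B"


def read_network(
    source: IO[str] | str, options: ParserOptions | None = None
) -> tuple[SignallingNetwork, list[str]]:
    """Parse an interaction table and build the network in one step."""
    records, descriptors, warnings = parse_interaction_table(source, options)
    return build_network(records, descriptors), warnings


def write_network(network: SignallingNetwork, format: str, sink: IO[str]) -> None:
    """Serialise a network as ``edge-table`` (round-trip TSV), ``SIF`` or
    ``GraphML``.

    The edge-table dialect is tab-delimited, LF-terminated, UTF-8, one row
    per (source, target, type); parsing it back reconstructs an identical
    network.  SIF uses the interaction type (spaces -> underscores) as the
    relation token.  GraphML stores compartment and category as node
    attributes for Cytoscape.
    """
    if format == "edge-table":
        sink.write(EDGE_TABLE_HEADER + "\n")
        for u, v, types in network.edges():
            for t in types:
                sink.write(f"{u}\t{v}\t{t}\n")
        return
    if network.node_count == 0:
        raise ValueError(f"cannot write an empty network as {format}")
    if format == "SIF":
        for u, v, types in network.edges():
            for t in types:
                sink.write(f"{u} {t.replace(' ', '_')} {v}\n")
        for n in network.nodes():
            if network.graph.degree(n) == 0:
                sink.write(f"{n}\n")
        return
    if format == "GraphML":
        g = nx.DiGraph()
        for n in network.nodes():
            d = network.descriptor(n)
            g.add_node(n, compartment=d.compartment, category=d.category)
        for u, v, types in network.edges():
            g.add_edge(u, v, interaction="|".join(types))
        buf = _io.BytesIO()
        nx.write_graphml(g, buf)
        sink.write(buf.getvalue().decode("utf-8"))
        return
    raise ValueError(f"unknown format: {format!r}")


def network_to_edge_table(network: SignallingNetwork) -> str:
    buf = _io.StringIO()
    write_network(network, "edge-table", buf)
    return buf.getvalue()


_NODE_COLUMNS = (
    "node",
    "in_degree",
    "out_degree",
    "betweenness",
    "closeness",
    "radiality",
    "reachable_count",
)


def write_topology_report_tsv(report: TopologyReport, sink: IO[str]) -> None:
    """One node per row, matching the degree/centrality/radiality columns."""
    sink.write("\t".join(_NODE_COLUMNS) + "\n")
    for row in report.node_rows():
        sink.write("\t".join(_fmt(x) for x in row) + "\n")


def _fmt(x) -> str:
    if isinstance(x, float):
        return format(x, ".6g")
    return str(x)


def write_topology_report_json(report: TopologyReport, sink: IO[str]) -> None:
    payload = {
        "node_count": report.node_count,
        "edge_count": report.edge_count,
        "diameter": report.diameter,
        "hubs": report.hubs,
        "nodes": report.per_node,
        "edge_betweenness": {f"{u}->{v}": w for (u, v), w in report.per_edge.items()},
    }
    json.dump(payload, sink, indent=1, sort_keys=True)
    sink.write("\n")
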