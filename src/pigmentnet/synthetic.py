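"""Seeded two-compartment synthetic networks and the packaged fixtures.

The generator emulates the structure the analysis assumes: a layered
feed-forward cascade split between a keratinocyte and a melanocyte
compartment, with zero-in-degree trigger/receptor sources in the first
layer, zero-out-degree biological-process sinks in the last, occasional
cross-compartment (paracrine) edges, and a tunable amount of parallel-route
redundancy.  The packaged fixtures are the sample interaction table, the
printed source-to-target path strings, and the designated source/target
sets of the curated pigmentation model.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from importlib import resources
from typing import NamedTuple

from .interactions import NodeDescriptor, ParserOptions, parse_interaction_table
from .network import SignallingNetwork, build_network
from .paths import parse_arrow_path

__all__ = [
    "PrintedPath",
    "SyntheticSpec",
    "generate_network",
    "printed_paths",
    "printed_paths_fixture",
    "table1_fixture",
    "table2_designations",
]


# ---------------------------------------------------------------------------
# generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a generated two-compartment layered cascade.

    Defaults mirror the curated pigmentation model's scale: 142
    keratinocyte and 113 melanocyte nodes, 20 sources and 9 targets.
    ``cross_talk_prob`` is the probability that a cascade edge crosses
    compartments (paracrine signalling); ``redundancy`` is the mean number
    of parallel in-branches per non-source node (1 = a tree-like cascade);
    ``inhibition_frac`` is the fraction of edges typed ``inhibits``;
    ``feedback_prob`` (default 0, giving a DAG) adds backward edges.
    """

    n_keratinocyte: int = 142
    n_melanocyte: int = 113
    n_sources: int = 20
    n_targets: int = 9
    n_layers: int = 8
    cross_talk_prob: float = 0.15
    redundancy: float = 1.5
    inhibition_frac: float = 0.2
    feedback_prob: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_sources < 1 or self.n_targets < 1:
            raise ValueError("need at least one source and one target")
        if self.n_layers < 2:
            raise ValueError("need at least 2 layers")
        if self.redundancy < 1:
            raise ValueError("redundancy must be >= 1")
        if not 0 <= self.cross_talk_prob <= 1:
            raise ValueError("cross_talk_prob must be in [0, 1]")
        if not 0 <= self.inhibition_frac <= 1:
            raise ValueError("inhibition_frac must be in [0, 1]")
        total = self.n_keratinocyte + self.n_melanocyte
        middle = total - self.n_sources - self.n_targets
        if middle < 0:
            raise ValueError("fewer nodes than sources + targets")
        if self.n_layers > 2 and middle < self.n_layers - 2:
            raise ValueError("not enough intermediate nodes for the layer count")


def _suffix(compartment: str) -> str:
    return "kerat" if compartment == "keratinocyte" else "melan"


def generate_network(spec: SyntheticSpec) -> SignallingNetwork:
    """Generate a seeded layered signalling network with designations.

    Layer 0 holds the designated sources, the final layer the designated
    biological-process targets; every node outside layer 0 receives at
    least one parent in the previous layer (so every target is reachable
    from a source) and every non-sink node at least one child.  Identical
    spec + seed yields a byte-identical edge table.
    """
    spec.validate()
    rng = random.Random(spec.seed)

    compartments = ["keratinocyte"] * spec.n_keratinocyte + [
        "melanocyte"
    ] * spec.n_melanocyte
    rng.shuffle(compartments)

    total = len(compartments)
    middle_total = total - spec.n_sources - spec.n_targets
    n_middle_layers = max(spec.n_layers - 2, 0)
    layer_sizes = [spec.n_sources]
    if n_middle_layers:
        base, extra = divmod(middle_total, n_middle_layers)
        layer_sizes += [base + (1 if i < extra else 0) for i in range(n_middle_layers)]
    layer_sizes.append(spec.n_targets)

    net = SignallingNetwork()
    layers: list[list[str]] = []
    idx = 0
    for li, size in enumerate(layer_sizes):
        layer: list[str] = []
        for j in range(size):
            comp = compartments[idx]
            idx += 1
            if li == 0:
                name = f"SRC{j + 1:02d}_{_suffix(comp)}"
                category = "protein"
            elif li == len(layer_sizes) - 1:
                name = f"PRC{j + 1:02d}_formation_{_suffix(comp)}"
                category = "biological_process"
            else:
                name = f"ND{idx:03d}_{_suffix(comp)}"
                category = "protein"
            base = name[: -(len(_suffix(comp)) + 1)]
            net.add_node(
                NodeDescriptor(
                    id=name, base_name=base, compartment=comp, category=category
                )
            )
            layer.append(name)
        layers.append(layer)

    def _edge_type() -> str:
        return "inhibits" if rng.random() < spec.inhibition_frac else "activates"

    def _pick_parent(child: str, pool: list[str]) -> str:
        child_comp = net.descriptor(child).compartment
        cross = rng.random() < spec.cross_talk_prob
        wanted = [
            p
            for p in pool
            if (net.descriptor(p).compartment != child_comp) == cross
        ]
        return rng.choice(wanted or pool)

    # mandatory in-edge per non-source node: guarantees reachability
    for li in range(1, len(layers)):
        prev = layers[li - 1]
        for v in layers[li]:
            net.add_edge(_pick_parent(v, prev), v, _edge_type())
        # redundancy: extra parallel parents, expected (redundancy - 1) each
        p_extra = min(1.0, (spec.redundancy - 1.0) / max(1, len(prev)))
        if p_extra > 0:
            for v in layers[li]:
                for u in prev:
                    if not net.graph.has_edge(u, v) and rng.random() < p_extra:
                        net.add_edge(u, v, _edge_type())

    # every non-sink node must feed the cascade
    for li in range(len(layers) - 1):
        nxt = layers[li + 1]
        for u in layers[li]:
            if net.graph.out_degree(u) == 0:
                net.add_edge(u, _pick_parent(u, nxt), _edge_type())

    if spec.feedback_prob > 0:
        for li in range(1, len(layers)):
            for u in layers[li]:
                if u in set(layers[-1]):
                    continue  # sinks keep out-degree 0
                for lj in range(1, li + 1):
                    for v in layers[lj]:
                        if v != u and rng.random() < spec.feedback_prob:
                            net.add_edge(u, v, _edge_type())

    return net.with_designations(layers[0], layers[-1])


# ---------------------------------------------------------------------------
# packaged fixtures
# ---------------------------------------------------------------------------

def _data_text(name: str) -> str:
    return (resources.files("pigmentnet") / "data" / name).read_text(encoding="utf-8")


def table1_fixture() -> SignallingNetwork:
    """The 20-row sample interaction table as a network (21 nodes, 20 edges)."""
    records, descriptors, _ = parse_interaction_table(
        _data_text("table1.tsv"), ParserOptions(delimiter="\t")
    )
    return build_network(records, descriptors)


class PrintedPath(NamedTuple):
    """One printed source-to-target path string from the curated analysis."""

    table: str
    process: str
    role: str  # predicted | control | alternate
    perturbed: str  # perturbed node id, empty for predicted paths
    nodes: tuple[str, ...]


def printed_paths() -> list[PrintedPath]:
    """All printed predicted/control/alternate path strings, parsed.

    Rows whose printed alternate is ``None`` (abrogated knockouts) are
    returned with an empty node tuple.
    """
    out: list[PrintedPath] = []
    lines = _data_text("printed_paths.tsv").splitlines()
    for line in lines[1:]:
        table, process, role, perturbed, path = line.split("\t")
        nodes = () if path == "None" else parse_arrow_path(path)
        out.append(PrintedPath(table, process, role, perturbed, nodes))
    return out


def printed_paths_fixture() -> SignallingNetwork:
    """Union network of every printed path string, with designations.

    Sources are the path-initial nodes (the UV/UVA/UVB triggers, kept
    distinct exactly as printed), targets the path-terminal nodes.  The
    printed routes state no interaction types, so every edge is typed
    ``unspecified`` (outside the controlled vocabulary by design).
    """
    net = SignallingNetwork()
    sources: list[str] = []
    targets: list[str] = []
    for pp in printed_paths():
        if not pp.nodes:
            continue
        for u, v in zip(pp.nodes, pp.nodes[1:]):
            net.add_edge(u, v, "unspecified")
        if pp.nodes[0] not in sources:
            sources.append(pp.nodes[0])
        if pp.nodes[-1] not in targets:
            targets.append(pp.nodes[-1])
    return net.with_designations(sources, targets)


def table2_designations() -> tuple[tuple[str, ...], tuple[str, ...]]:
    """The designated source and target node id sets of the curated model
    (20 trigger/receptor sources, 9 biological-process targets)."""
    sources = tuple(_data_text("table2_sources.txt").split())
    targets = tuple(_data_text("table2_targets.txt").split())
    return sources, targets
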