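"""Virtual knockouts: perturbation networks, essentiality and rerouting.

A knockout removes one node and all its incident edges, after which every
designated source->target pair is re-examined.  A pair whose baseline
shortest route ran through the removed node either reroutes (an alternate
path exists) or is abrogated (the signal can no longer reach its
destination); a node is *essential* for a pair when its removal abrogates
it, and its essentiality count ranks it as in the curated analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .network import SignallingNetwork
from .paths import PathResult, PathSet, all_shortest_paths, shortest_path

__all__ = [
    "EssentialityTable",
    "KnockoutOutcome",
    "alternate_path_report",
    "classify_pair",
    "essentiality_scan",
    "knockout",
    "shortlist_candidates",
]

STATUSES = ("abrogated", "rerouted", "unchanged", "not_applicable")


def knockout(network: SignallingNetwork, node: str) -> SignallingNetwork:
    """Return a copy of the network lacking ``node`` and its incident edges.

    The input network is never modified."""
    if node not in network:
        raise KeyError(f"unknown node: {node!r}")
    perturbed = network.copy()
    perturbed.graph.remove_node(node)
    perturbed.sources = tuple(s for s in network.sources if s != node)
    perturbed.targets = tuple(t for t in network.targets if t != node)
    return perturbed


@dataclass(frozen=True)
class PairOutcome:
    """Effect of one knockout on one ordered (source, target) pair."""

    source: str
    target: str
    status: str  # abrogated | rerouted | unchanged | not_applicable
    baseline_path: PathResult | None = None
    perturbed_path: PathResult | None = None


@dataclass
class KnockoutOutcome:
    """All per-pair effects of removing one node."""

    removed: str
    pairs: list[PairOutcome] = field(default_factory=list)

    @property
    def abrogated_count(self) -> int:
        return sum(1 for p in self.pairs if p.status == "abrogated")


def _verify_derived(
    baseline: SignallingNetwork, perturbed: SignallingNetwork, removed: str
) -> None:
    if removed in perturbed:
        raise ValueError(f"perturbed network still contains {removed!r}")
    if set(perturbed.graph.nodes) != set(baseline.graph.nodes) - {removed}:
        raise ValueError("perturbed network is not knockout(baseline, removed)")


def classify_pair(
    baseline: SignallingNetwork,
    perturbed: SignallingNetwork,
    source: str,
    target: str,
    removed: str,
) -> PairOutcome:
    """Classify the effect of a knockout on one source->target pair.

    ``not_applicable``: the removed node is the source or target itself, or
    the pair was disconnected at baseline.  ``abrogated``: connected at
    baseline, disconnected after removal.  ``rerouted``: the removed node
    lay on at least one tied baseline shortest route but the pair stays
    connected; the stored baseline path is the lexicographically smallest
    tied route *through* the removed node (the route the knockout
    invalidates) and the perturbed path is the canonical alternate.
    ``unchanged``: the removed node lay on no baseline shortest route, so
    the canonical path survives identically.
    """
    _verify_derived(baseline, perturbed, removed)
    if removed in (source, target):
        return PairOutcome(source, target, "not_applicable")
    tied = all_shortest_paths(baseline, source, target)
    if not tied:
        return PairOutcome(source, target, "not_applicable")
    through = [p for p in tied if removed in p.nodes]
    after = shortest_path(perturbed, source, target)
    if after is None:
        return PairOutcome(source, target, "abrogated", baseline_path=through[0] if through else tied[0])
    if through:
        return PairOutcome(
            source, target, "rerouted", baseline_path=through[0], perturbed_path=after
        )
    return PairOutcome(
        source, target, "unchanged", baseline_path=tied[0], perturbed_path=after
    )


@dataclass
class EssentialityTable:
    """Nodes ranked by the number of source->target pairs whose signalling
    their removal abrogates (descending count, then lexicographic id)."""

    rows: list[tuple[str, int]]

    def count(self, node: str) -> int:
        for n, c in self.rows:
            if n == node:
                return c
        raise KeyError(node)

    def to_tsv(self) -> str:
        lines = ["node\tessential_pair_count"]
        lines += [f"{n}\t{c}" for n, c in self.rows]
        return "\n".join(lines) + "\n"


def essentiality_scan(
    network: SignallingNetwork,
    sources: Iterable[str],
    targets: Iterable[str],
    candidates: Iterable[str],
) -> tuple[EssentialityTable, list[KnockoutOutcome]]:
    """Knock out each candidate in turn and classify every (s, t) pair.

    A candidate's essentiality count is the number of abrogated pairs;
    pairs where the candidate is itself the source or target never count.
    """
    src, tgt = tuple(sources), tuple(targets)
    cand = sorted(set(candidates))
    if not cand:
        raise ValueError("empty candidate set")
    unknown = [c for c in cand if c not in network]
    if unknown:
        raise KeyError(f"unknown candidate id(s): {', '.join(unknown)}")

    outcomes: list[KnockoutOutcome] = []
    for node in cand:
        perturbed = knockout(network, node)
        outcome = KnockoutOutcome(removed=node)
        for s in src:
            for t in tgt:
                if s == t:
                    continue
                outcome.pairs.append(classify_pair(network, perturbed, s, t, node))
        outcomes.append(outcome)

    rows = sorted(
        ((o.removed, o.abrogated_count) for o in outcomes),
        key=lambda r: (-r[1], r[0]),
    )
    return EssentialityTable(rows=rows), outcomes


def shortlist_candidates(
    network: SignallingNetwork,
    paths: PathSet,
    rule: Mapping[str, int],
) -> set[str]:
    """Shortlist knockout candidates by degree and by path frequency.

    ``rule`` has keys ``top_by_degree`` (n) and ``top_by_path_frequency``
    (m); the result is the union of the top-n total-degree nodes and the
    top-m nodes by shortest-path frequency, excluding the designated
    sources and targets.  Ties break lexicographically.
    """
    n = int(rule.get("top_by_degree", 0))
    m = int(rule.get("top_by_path_frequency", 0))
    if n < 0 or m < 0:
        raise ValueError("shortlist sizes must be >= 0")
    excluded = set(paths.sources) | set(paths.targets)
    g = network.graph

    by_degree = sorted(
        (v for v in g.nodes if v not in excluded),
        key=lambda v: (-(g.in_degree(v) + g.out_degree(v)), v),
    )
    by_freq = sorted(
        (v for v, f in paths.frequency.items() if f > 0 and v not in excluded),
        key=lambda v: (-paths.frequency[v], v),
    )
    return set(by_degree[:n]) | set(by_freq[:m])


def alternate_path_report(
    outcomes: Sequence[KnockoutOutcome],
) -> list[tuple[str, str, str, str, str]]:
    """Rows (removed, source, target, baseline path, alternate path) for
    every rerouted or abrogated pair; abrogated pairs print ``None``."""
    rows = []
    for o in outcomes:
        for p in o.pairs:
            if p.status == "rerouted":
                rows.append(
                    (o.removed, p.source, p.target, p.baseline_path.to_arrow(),
                     p.perturbed_path.to_arrow())
                )
            elif p.status == "abrogated":
                base = p.baseline_path.to_arrow() if p.baseline_path else ""
                rows.append((o.removed, p.source, p.target, base, "None"))
    return rows


def alternate_report_tsv(rows: Sequence[tuple[str, str, str, str, str]]) -> str:
    lines = ["removed\tsource\ttarget\tcontrol_path\talternate_path"]
    lines += ["\t".join(r) for r in rows]
    return "\n".join(lines) + "\n"
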