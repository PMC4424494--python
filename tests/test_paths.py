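"""Shortest-path enumeration, source-to-target path sets, sub-networks."""

from __future__ import annotations

import random

import pytest

from conftest import network_from_edges
from oracles import brute_shortest_paths, random_edge_list
from pigmentnet import (
    all_pairs_connectivity,
    all_shortest_paths,
    extract_s2t_subnetwork,
    parse_arrow_path,
    shortest_path,
    source_target_paths,
)


# -- canonical shortest path ------------------------------------------------

def test_canonical_path_takes_the_lexicographic_tie_winner(table1_net):
    p = shortest_path(table1_net, "PGE2_kerat", "Eumelanin_melan")
    assert p.length == 6
    assert p.nodes[1] == "PTGER1_melan"  # beats the PTGER3_melan tie


def test_unreachable_pair_returns_absent(table1_net):
    # the UVA cascade dead-ends at cAMP_melan in the sample table
    assert shortest_path(table1_net, "UVA", "Eumelanin_melan") is None


def test_source_equals_target_is_the_zero_length_path(table1_net):
    p = shortest_path(table1_net, "TYR_melan", "TYR_melan")
    assert p.nodes == ("TYR_melan",) and p.length == 0


def test_self_loops_never_shorten_anything():
    net = network_from_edges([("A", "A"), ("A", "B")])
    assert shortest_path(net, "A", "A").length == 0
    assert shortest_path(net, "A", "B").length == 1


def test_unknown_ids_raise_lookup_errors(table1_net):
    with pytest.raises(KeyError):
        shortest_path(table1_net, "NOPE", "TYR_melan")
    with pytest.raises(KeyError):
        all_shortest_paths(table1_net, "TYR_melan", "NOPE")


def test_edge_types_follow_the_route(table1_net):
    p = shortest_path(table1_net, "PRKCB_melan", "Eumelanin_melan")
    assert p.edge_types == ("activates", "increases level")


# -- tied enumeration -------------------------------------------------------

def test_both_tied_routes_are_enumerated_in_order(table1_net):
    tied = all_shortest_paths(table1_net, "PGE2_kerat", "Eumelanin_melan")
    assert [p.length for p in tied] == [6, 6]
    assert tied[0].nodes[1] == "PTGER1_melan"
    assert tied[1].nodes[1] == "PTGER3_melan"


def test_disconnected_pair_gives_empty_list(table1_net):
    assert all_shortest_paths(table1_net, "UVA", "Eumelanin_melan") == []


def test_single_edge_pair_gives_one_unit_path():
    net = network_from_edges([("A", "B")])
    [p] = all_shortest_paths(net, "A", "B")
    assert p.length == 1


@pytest.mark.parametrize("seed", range(30))
def test_shortest_paths_equal_exhaustive_enumeration(seed):
    rng = random.Random(1000 + seed)
    edges = random_edge_list(rng, rng.randint(4, 12), 0.25) or [("N00", "N01")]
    net = network_from_edges(edges)
    names = sorted(set(n for e in edges for n in e))
    for s in names:
        for t in names:
            if s == t:
                continue
            expected = brute_shortest_paths(edges, s, t)
            got = all_shortest_paths(net, s, t)
            assert [p.nodes for p in got] == expected
            canonical = shortest_path(net, s, t)
            if expected:
                assert canonical.nodes == expected[0]
            else:
                assert canonical is None


# -- all-pairs connectivity -------------------------------------------------

def test_connectivity_counts_on_path_and_cycle():
    path = network_from_edges([("A", "B"), ("B", "C")])
    assert all_pairs_connectivity(path)[1] == 3
    cycle = network_from_edges([("A", "B"), ("B", "C"), ("C", "A")])
    assert all_pairs_connectivity(cycle)[1] == 6


def test_distances_satisfy_the_triangle_inequality(table1_net):
    dist, _ = all_pairs_connectivity(table1_net)
    nodes = list(table1_net.nodes())
    for (s, t), d in dist.items():
        for m in nodes:
            if (s, m) in dist and (m, t) in dist:
                assert d <= dist[(s, m)] + dist[(m, t)]


# -- source -> target sets --------------------------------------------------

def test_canonical_mode_yields_one_path_per_connected_pair(table1_net):
    ps = source_target_paths(
        table1_net, ["PTGER1_melan", "PTGER3_melan"], ["Eumelanin_melan"]
    )
    assert ps.path_count == 2 and ps.connected_pairs == 2
    assert all(p.length == 5 for p in ps.paths)


def test_all_tied_mode_keeps_every_tied_route(table1_net):
    ps = source_target_paths(
        table1_net, ["PGE2_kerat"], ["Eumelanin_melan"], mode="all_tied"
    )
    assert ps.connected_pairs == 1 and ps.path_count == 2


def test_singleton_source_equal_to_target_yields_nothing(table1_net):
    ps = source_target_paths(table1_net, ["TYR_melan"], ["TYR_melan"])
    assert ps.path_count == 0 and ps.connected_pairs == 0


def test_unknown_designations_are_listed(table1_net):
    with pytest.raises(KeyError, match="BAD1"):
        source_target_paths(table1_net, ["BAD1"], ["Eumelanin_melan"])


def test_node_frequencies_sum_to_total_path_node_count(table1_net):
    ps = source_target_paths(
        table1_net, ["PGE2_kerat", "UVA"], ["Eumelanin_melan", "cAMP_melan"],
        mode="all_tied",
    )
    assert sum(ps.frequency.values()) == sum(len(p.nodes) for p in ps.paths)
    for node, f in ps.frequency.items():
        assert f > 0 and any(node in p.nodes for p in ps.paths)


def test_invalid_mode_rejected(table1_net):
    with pytest.raises(ValueError):
        source_target_paths(table1_net, ["UVA"], ["cAMP_melan"], mode="fastest")


# -- sub-network extraction -------------------------------------------------

def test_single_path_subnetwork_counts(table1_net):
    ps = source_target_paths(table1_net, ["PGE2_kerat"], ["Eumelanin_melan"])
    sub = extract_s2t_subnetwork(table1_net, ps)
    assert sub.node_count == 7 and sub.edge_count == 6


def test_shared_suffix_is_counted_once(table1_net):
    ps = source_target_paths(
        table1_net, ["PTGER1_melan", "PTGER3_melan"], ["Eumelanin_melan"]
    )
    sub = extract_s2t_subnetwork(table1_net, ps)
    # two length-5 paths sharing the PLC->...->Eumelanin suffix
    assert sub.node_count == 7 and sub.edge_count == 6


def test_every_path_retraces_in_the_subnetwork_with_identical_length(printed_net):
    ps = source_target_paths(printed_net, printed_net.sources, printed_net.targets)
    sub = extract_s2t_subnetwork(printed_net, ps)
    for p in ps.paths:
        again = shortest_path(sub, p.source, p.target)
        assert again is not None and again.length == p.length


def test_foreign_paths_raise_a_consistency_error(table1_net, printed_net):
    ps = source_target_paths(printed_net, ["UV"], ["Eumelanin_melan"])
    with pytest.raises((ValueError, KeyError)):
        extract_s2t_subnetwork(table1_net, ps)


# -- arrow dialect ----------------------------------------------------------

def test_arrow_serialisation_round_trips(table1_net):
    p = shortest_path(table1_net, "PGE2_kerat", "Eumelanin_melan")
    assert parse_arrow_path(p.to_arrow()) == p.nodes


def test_arrow_parser_accepts_both_typographic_variants():
    assert parse_arrow_path("A- > B- > C") == ("A", "B", "C")
    assert parse_arrow_path("A->B->C") == ("A", "B", "C")
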