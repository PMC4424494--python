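"""Virtual knockouts: classification, essentiality, alternate routes."""

from __future__ import annotations

import random

import pytest

from conftest import network_from_edges
from oracles import is_cut_node_for_pair, random_edge_list
from pigmentnet import (
    alternate_path_report,
    classify_pair,
    essentiality_scan,
    knockout,
    shortest_path,
    shortlist_candidates,
    source_target_paths,
)


# -- knockout construction --------------------------------------------------

def test_knockout_removes_node_and_incident_edges(table1_net):
    perturbed = knockout(table1_net, "PLC_melan")
    assert perturbed.node_count == 20 and perturbed.edge_count == 17
    assert "PLC_melan" not in perturbed
    # value semantics: the baseline is untouched
    assert table1_net.node_count == 21 and table1_net.edge_count == 20


def test_knockout_of_an_isolated_node_only_drops_the_node():
    net = network_from_edges([("A", "B")])
    from pigmentnet import classify_node

    net.add_node(classify_node("Lonely"))
    perturbed = knockout(net, "Lonely")
    assert perturbed.edge_count == 1 and perturbed.node_count == 2


def test_knockout_of_unknown_node_is_a_lookup_error(table1_net):
    with pytest.raises(KeyError):
        knockout(table1_net, "GHOST")


# -- pair classification ----------------------------------------------------

def test_rerouting_when_the_removed_node_sat_on_a_tied_shortest_route(printed_net):
    out = classify_pair(
        printed_net, knockout(printed_net, "PTGER3_melan"),
        "UV", "Eumelanin_melan", "PTGER3_melan",
    )
    assert out.status == "rerouted"
    assert "PTGER3_melan" in out.baseline_path.nodes
    assert ("EDN1_kerat", "EDNRB_melan") in list(
        zip(out.perturbed_path.nodes, out.perturbed_path.nodes[1:])
    )


def test_abrogation_when_the_removed_node_is_unavoidable(printed_net):
    out = classify_pair(
        printed_net, knockout(printed_net, "TYR_melan"),
        "UV", "Eumelanin_melan", "TYR_melan",
    )
    assert out.status == "abrogated" and out.perturbed_path is None


def test_unchanged_when_the_removed_node_misses_every_route(table1_net):
    out = classify_pair(
        table1_net, knockout(table1_net, "CREB1_melan"),
        "PGE2_kerat", "Eumelanin_melan", "CREB1_melan",
    )
    assert out.status == "unchanged"
    assert out.baseline_path.nodes == out.perturbed_path.nodes


def test_removed_source_or_target_is_not_applicable(table1_net):
    out = classify_pair(
        table1_net, knockout(table1_net, "PGE2_kerat"),
        "PGE2_kerat", "Eumelanin_melan", "PGE2_kerat",
    )
    assert out.status == "not_applicable"


def test_baseline_disconnected_pair_is_not_applicable(table1_net):
    out = classify_pair(
        table1_net, knockout(table1_net, "TP53_kerat"),
        "UVA", "Eumelanin_melan", "TP53_kerat",
    )
    assert out.status == "not_applicable"


def test_mismatched_networks_are_a_consistency_error(table1_net):
    with pytest.raises(ValueError):
        classify_pair(table1_net, table1_net, "PGE2_kerat", "Eumelanin_melan",
                      "PLC_melan")


@pytest.mark.parametrize("seed", range(20))
def test_abrogation_matches_the_cut_node_oracle(seed):
    rng = random.Random(5000 + seed)
    edges = random_edge_list(rng, rng.randint(4, 10), 0.25) or [("N00", "N01")]
    net = network_from_edges(edges)
    names = sorted(set(n for e in edges for n in e))
    for removed in names:
        perturbed = knockout(net, removed)
        for s in names:
            for t in names:
                if s == t or removed in (s, t):
                    continue
                out = classify_pair(net, perturbed, s, t, removed)
                if out.status == "not_applicable":
                    continue
                assert (out.status == "abrogated") == is_cut_node_for_pair(
                    edges, removed, s, t
                )


@pytest.mark.parametrize("seed", range(10))
def test_distances_never_shrink_and_reachability_never_grows(seed):
    rng = random.Random(9000 + seed)
    edges = random_edge_list(rng, 8, 0.3) or [("N00", "N01")]
    net = network_from_edges(edges)
    names = sorted(set(n for e in edges for n in e))
    removed = rng.choice(names)
    perturbed = knockout(net, removed)
    for s in names:
        for t in names:
            if s == t or removed in (s, t):
                continue
            before = shortest_path(net, s, t)
            after = shortest_path(perturbed, s, t)
            if before is None:
                assert after is None
            elif after is not None:
                assert after.length >= before.length


# -- essentiality scan ------------------------------------------------------

def test_scan_over_the_sample_cascade_matches_the_cut_node_counts(table1_net):
    intermediates = ["PTGER1_melan", "PTGER3_melan", "PLC_melan", "DAG_melan",
                     "PRKCB_melan", "TYR_melan"]
    table, outcomes = essentiality_scan(
        table1_net, ["PGE2_kerat"], ["Eumelanin_melan"], intermediates
    )
    counts = dict(table.rows)
    assert counts == {
        "PLC_melan": 1, "DAG_melan": 1, "PRKCB_melan": 1, "TYR_melan": 1,
        "PTGER1_melan": 0, "PTGER3_melan": 0,
    }
    # ranked by count descending, then lexicographically
    assert [n for n, _ in table.rows[:4]] == sorted(
        ["PLC_melan", "DAG_melan", "PRKCB_melan", "TYR_melan"]
    )
    assert len(outcomes) == 6


def test_counts_never_exceed_connected_pairs_and_exclude_own_pairs(printed_net):
    sources, targets = printed_net.sources, printed_net.targets
    baseline = source_target_paths(printed_net, sources, targets)
    table, outcomes = essentiality_scan(
        printed_net, sources, targets, ["NFKB1_kerat", "TYR_melan", "KIT_melan"]
    )
    for _, count in table.rows:
        assert 0 <= count <= baseline.connected_pairs
    for o in outcomes:
        for pair in o.pairs:
            if o.removed in (pair.source, pair.target):
                assert pair.status == "not_applicable"


def test_empty_candidate_set_is_rejected(table1_net):
    with pytest.raises(ValueError):
        essentiality_scan(table1_net, ["PGE2_kerat"], ["Eumelanin_melan"], [])


def test_unknown_candidates_are_a_lookup_error(table1_net):
    with pytest.raises(KeyError):
        essentiality_scan(table1_net, ["PGE2_kerat"], ["Eumelanin_melan"], ["GHOST"])


# -- shortlisting -----------------------------------------------------------

def test_zero_sizes_give_the_empty_shortlist(table1_net):
    ps = source_target_paths(table1_net, ["PGE2_kerat"], ["Eumelanin_melan"])
    assert shortlist_candidates(table1_net, ps, {"top_by_degree": 0,
                                                 "top_by_path_frequency": 0}) == set()


def test_top_frequency_shortlist_on_the_tied_cascade(table1_net):
    ps = source_target_paths(
        table1_net, ["PGE2_kerat"], ["Eumelanin_melan"], mode="all_tied"
    )
    chosen = shortlist_candidates(table1_net, ps, {"top_by_path_frequency": 3})
    assert chosen == {"DAG_melan", "PLC_melan", "PRKCB_melan"}


def test_oversized_request_clamps_to_eligible_nodes(table1_net):
    ps = source_target_paths(
        table1_net, ["PGE2_kerat"], ["Eumelanin_melan"], mode="all_tied"
    )
    chosen = shortlist_candidates(table1_net, ps, {"top_by_path_frequency": 999})
    # every path intermediate, but never the designated source or target
    assert "PGE2_kerat" not in chosen and "Eumelanin_melan" not in chosen
    assert chosen == {"PTGER1_melan", "PTGER3_melan", "PLC_melan", "DAG_melan",
                      "PRKCB_melan", "TYR_melan"}


# -- alternate-path report --------------------------------------------------

def test_report_prints_alternates_and_none_for_abrogations(printed_net):
    _, outcomes = essentiality_scan(
        printed_net, ["UV"], ["Eumelanin_melan"], ["PTGER3_melan", "TYR_melan",
                                                   "CREB1_melan"]
    )
    rows = alternate_path_report(outcomes)
    by_removed = {r[0]: r for r in rows}
    assert by_removed["TYR_melan"][4] == "None"
    assert by_removed["PTGER3_melan"][4].startswith("UV- > ")
    assert "CREB1_melan" not in by_removed  # unchanged pairs emit no row
    # a rerouted alternate re-traces in the perturbed network
    from pigmentnet import knockout as ko, parse_arrow_path

    alt = parse_arrow_path(by_removed["PTGER3_melan"][4])
    perturbed = ko(printed_net, "PTGER3_melan")
    for u, v in zip(alt, alt[1:]):
        assert perturbed.graph.has_edge(u, v)
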