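"""Trace shortest signalling routes from a keratinocyte-secreted factor to
melanin synthesis, and extract the source-to-target sub-network.

PGE2 released by keratinocytes can reach eumelanin production in
melanocytes through either of two prostaglandin receptors; both routes tie
at six steps, and the canonical (lexicographically smallest) one is
reported."""

from pigmentnet import (
    all_shortest_paths,
    extract_s2t_subnetwork,
    source_target_paths,
    table1_fixture,
)

net = table1_fixture()

tied = all_shortest_paths(net, "PGE2_kerat", "Eumelanin_melan")
print(f"tied shortest routes PGE2_kerat -> Eumelanin_melan: {len(tied)}")
for p in tied:
    print(f"  length {p.length}: {p.to_arrow()}")

pset = source_target_paths(net, ["PGE2_kerat", "UVA"], ["Eumelanin_melan"])
print(f"connected source->target pairs: {pset.connected_pairs} "
      "# the UVA cascade dead-ends at cAMP in this sample")

sub = extract_s2t_subnetwork(net, pset)
print(f"S2T sub-network: {sub.node_count} nodes, {sub.edge_count} edges, "
      f"weakly connected: {sub.is_weakly_connected()}")
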