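# Methods

## Model

The object of study is a directed, typed interaction graph over molecular
components of UV-driven skin pigmentation in two epidermal compartments.
Node identity is the curated name with its terminal compartment suffix
(`_kerat` = keratinocyte, `_melan` = melanocyte; no suffix = extracellular
or shared, e.g. the UV/UVA/UVB triggers). Complexes are nodes whose base
name lists members separated by colons. Edges carry one or more interaction
types from a controlled vocabulary (activates, inhibits, induces,
increases/decreases level, increases/decreases expression, third molecule
regulation); unknown type strings are preserved but flagged. Duplicate
curated rows for one ordered pair merge into a single edge whose type set
is the union, so "edge count" always means unique ordered pairs (a
multigraph reading is deliberately not the default). Self-loops are kept
but can never participate in a shortest path.

The central modelling assumption, shared with most signalling-network
path analyses, is that *signal flow is reachability*: an inhibitory edge
transmits information just as an activating one does, and sign is carried
along as metadata rather than interpreted. No weights, no Boolean logic,
no dynamics.

## Topology metrics

Degrees count unique ordered pairs; a self-loop contributes one to each.
Node and edge betweenness are unnormalised directed Brandes betweenness
(tied shortest paths split each ordered pair's unit contribution equally);
the graph machinery is `networkx`, and the test suite checks it against an
independent exhaustive path enumeration on small random graphs. Because the
network is far from strongly connected, closeness and radiality use a
reachable-set convention: with r(v) the number of nodes reachable from v,
n the node count and Δ the largest finite directed distance in the graph,

- closeness(v) = (r/(n−1)) · (r / Σ_{w reachable} d(v,w)), 0 if r = 0;
- radiality(v) = Σ_{w reachable} (Δ + 1 − d(v,w)) / (n−1).

Unreachable pairs simply contribute nothing. Hub selection is parameterised
(`top_fraction` or `min_total_degree`) because no single published
threshold exists; ties always break lexicographically by id.

## Shortest routes and the canonical path

All distances are breadth-first (unit edge weights). Where several
minimal-length routes tie, the *canonical* path is the lexicographically
smallest node sequence, found by walking greedily from the source and
always taking the smallest-id successor that stays on some shortest route
(distances-to-target computed once on the reversed graph). This makes every
reported path string reproducible without pretending the tie does not
exist; `all_tied` mode returns the full tied set, and the source→target
machinery reports both the per-pair canonical count and the tied count.
All-vs-all connectivity counts ordered pairs (u, v), u ≠ v, at finite
distance.

## Knockout classification

A knockout deletes one node and its incident edges (value semantics; the
baseline is never mutated). For each ordered (source, target) pair:

- *not_applicable* — the removed node is the source or target, or the pair
  was already disconnected at baseline. Excluding a node's own pairs
  matters for essentiality ranking: a designated receptor can otherwise
  never score low.
- *abrogated* — connected at baseline, disconnected after removal
  (equivalently: the node lay on every simple path; the test suite verifies
  this equivalence exhaustively).
- *rerouted* — the removed node lay on at least one *tied* baseline
  shortest route and the pair stays connected. The stored baseline path is
  the smallest tied route through the removed node (the route the knockout
  invalidates), the stored perturbed path the canonical alternate; the two
  therefore always differ in sequence. Judging reroutes against tied routes
  rather than only the single canonical path is a deliberate choice:
  removing one of two redundant receptors is a reroute, not a no-op, which
  matches how control/alternate route pairs are presented in the curated
  analysis this package reproduces.
- *unchanged* — the removed node lay on no baseline shortest route; the
  canonical path survives verbatim.

Essentiality counts abrogations only; rerouting never counts. The ranked
table sorts by count descending, then id. Candidate shortlisting takes the
union of the top-n nodes by total degree and the top-m by shortest-path
frequency (designated sources/targets excluded); n and m are parameters
because the published analysis states the criteria but not its thresholds,
so the published 33-node shortlist membership is reproducible in rule but
not in extension.

## Synthetic generator

`SyntheticSpec` describes a layered feed-forward cascade: layer 0 holds the
designated sources (in-degree 0 by construction), the last layer the
designated biological-process sinks (out-degree 0), intermediate nodes are
spread evenly across the remaining layers. Every non-source node draws one
mandatory parent from the previous layer — which makes every target
reachable from some source — and extra parents with probability
(redundancy − 1)/|previous layer| each, so `redundancy` is the expected
in-branch count and directly controls how robust routes are to knockouts
(the suite checks the abrogation fraction is non-increasing in redundancy,
averaged over seeds). Compartment labels are a seeded shuffle of the
requested keratinocyte/melanocyte counts; a mandatory edge crosses
compartments with probability `cross_talk_prob`, emulating paracrine
signalling. Edges are typed `inhibits` with probability `inhibition_frac`,
else `activates`. The default output is a DAG; `feedback_prob` > 0 adds
backward/within-layer edges, and nothing in the analysis code assumes
acyclicity. One `random.Random(seed)` owns all randomness, so identical
spec + seed gives a byte-identical edge table on any platform.

Defaults (142 keratinocyte + 113 melanocyte nodes, 20 sources, 9 targets)
mirror the curated model's published scale. Depth 8 approximates the
printed route lengths (5–14 edges); cross-compartment probability 0.15
reflects that paracrine links are a minority of curated edges; redundancy
1.5 yields the mix of fragile and rerouting pairs the analysis focuses on;
inhibitory fraction 0.2 is a typical share for signalling maps. These four
are conventions chosen once, not published values.

What the generator does *not* emulate: the real degree distribution of the
curated network (heavy-tailed hubs like NFKB1), feedback loops present in
real signalling, or biologically meaningful node names. Passing tests on
synthetic networks therefore demonstrate correctness of the machinery
(path enumeration, classification, counting), not biological conclusions
about pigmentation.

## Packaged fixtures

Three in-print data sets ship inside the package and are checksum-pinned in
the tests: the 20-row sample interaction table (21 nodes/20 edges); the
printed predicted/control/alternate pathway strings, whose edge union forms
a 60-node/65-edge network with the three UV triggers as sources and the
twelve printed route terminals as targets; and the designated 20-source /
9-target sets. Printed quirks are kept verbatim rather than silently
curated: `UV`, `UVA` and `UVB` remain three distinct trigger nodes, and the
route terminals `melanogenesis` and `Melanogensis` (sic) remain distinct
sink nodes. A branch terminal written as two alternatives ("eumelanin /
pheomelanin") is stored as two paths. The printed strings carry no
interaction types, so fixture edges are typed `unspecified` — intentionally
outside the controlled vocabulary, exercising the flagged-but-preserved
path of the parser. The full 265-node/429-edge curated model lives in
supplementary material that is distributed separately; its headline counts
are therefore not recomputed here, and the analysis operates on any such
table supplied in the same schema.

## Numerical and degenerate-input conventions

Parsing trims whitespace, collapses internal runs to underscores, preserves
case in node ids, and canonicalises interaction types case-insensitively.
Empty networks: empty degree profile, no hubs, header-only edge table; SIF
and GraphML refuse empty graphs. A source equal to its target yields the
zero-length path. Betweenness comparisons in tests use exact float
tolerance (1e-9-scale) since contributions are small rationals. Every
ordering the package emits (records, descriptors, edges, tied paths,
ranking tables) is either stable input order or an explicit sort — no
hash-order dependence anywhere.

## Problem sizes

The test suite and the acceptance script run entirely on the packaged
fixtures, on random graphs of 4–12 nodes (where exhaustive enumeration is
the oracle: 200 networks in the property suite, 100 in the acceptance
script), and on generated cascades of 20–60 nodes; the whole suite
completes in a few seconds. These sizes are chosen so that every
non-trivial number is cross-checked against an independent brute-force
computation; the machinery itself is the same code path one would run on
the full 265-node model, where all-vs-all BFS and Brandes betweenness are
comfortably fast.

## Known limitations

- Sign-blind path analysis can report routes that are not biologically
  coherent chains of activation.
- Canonical-path determinism is an ordering convention, not a biological
  claim; tied alternates are equally valid and available via `all_tied`.
- Single-node knockouts only; combinatorial essentiality is out of scope.
- The category heuristics (environmental factors, process-name suffixes)
  cover the packaged vocabulary; arbitrary curated tables should supply a
  node-annotation file for faithful categories.
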