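# Methods

## The screening model

The pipeline operationalises a common network-pharmacology screen: a
multi-component remedy is represented by the set of proteins its
ingredients putatively bind, a disease by its known therapeutic targets,
and both sets are embedded in a merged PPI map. The working assumptions
are those of the field: (i) the merged PPI union is an unweighted simple
graph (no confidence scores, no direction); (ii) topological prominence is
a proxy for functional importance; (iii) over-representation of a gene set
among the topologically prominent proteins indicates pathway-level action.

The screen is two-staged and entirely deterministic given its inputs:

1. **Hub stage.** A node is a hub iff `degree > hub_factor × median(degree)`
   over *all* network nodes, strict inequality, `hub_factor = 2`. On
   sparse PPI unions the median degree is 1 and the rule reduces to
   "remove degree ≤ 2".
2. **Major-hub stage.** The vertex-induced subgraph on the hubs ("direct
   interactions among hubs") is profiled with degree, betweenness,
   closeness, and coreness, and a hub survives iff it strictly exceeds the
   threshold on all four. By default the thresholds are the medians of the
   four metrics over the profiled graph (`median_derived`); explicit
   cutoffs can be supplied instead, and the published values
   (4 / 0.0002 / 0.3919 / 5) ship as the `paper` preset.

A flag (`profile_graph="full"`) profiles the metrics on the whole network
instead of the hub subnetwork, as a sensitivity analysis; the two
conventions genuinely differ and published screens rarely say which they
used. This is the main reconstruction uncertainty of the whole procedure
and the reason the explicit-cutoff preset is not expected to reproduce a
published major-hub count on other people's data.

## Metric conventions

- **Betweenness**: fractional shortest-path counting, endpoints excluded;
  normalised by `(n−1)(n−2)/2`. Graphs with fewer than three nodes
  normalise to all zeros.
- **Closeness**: component-restricted with Wasserman–Faust scaling,
  `((r−1)/(n−1)) · ((r−1)/Σ d)` for a node whose component has `r` nodes.
  This keeps values in [0, 1] and comparable across components of a
  disconnected graph; isolated nodes score 0. Harmonic closeness
  (normalised by `n−1`) is available as an alternative, since the
  convention behind any particular published cutoff is usually unstated.
- **Coreness**: k-core shell index (iterative pruning of nodes with degree
  < k); satisfies `coreness(i) ≤ degree(i)` everywhere.
- **Medians** over an even count are the mean of the two central order
  statistics. Every filter is a strict `>`, so an all-equal metric empties
  its criterion — the intended behaviour of a median cut.
- No tie-breaking is needed anywhere in the screen: the filters are
  deterministic set comprehensions. In `top_pathways`, ties in p are
  broken by larger overlap, then lexical pathway name.
- Centralities are floating point; report comparisons in tests use an
  absolute tolerance of 1e−10 against brute-force oracles.

## Null model

"Randomised counterpart" is read as **G(n, m)** resampling: uniform over
simple graphs with exactly the real network's node set and edge count,
node class labels carried over. Degree-preserving rewiring is deliberately
not offered — conserving degrees would conserve precisely the heavy tail
that the hub screen detects, making the contrast vacuous. Under
`median_derived` thresholds each replicate re-derives its own medians
(mirroring how the real network was screened); explicit thresholds are
reused verbatim. The report gives per-replicate major-hub counts and the
exceedance fraction `#{replicates with ≥ real count}/n_replicates`; with
the default 100 replicates the resolution of that fraction is 0.01.

## Enrichment

Over-representation uses the upper-tail hypergeometric `P(X ≥ k)` with
population `N` (the universe), `K` pathway members, `n` query genes —
equivalent to the one-sided Fisher exact test, and verified against both
exhaustive draw enumeration and a factorial-based Fisher oracle in the
tests. The universe defaults to the analysed network's nodes restricted to
the annotation (option: the annotation's own universe); pathways empty
after restriction are skipped. Benjamini–Hochberg q-values (via
statsmodels) are always reported; the significance filter uses raw
p < alpha by default — matching the original screen's convention — with
`use_q` recommended when many pathways are tested. Because the statistic
is discrete, the realised false-positive rate of the raw-p filter sits at
or just below alpha. Module assignment (grouping significant pathways and
their member hubs into functional blocks) is mechanised through an
explicit pathway→category table rather than inferred.

## Synthetic studies

The generator emulates the *shape* of a published herb-formula screen; all
defaults are the study conditions themselves:

| parameter | default | meaning |
|---|---|---|
| `n_nodes` / `n_edges` | 5559 / 21567 | merged study network size |
| `leaf_fraction` | 0.55 | fraction of degree-1 nodes, pinning median degree at 1 |
| `n_targets_herb_a` / `b` / `n_overlap` | 175 / 348 / 106 | herb target sets and shared ids |
| `n_disease_targets` | 90 (75 + 15) | disease targets across two labelled sources |
| `n_planted_hubs` | 20 | nodes boosted to unambiguous major-hub topology |
| `hub_boost_quantile` | 0.97 | planted-hub degree target within the core degree distribution |
| `n_pathways` / `n_planted_pathways` | 50 / 5 | annotation size and planted signal |
| `pathway_size_range` | (10, 60) | uniform pathway sizes |
| `planted_pathway_fraction` | 0.8 | fraction of a planted pathway drawn from the planted-hub neighbourhood |

Construction: a preferential-attachment core (grown one edge per node,
then densified preferentially to the exact edge budget) surrounded by
degree-1 leaves attached preferentially to the core. This reproduces the
two features the screen depends on — median degree 1 (hub cutoff 2) and a
heavy-tailed core — while keeping the edge count exact. Planted hubs are
wired post hoc to random core partners up to the core's 97th degree
percentile (never below `2·median+3`), and the added edges are balanced by
deleting edges between unplanted nodes that keep at least degree 3 (2 as a
fallback), so `n_edges` is invariant. Planted pathways are built around
the planted hubs themselves and filled degree-weighted from their
interactor neighbourhood; remaining members and all non-planted pathways
are uniform. An `erdos_renyi` topology option generates structure-free
fixtures for null-style testing. All randomness flows from one seed
through `numpy.random.SeedSequence`; equal configs serialise
byte-identically.

Because the generator emits the study network itself (seeds, linkers and
all), the config written by `simulate` analyses it with
`expansion_rule="full"`; for real exports the library default is
first-neighbour closure of the seed sets, with `seed_only` and `full` as
alternatives.

**What the generator does not emulate:** real PPI unions have
database-correlated redundancy, study bias toward well-known proteins,
and identifier noise; real pathway annotations overlap heavily and are
hierarchically nested; real target predictions carry false positives that
are not independent of degree. Passing the recovery tests therefore shows
the pipeline is correct and well-calibrated under its own model, not that
any particular biological screen's published hub list would be reproduced.

## Problem sizes in the tests

The full-size study (5 559 nodes) is screened once in the null-model
test and once in `scripts/acceptance.py` (≈ 20 s per screen, dominated by
betweenness on the ~2 200-node hub subnetwork). Repeated-screen tests
(20-seed recovery) use a 1 400-node / 5 430-edge study with the same edge
density and leaf fraction, which screens in ~1 s. Metric-oracle tests run
over every connected graph on up to 7 nodes (the complete graph atlas)
plus 200 seeded random graphs with up to 30 nodes.

## Known limitations

- Identifier handling is string normalisation plus an optional mapping
  table; no live ID-mapping service is queried, so cross-database
  reconciliation is only as good as the supplied map.
- Closeness/betweenness conventions differ across published screens;
  explicit cutoffs from elsewhere should be used only with matching
  conventions (normalised, Wasserman–Faust).
- The exceedance fraction is a Monte-Carlo estimate with resolution
  `1/n_replicates`; it is a structure check, not a calibrated p-value.
- Enrichment quality is bounded by the supplied GMT; proprietary pathway
  contents cannot be reproduced by construction.
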