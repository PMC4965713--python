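# Methods

## Network model

The detector operates on a multi-relationship protein interaction network:
a shared protein universe carrying up to four typed, undirected, weighted
edges per pair. The physical relation is the input PPI network weighted by
the edge clustering coefficient (ECC); the other three relations encode
shared GO annotation per aspect (BP, MF, CC), weighted by the squared
annotation overlap. All weights are strictly positive by construction —
zero-weight edges are filtered before assembly — and the network is
decomposed back into four single-relation graphs (PPIN, BPN, MFN, CCN)
before mining, because the relations are measured under different
conditions and are deliberately not merged into one score.

Two filters shape the network:

* Physical edges with ECC = 0 (no common neighbour, or an endpoint of
  degree 1) are removed. The rationale is noise suppression: an interaction
  not embedded in any triangle has no topological support.
* A shared-annotation edge requires at least two common terms in its aspect
  and at least one common neighbour of the pair in the *original* PPI graph
  (the pre-ECC-filter topology — the ECC filter applies to the physical
  relation only). Share-edges are newly generated relations and may connect
  pairs with no physical interaction; the common-neighbour condition
  confines them to the PPI vertex universe and bounds candidate enumeration
  to two-hop pairs, which is also how the implementation enumerates them.

Annotation terms are used exactly as given, with no propagation through the
ontology graph; "shared function" is counted on the annotation sets
themselves. ECC neighbour sets follow the standard convention: N_i is the
full PPI neighbourhood of v_i, partner included. The brute-force oracle in
the test suite recomputes ECC from the adjacency matrix under exactly this
convention, so the choice is pinned by a test rather than implicit.

## Detection procedure

Networks are visited in fixed order (PPIN, BPN, MFN, CCN); within each
network every vertex seeds a growth, in lexicographic order. Growth offers
the seed's neighbours one by one — descending seed-edge weight, ties broken
lexicographically — and keeps a neighbour only if the weighted density of
the enlarged candidate stays ≥ WDT. Growth never leaves the seed's
one-ring: candidates are generated from the neighbourhood graph of each
protein, not by recursive frontier expansion. Weighted density normalises
by the subgraph's own maximum edge weight (not the network-wide maximum),
so a single edge always has density 1 and the measure lies in (0, 1].
An edgeless or singleton member set has density 0 by definition — it
cannot cohere, and the convention lets the growth loop treat such sets
uniformly.

Coupling pruning then removes members (never the seed) whose weighted
degree into the candidate is *strictly* smaller than into the external
neighbour set, iterating to a fixpoint with the neighbour set recomputed
each pass. Ties retain the member. The seed is exempt so that every seed's
candidate stays anchored; since growth restarts from every vertex, no
complex is lost to this exemption. A node pruned once is not reconsidered —
pruning runs after growth has completed.

A candidate shorter than `min_size` (default 2) is dropped. The surviving
candidate enters the accumulating complex set only if it is not a subset of
(or equal to) any complex already accepted; the accumulating set is global
across the four networks, so a BPN candidate can be suppressed by a PPIN
superset found earlier. Finally a redundancy filter processes complexes in
output order — size descending, weighted density descending, then
lexicographic members — and discards the later member of any pair whose
matching score reaches the overlap threshold (default 0.8). Because of the
sort, "later" is exactly the smaller complex, then the less dense one, then
the lexicographically later one; size takes precedence over density as the
primary discard key, a deliberate tie-break where the discard rule is
otherwise underdetermined ("small density or small size"). Each complex's
density is measured on its own source network, including for
cross-network pairs.

All iteration is over sorted structures and all weight sums run in
canonical pair order, so identical inputs and parameters give identical
output independent of hash seeding or adjacency insertion order (float
summation order is part of the contract; a reordered copy of the same
graph yields bit-identical densities).

## Parameters

| parameter | default | meaning |
|---|---|---|
| WDT | 0.05 | weighted-density floor during growth, in [0, 1]; the best-performing setting on yeast benchmarks, kept as the package default |
| overlap threshold | 0.8 | matching score at which two outputs are redundant |
| min_size | 2 | smallest reportable complex; the weakest meaningful floor, configurable |
| match threshold | 0.2 | MS level at which a prediction matches a benchmark complex |
| significance cutoff | 0.01 | strict upper bound on p for a "significant" complex |

## Evaluation

Matching uses MS(A, B) = |A∩B|²/(|A||B|). A prediction counts as matched
if some benchmark complex reaches the threshold, and vice versa for
benchmark recall; a perfect match means MS = 1, i.e. set equality.
F-measure is the harmonic mean of precision and recall (0 when both are 0).

Functional coherence uses the hypergeometric upper tail: for each GO term
annotating a complex member, the probability of at least the observed
number of carriers in a draw of the complex's size from the background.
The background is the full vertex set of the input PPI network — the
self-contained choice when no reference annotation universe is given. The
per-complex p-value is the minimum over terms and aspects; ties between
terms resolve to the lexicographically first term. P-values are raw by
default, matching the conventional p < 0.01 cutoff these scores are quoted
under; a Benjamini–Hochberg adjustment across complexes is available behind
a flag for users who want error-rate control. The p-score averages
−log₁₀ p over the significant complexes only (dividing by their count, not
by the total number of predictions — the conditional reading of the
definition; the two readings differ only by the proportion factor).
"lg" is log base 10 throughout.

## Synthetic benchmark generator

The generator emulates the two structural premises the method relies on:
complexes are dense subgraphs, and complex members share annotations.
Disjoint planted member blocks (default: 10 complexes of 4–8 proteins) are
wired internally at p_in (default 0.9); every other pair — background,
cross-complex, and 40 noise proteins — at p_out (default 0.02). Each
complex receives 3 fresh GO terms per aspect, annotated onto all members,
and a leak rate (default 0.05) sprinkles each term onto random outsiders.
A single seeded NumPy generator drives wiring then annotation in fixed call
order, so a spec plus seed reproduces a bundle exactly; members that end up
isolated are given one edge to a complex partner so the ground truth is
always contained in the network's vertex set. Protein IDs are zero-padded
("P0001") so lexicographic tie-breaks in the detector are predictable.

What the generator does *not* model: scale-free degree structure, shared
members between complexes, core–attachment organisation, annotation depth
differences between GO aspects, and experimental bait–prey sampling bias.
Passing the recovery tests therefore demonstrates correctness of the
pipeline's mechanics on favourable, well-separated structure — not
performance on real interactome data, where noise is structured and
annotation is incomplete.

The hand-built coupling example (`coupling_removal_example`) is a six-node
weighted network in which a candidate member D has weighted degree 0.2 into
the candidate and 0.7 (0.3 + 0.4) into the external neighbour set, so
pruning must remove exactly D; it doubles as the acceptance-script fixture.

## Numerical choices and problem sizes

Internal arithmetic is double precision; file output rounds weights to six
decimals, which round-trips stably. Hypergeometric tails come from
`scipy.stats.hypergeom.sf` and are clamped into (0, 1] so that a log-score
is always defined. Exact-value tests assert to 1e-12; brute-force
equivalence suites run on a few hundred random instances of ≤ 12 nodes,
and end-to-end properties (determinism, redundancy, threshold monotonicity,
planted recovery) on generated networks of roughly 100 proteins — sizes at
which every invariant can be checked exhaustively while the full suite
runs in seconds.

## Known limitations

* Recovery and enrichment figures on synthetic data are optimistic by
  construction (annotations correlate with the planted truth).
* Overlapping complexes are only partially representable: subset screening
  and redundancy filtering suppress heavily overlapping outputs by design.
* No GO ancestor propagation means annotation at inconsistent granularity
  across datasets will change share-edge structure; harmonising annotation
  depth is left to preprocessing.
* Identifier matching is exact and case-sensitive; cross-database ID
  mapping is a user preprocessing step.
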