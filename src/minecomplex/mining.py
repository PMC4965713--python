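"""Greedy detection of high-cohesion / low-coupling complexes.

The detector visits each single-relation weighted network in a fixed order
(PPIN, BPN, MFN, CCN) and grows a candidate complex from every vertex:

1. *Growth* — the seed's neighbours are inserted one by one, heaviest
   seed-edge first; an insertion is kept only if the weighted density of the
   candidate stays at or above the threshold WDT.
2. *Coupling pruning* — members (never the seed) whose weighted degree into
   the candidate is strictly smaller than their weighted degree into the
   external neighbour set are removed, iterating to a fixpoint.
3. *Subset screening* — a candidate equal to, or contained in, a complex
   already accepted (across all four networks) is discarded.
4. *Redundancy filtering* — among pairs whose matching score reaches the
   overlap threshold (default 0.8), the smaller complex is discarded
   (ties: lower weighted density, then lexicographically later members).

Weighted density of a subgraph is the sum of its edge weights, doubled,
normalised by the subgraph's maximum edge weight times the number of vertex
pairs; a single edge therefore always has density 1, and the measure lies in
(0, 1].  The matching score of sets A, B is |A ∩ B|^2 / (|A| * |B|).

All iteration orders are sorted, so identical inputs and parameters yield
identical output regardless of hash seeding.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import AbstractSet, Iterable, Sequence

import networkx as nx


@dataclass
class MineParams:
    """Tunable parameters of the detector.

    wdt:
        Weighted-density threshold in [0, 1] governing neighbour acceptance
        during growth.  Default 0.05, the best-performing setting on yeast
        benchmarks.
    overlap_threshold:
        Matching-score level at which two output complexes are considered
        redundant; default 0.8.
    min_size:
        Minimum complex size; smaller candidates are dropped.  Default 2.
    """

    wdt: float = 0.05
    overlap_threshold: float = 0.8
    min_size: int = 2

    def __post_init__(self) -> None:
        if not 0.0 <= self.wdt <= 1.0:
            raise ValueError(f"wdt must be in [0, 1], got {self.wdt}")
        if not 0.0 <= self.overlap_threshold <= 1.0:
            raise ValueError(
                f"overlap_threshold must be in [0, 1], got {self.overlap_threshold}"
            )
        if self.min_size < 1:
            raise ValueError(f"min_size must be >= 1, got {self.min_size}")


@dataclass(frozen=True)
class CandidateComplex:
    """A detected complex with its provenance.

    ``wd`` is the weighted density of the member set on the source network
    at the time the candidate was finalised.
    """

    members: frozenset[str]
    seed: str
    relation: str
    wd: float

    def __post_init__(self) -> None:
        if self.seed not in self.members:
            raise ValueError("seed must be a member of the candidate complex")


def weighted_density(members: AbstractSet[str], network: nx.Graph) -> float:
    """Weighted density of the subgraph induced by ``members``.

    2 * Σ w(e) / (max w(e) * |V| * (|V| - 1)), sums and max over the induced
    subgraph's own edges.  Defined as 0 for fewer than two members or an
    edgeless induced subgraph (such a set cannot cohere).
    """
    n = len(members)
    if n < 2:
        return 0.0
    # canonical pair order: summation is independent of adjacency ordering
    keyed = sorted(
        (tuple(sorted((u, v))), d)
        for u, v, d in network.subgraph(members).edges(data="weight")
    )
    if not keyed:
        return 0.0
    weights = [d for _, d in keyed]
    return 2.0 * sum(weights) / (max(weights) * n * (n - 1))


def swd(u: str, targets: AbstractSet[str], network: nx.Graph) -> float:
    """Sub-network weighted degree: Σ w(u, v) over v in ``targets``."""
    if u not in network:
        return 0.0
    adj = network[u]
    return sum(adj[v]["weight"] for v in sorted(targets) if v in adj)


def grow_candidate(seed: str, network: nx.Graph, params: MineParams) -> CandidateComplex:
    """Grow a candidate complex from ``seed`` within its neighbourhood.

    Neighbours are offered in descending seed-edge weight (ties broken
    lexicographically); each is kept only if the weighted density of the
    enlarged candidate is at least ``params.wdt``.  Growth never leaves the
    seed's one-ring.
    """
    if seed not in network:
        raise KeyError(f"seed {seed!r} is not a vertex of the network")
    ccs: set[str] = {seed}
    order = sorted(network[seed], key=lambda v: (-network[seed][v]["weight"], v))
    for v in order:
        trial = ccs | {v}
        if weighted_density(trial, network) >= params.wdt:
            ccs = trial
    return CandidateComplex(
        members=frozenset(ccs),
        seed=seed,
        relation=network.graph.get("relation", ""),
        wd=weighted_density(ccs, network),
    )


def prune_coupling(candidate: CandidateComplex, network: nx.Graph) -> CandidateComplex:
    """Remove members more strongly coupled to the outside than to the candidate.

    With NS the external neighbour set of the candidate, a member u (never
    the seed) is removed when swd(u, CCS \\ {u}) < swd(u, NS), strictly;
    removal repeats, recomputing NS each pass, until no member qualifies.
    """
    ccs = set(candidate.members)
    while True:
        ns = {v for u in ccs if u in network for v in network[u] if v not in ccs}
        flagged = [
            u
            for u in sorted(ccs)
            if u != candidate.seed
            and swd(u, ccs - {u}, network) < swd(u, ns, network)
        ]
        if not flagged:
            break
        ccs.difference_update(flagged)
    return CandidateComplex(
        members=frozenset(ccs),
        seed=candidate.seed,
        relation=candidate.relation,
        wd=weighted_density(ccs, network),
    )


def matching_score(a: AbstractSet[str], b: AbstractSet[str]) -> float:
    """Overlap score of two complexes: |A ∩ B|^2 / (|A| * |B|), in [0, 1]."""
    if not a or not b:
        raise ValueError("matching_score is undefined for empty sets")
    common = len(a & b)
    return common * common / (len(a) * len(b))


def _sort_key(c: CandidateComplex) -> tuple:
    return (-len(c.members), -c.wd, tuple(sorted(c.members)))


def redundancy_filter(
    complexes: Iterable[CandidateComplex], overlap_threshold: float = 0.8
) -> list[CandidateComplex]:
    """Discard the weaker member of every pair overlapping at or above threshold.

    Complexes are processed in output order (size descending, weighted
    density descending, lexicographic members); when a pair conflicts the
    later one — smaller, then lower-density, then lexicographically later —
    is discarded, so no surviving pair has matching score >= threshold.
    """
    kept: list[CandidateComplex] = []
    for cand in sorted(complexes, key=_sort_key):
        if any(
            matching_score(cand.members, k.members) >= overlap_threshold for k in kept
        ):
            continue
        kept.append(cand)
    return kept


def mine(
    networks: Sequence[nx.Graph], params: MineParams | None = None
) -> list[CandidateComplex]:
    """Detect complexes across one or more single-relation weighted networks.

    Networks are visited in the order given; within each network every
    vertex seeds a growth in sorted order.  A grown-and-pruned candidate
    enters the accumulating set only if it meets ``min_size`` and is not a
    subset of (or equal to) any complex already accepted — the accumulating
    set is global across networks.  A final redundancy filter enforces
    pairwise matching score below the overlap threshold.  Output is sorted
    by size (descending), weighted density (descending), then members.
    """
    if params is None:
        params = MineParams()
    if not networks:
        raise ValueError("mine requires at least one network")
    sc: list[CandidateComplex] = []
    for network in networks:
        for seed in sorted(network.nodes):
            cand = prune_coupling(grow_candidate(seed, network, params), network)
            if len(cand.members) < params.min_size:
                continue
            if any(cand.members <= prior.members for prior in sc):
                continue
            sc.append(cand)
    return redundancy_filter(sc, params.overlap_threshold)
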