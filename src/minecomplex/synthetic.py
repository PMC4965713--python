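"""Synthetic PPI networks with planted complexes and correlated annotations.

The generator emulates the structural premise behind topology-based complex
detection: complexes are dense subgraphs whose members share annotations.
Disjoint member blocks are wired internally at probability ``p_in``
(Erdős–Rényi within the block); every other protein pair — background,
cross-complex and noise — is wired at ``p_out``.  Each complex receives a
fixed number of fresh GO terms per aspect, annotated onto all members, and a
leak rate sprinkles those terms onto random outside proteins so that
annotation is informative but not a clean label.

A single seeded generator drives graph wiring first and annotation second,
in fixed call order, so a spec plus seed reproduces the bundle exactly.
Protein IDs are zero-padded ("P0001") to make lexicographic tie-breaking in
the detector deterministic and predictable in tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import numpy as np

from minecomplex.io import ASPECTS, Complex, GoAnnotationTable, PpiEdgeList


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a planted-complex benchmark.

    p_in / p_out are intra-complex and background edge probabilities
    (0 <= p_out < p_in <= 1); ``terms_per_complex`` GO terms per aspect are
    given to every member of a complex, and ``leak_rate`` is the per
    (term, outsider) probability of a stray annotation.
    """

    n_complexes: int = 10
    size_range: tuple[int, int] = (4, 8)
    p_in: float = 0.9
    p_out: float = 0.02
    n_noise_proteins: int = 40
    terms_per_complex: int = 3
    leak_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.size_range
        if lo < 2 or hi < lo:
            raise ValueError(f"invalid complex size range {self.size_range}")
        if not 0.0 <= self.p_out < self.p_in <= 1.0:
            raise ValueError(
                f"need 0 <= p_out < p_in <= 1, got p_in={self.p_in}, p_out={self.p_out}"
            )
        if self.n_complexes < 1:
            raise ValueError("need at least one planted complex")
        if self.n_noise_proteins < 0:
            raise ValueError("n_noise_proteins must be >= 0")
        if self.terms_per_complex < 2:
            # fewer than two shared terms can never produce a share-edge
            raise ValueError("terms_per_complex must be >= 2")
        if not 0.0 <= self.leak_rate <= 1.0:
            raise ValueError("leak_rate must be in [0, 1]")


@dataclass
class SyntheticBundle:
    """A generated benchmark: network, annotations, ground truth, spec echo."""

    ppi: PpiEdgeList
    go: GoAnnotationTable
    complexes: list[Complex]
    spec: SyntheticSpec


def generate(spec: SyntheticSpec) -> SyntheticBundle:
    """Generate a planted-complex bundle, fully reproducible from the seed."""
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.size_range
    sizes = rng.integers(lo, hi + 1, size=spec.n_complexes)
    total = int(sizes.sum()) + spec.n_noise_proteins
    proteins = [f"P{i:04d}" for i in range(1, total + 1)]

    blocks: list[list[str]] = []
    cursor = 0
    for s in sizes:
        blocks.append(proteins[cursor : cursor + int(s)])
        cursor += int(s)

    membership = {p: ci for ci, block in enumerate(blocks) for p in block}

    edges: list[tuple[str, str]] = []
    incident: set[str] = set()
    for a, b in combinations(proteins, 2):
        same = membership.get(a) is not None and membership.get(a) == membership.get(b)
        p = spec.p_in if same else spec.p_out
        if rng.random() < p:
            edges.append((a, b))
            incident.add(a)
            incident.add(b)

    # Guarantee every planted member occurs in the PPI vertex set: an
    # isolated member gets one edge to a random partner in its complex.
    for block in blocks:
        for p in block:
            if p not in incident:
                others = [q for q in block if q != p]
                q = others[int(rng.integers(len(others)))]
                pair = (p, q) if p <= q else (q, p)
                edges.append(pair)
                incident.update(pair)
    edges.sort()

    go = GoAnnotationTable()
    term_serial = 0
    for ci, block in enumerate(blocks):
        for aspect in ASPECTS:
            for _ in range(spec.terms_per_complex):
                term_serial += 1
                term = f"GO:{term_serial:07d}"
                for p in block:
                    go.add(p, term, aspect)
                if spec.leak_rate > 0.0:
                    for p in proteins:
                        if membership.get(p) == ci:
                            continue
                        if rng.random() < spec.leak_rate:
                            go.add(p, term, aspect)

    complexes = [
        Complex(members=frozenset(block), source="planted") for block in blocks
    ]
    return SyntheticBundle(
        ppi=PpiEdgeList(edges=edges, n_dropped=0),
        go=go,
        complexes=complexes,
        spec=spec,
    )


@dataclass
class CouplingExample:
    """A hand-built weighted network with a labelled candidate/neighbour split.

    The candidate set contains a node D attached to the rest of the
    candidate by a single edge of weight 0.2, while D's edges to the two
    external neighbour-set nodes weigh 0.3 and 0.4.  D's weighted degree is
    therefore 0.2 inside versus 0.7 outside, so coupling pruning must remove
    exactly D.
    """

    network: nx.Graph
    candidate: frozenset[str]
    neighbor_set: frozenset[str]
    seed: str


def coupling_removal_example() -> CouplingExample:
    """The worked example of high-coupling node removal."""
    g = nx.Graph(relation="PPIN")
    g.add_edge("A", "B", weight=0.8)
    g.add_edge("A", "C", weight=0.8)
    g.add_edge("B", "C", weight=0.8)
    g.add_edge("C", "D", weight=0.2)
    g.add_edge("D", "E", weight=0.3)
    g.add_edge("D", "F", weight=0.4)
    return CouplingExample(
        network=g,
        candidate=frozenset({"A", "B", "C", "D"}),
        neighbor_set=frozenset({"E", "F"}),
        seed="A",
    )
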