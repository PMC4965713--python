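"""Construction of the weighted multi-relationship protein interaction network.

A multi-relationship protein interaction network (MPIN) overlays up to four
typed edges on each protein pair: the physical PPI edge, weighted by the
edge clustering coefficient (ECC), and one "shared-annotation" edge per GO
aspect (BP, MF, CC), weighted by the squared annotation overlap.  Two
filters remove unreliable edges before assembly:

* PPI edges with ECC = 0 are dropped (a pair with no common neighbours is
  likely a false positive);
* a shared-annotation edge requires at least two common terms in its aspect
  AND at least one common neighbour of the pair in the original PPI graph.

Common neighbours for the share-edge filter are counted on the original,
unfiltered PPI graph; the ECC filter applies to physical edges only.
Share-edges may connect pairs with no physical interaction — they are newly
generated relations — but the common-neighbour condition confines them to
the PPI vertex universe.  GO terms are used exactly as annotated, with no
ancestor propagation through the ontology.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import AbstractSet

import networkx as nx

from minecomplex.io import ASPECTS, GoAnnotationTable, PpiEdgeList

#: Fixed order of the single-relation networks.
RELATIONS = ("PPIN", "BPN", "MFN", "CCN")

#: GO aspect -> relation label of the share-edge network.
ASPECT_TO_RELATION = {"BP": "BPN", "MF": "MFN", "CC": "CCN"}

#: Minimum number of common terms for a share-edge (pairs sharing only one
#: common function are filtered out).
MIN_COMMON_TERMS = 2


def ecc_weight(neighbors_i: AbstractSet[str], neighbors_j: AbstractSet[str]) -> float:
    """Edge clustering coefficient of an interacting pair.

    ECC = |N_i ∩ N_j|^2 / ((|N_i| - 1) * (|N_j| - 1)) when both proteins
    have degree > 1, else 0.  ``neighbors_i``/``neighbors_j`` are the full
    PPI neighbour sets of the two endpoints (each contains the partner,
    never the protein itself).
    """
    if len(neighbors_i) <= 1 or len(neighbors_j) <= 1:
        return 0.0
    common = len(neighbors_i & neighbors_j)
    return common * common / ((len(neighbors_i) - 1) * (len(neighbors_j) - 1))


def go_overlap_weight(terms_i: AbstractSet[str], terms_j: AbstractSet[str]) -> float:
    """Strength of annotation sharing: |T_i ∩ T_j|^2 / (|T_i| * |T_j|).

    Zero when either term set is empty.  Bounded by min(|T_i|, |T_j|), and
    by 1 whenever the overlap is counted from plain sets (Cauchy–Schwarz).
    """
    if not terms_i or not terms_j:
        return 0.0
    common = len(terms_i & terms_j)
    return common * common / (len(terms_i) * len(terms_j))


@dataclass
class MPIN:
    """Bundle of typed weighted edge sets over a shared protein universe.

    ``edges`` maps each relation label to {canonical pair: weight}; every
    stored weight is strictly positive (zero-weight edges are filtered out
    before assembly).  A protein pair may carry up to four parallel edges,
    at most one per relation.
    """

    vertices: frozenset[str]
    edges: dict[str, dict[tuple[str, str], float]]

    def edge_count(self) -> int:
        return sum(len(e) for e in self.edges.values())

    def to_tsv(self, path: str | Path) -> None:
        """Debug dump: protein_a, protein_b, relation, weight (6 decimals)."""
        short = {"PPIN": "PPI", "BPN": "BP", "MFN": "MF", "CCN": "CC"}
        with Path(path).open("w") as fh:
            for rel in RELATIONS:
                for (a, b), w in sorted(self.edges[rel].items()):
                    fh.write(f"{a}\t{b}\t{short[rel]}\t{w:.6f}\n")


def _share_candidate_pairs(graph: nx.Graph) -> set[tuple[str, str]]:
    """All unordered pairs with >= 1 common neighbour in ``graph``.

    Enumerated as pairs of neighbours of each vertex; pairs without a common
    neighbour cannot receive a share-edge, so nothing else is visited.
    """
    pairs: set[tuple[str, str]] = set()
    for hub in graph:
        for u, v in combinations(sorted(graph[hub]), 2):
            pairs.add((u, v))
    return pairs


def build_mpin(ppi: PpiEdgeList, go: GoAnnotationTable) -> MPIN:
    """Assemble the weighted MPIN from a PPI edge list and GO annotations.

    Physical edges are weighted by ECC and kept only when ECC > 0.  For each
    GO aspect, a share-edge connects u, v iff they have >= 2 common terms of
    that aspect and >= 1 common neighbour in the original PPI graph; its
    weight is the squared annotation overlap.
    """
    if not ppi.edges:
        raise ValueError("cannot build an MPIN from an empty PPI network")

    graph = nx.Graph(ppi.edges)
    edges: dict[str, dict[tuple[str, str], float]] = {rel: {} for rel in RELATIONS}

    for a, b in ppi.edges:
        w = ecc_weight(set(graph[a]), set(graph[b]))
        if w > 0.0:
            edges["PPIN"][(a, b)] = w

    candidates = _share_candidate_pairs(graph)
    for aspect in ASPECTS:
        annotated = go.annotated(aspect)
        rel = ASPECT_TO_RELATION[aspect]
        for u, v in candidates:
            terms_u = annotated.get(u)
            terms_v = annotated.get(v)
            if not terms_u or not terms_v:
                continue
            if len(terms_u & terms_v) < MIN_COMMON_TERMS:
                continue
            edges[rel][(u, v)] = go_overlap_weight(terms_u, terms_v)

    return MPIN(vertices=frozenset(graph.nodes), edges=edges)


def decompose(mpin: MPIN) -> list[nx.Graph]:
    """Split the MPIN into its four single-relation weighted networks.

    Returns networks in fixed order (PPIN, BPN, MFN, CCN), each carrying its
    relation label in ``graph.graph["relation"]``.  The vertex set of each
    network is exactly the endpoints of its own edges; weights are copied
    unchanged, so the decomposition is a lossless partition of the MPIN
    edge multiset.
    """
    networks: list[nx.Graph] = []
    for rel in RELATIONS:
        g = nx.Graph(relation=rel)
        for (a, b), w in mpin.edges[rel].items():
            g.add_edge(a, b, weight=w)
        networks.append(g)
    return networks
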