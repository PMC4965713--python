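"""Benchmark matching and statistical evaluation of predicted complexes.

A predicted complex matches a benchmark complex when their matching score
MS = |A ∩ B|^2 / (|A| * |B|) reaches a threshold (0.2 by convention).
Precision is the fraction of predictions matched by some benchmark complex,
recall the fraction of benchmark complexes matched by some prediction, and
the F-measure their harmonic mean.  A perfect match requires MS = 1, i.e.
set equality.

Functional coherence is scored by hypergeometric over-representation of GO
terms: for each term annotating a complex member, the upper-tail probability
of observing at least that many annotated members in a random draw of the
complex's size from the background (all proteins of the input network).  A
complex is significant when its best (minimal) p-value is below 0.01, and
the p-score is the mean of -log10(p) over significant complexes.  P-values
are used raw by default, matching the 0.01 cutoff convention; an optional
Benjamini–Hochberg adjustment is available behind a flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import AbstractSet, Iterable, Sequence

from scipy import stats

from minecomplex.io import ASPECTS, GoAnnotationTable
from minecomplex.mining import matching_score


def _member_sets(complexes: Iterable) -> list[frozenset[str]]:
    out = []
    for c in complexes:
        members = c.members if hasattr(c, "members") else frozenset(c)
        if not members:
            raise ValueError("complex with no members")
        out.append(frozenset(members))
    return out


@dataclass(frozen=True)
class MatchReport:
    """Counts and rates of a predicted-vs-benchmark comparison.

    n_cp: predicted complexes matched by some benchmark complex.
    n_cb: benchmark complexes matched by some prediction.
    n_pcp: predicted complexes perfectly matching a benchmark complex (MS = 1).
    """

    n_predicted: int
    n_benchmark: int
    n_cp: int
    n_cb: int
    n_pcp: int
    precision: float
    recall: float
    f_measure: float
    threshold: float


def match_counts(
    predicted: Sequence, benchmark: Sequence, threshold: float = 0.2
) -> MatchReport:
    """Match predictions against a benchmark set at a matching-score threshold.

    precision = N_cp / |P|, recall = N_cb / |B|,
    F = 2 * precision * recall / (precision + recall) (0 when both are 0).
    """
    pred = _member_sets(predicted)
    bench = _member_sets(benchmark)
    if not pred or not bench:
        raise ValueError("predicted and benchmark lists must be nonempty")

    n_cp = sum(1 for p in pred if any(matching_score(p, b) >= threshold for b in bench))
    n_cb = sum(1 for b in bench if any(matching_score(p, b) >= threshold for p in pred))
    n_pcp = sum(1 for p in pred if any(p == b for b in bench))

    precision = n_cp / len(pred)
    recall = n_cb / len(bench)
    f = (
        2.0 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    return MatchReport(
        n_predicted=len(pred),
        n_benchmark=len(bench),
        n_cp=n_cp,
        n_cb=n_cb,
        n_pcp=n_pcp,
        precision=precision,
        recall=recall,
        f_measure=f,
        threshold=threshold,
    )


def _background_term_counts(
    go: GoAnnotationTable, background: AbstractSet[str]
) -> dict[str, dict[str, int]]:
    counts: dict[str, dict[str, int]] = {a: {} for a in ASPECTS}
    for aspect in ASPECTS:
        table = counts[aspect]
        for protein, terms in go.annotated(aspect).items():
            if protein not in background:
                continue
            for term in terms:
                table[term] = table.get(term, 0) + 1
    return counts


def complex_enrichment(
    members: AbstractSet[str],
    go: GoAnnotationTable,
    background: AbstractSet[str],
    _term_counts: dict[str, dict[str, int]] | None = None,
) -> tuple[float, str | None]:
    """Best (minimal) hypergeometric enrichment of a complex's GO terms.

    For each term annotating >= 1 member, the upper-tail probability of
    drawing >= k term-carrying proteins in a sample of size n = |complex|
    from a background of size N containing K carriers.  Returns
    (min p-value, best term); (1.0, None) when no member is annotated.
    """
    members = frozenset(members)
    if not members <= background:
        raise ValueError("complex members must be a subset of the background")
    n_bg = len(background)
    n = len(members)
    counts = (
        _term_counts
        if _term_counts is not None
        else _background_term_counts(go, background)
    )
    best_p, best_term = 1.0, None
    for aspect in ASPECTS:
        hits: dict[str, int] = {}
        for protein in members:
            for term in go.terms(protein, aspect):
                hits[term] = hits.get(term, 0) + 1
        for term in sorted(hits):
            k = hits[term]
            big_k = counts[aspect].get(term, 0)
            p = float(stats.hypergeom.sf(k - 1, n_bg, big_k, n))
            p = min(max(p, 5e-324), 1.0)  # clamp into (0, 1]
            if p < best_p:
                best_p, best_term = p, term
    return best_p, best_term


def significant_count(p_values: Iterable[float], cutoff: float = 0.01) -> int:
    """Number of p-values strictly below the significance cutoff."""
    return sum(1 for p in _checked(p_values) if p < cutoff)


def p_score(p_values: Iterable[float], cutoff: float = 0.01) -> float:
    """Mean of -log10(p) over significant p-values (p < cutoff); 0 if none."""
    sig = [p for p in _checked(p_values) if p < cutoff]
    if not sig:
        return 0.0
    return sum(-math.log10(p) for p in sig) / len(sig)


def _checked(p_values: Iterable[float]) -> list[float]:
    ps = list(p_values)
    for p in ps:
        if p <= 0.0 or p > 1.0:
            raise ValueError(f"p-value out of (0, 1]: {p}")
    return ps


@dataclass(frozen=True)
class EnrichmentReport:
    """Per-complex enrichment with the aggregate significance summary.

    ``entries`` holds one (p-value, best term) pair per predicted complex,
    in input order; ``sc_count`` counts complexes significant at the cutoff,
    ``proportion`` its fraction of all predictions.
    """

    entries: tuple[tuple[float, str | None], ...]
    sc_count: int
    proportion: float
    p_score: float
    cutoff: float
    adjusted: bool


def enrichment_report(
    predicted: Sequence,
    go: GoAnnotationTable,
    background: AbstractSet[str],
    cutoff: float = 0.01,
    benjamini_hochberg: bool = False,
) -> EnrichmentReport:
    """Score every predicted complex for GO term over-representation.

    Computes each complex's minimal hypergeometric p-value against the
    common background, then the number and proportion of significant
    complexes and the p-score.  With ``benjamini_hochberg`` the minimal
    p-values are BH-adjusted across complexes before the cutoff is applied.
    """
    sets = _member_sets(predicted)
    if not sets:
        raise ValueError("no predicted complexes to evaluate")
    counts = _background_term_counts(go, background)
    entries = [
        complex_enrichment(members, go, background, _term_counts=counts)
        for members in sets
    ]
    ps = [p for p, _ in entries]
    if benjamini_hochberg:
        adjusted = stats.false_discovery_control(ps, method="bh")
        ps = [min(max(float(p), 5e-324), 1.0) for p in adjusted]
        entries = [(p, term) for p, (_, term) in zip(ps, entries)]
    sc = significant_count(ps, cutoff)
    return EnrichmentReport(
        entries=tuple(entries),
        sc_count=sc,
        proportion=sc / len(sets),
        p_score=p_score(ps, cutoff),
        cutoff=cutoff,
        adjusted=benjamini_hochberg,
    )
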