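"""Readers and writers for the plain-text formats the tool exchanges.

Three inputs are supported: a two-column PPI edge list (TSV, extra columns
ignored), GO annotations as either GAF 2.x or a three-column TSV
(protein, term, aspect), and benchmark complex sets with one complex per
line as whitespace-separated protein IDs.  Protein IDs are matched by exact,
case-sensitive string equality; any identifier mapping is left to the user.

No science lives here: loaders only normalise (drop self-interactions,
collapse duplicates, route GO aspect codes) and validate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

logger = logging.getLogger(__name__)

#: GO aspect labels used throughout the package.
ASPECTS = ("BP", "MF", "CC")

#: GAF single-letter aspect codes -> aspect labels.
ASPECT_CODES = {"P": "BP", "F": "MF", "C": "CC", "BP": "BP", "MF": "MF", "CC": "CC"}


def _normalise_pair(a: str, b: str) -> tuple[str, str]:
    """Canonical (sorted) form of an undirected protein pair."""
    return (a, b) if a <= b else (b, a)


@dataclass
class PpiEdgeList:
    """An undirected PPI edge list: no self-pairs, no duplicate pairs.

    ``edges`` holds canonically ordered (lexicographically sorted) pairs in
    first-appearance order; ``n_dropped`` counts records removed during
    loading (self-interactions plus repeated interactions).
    """

    edges: list[tuple[str, str]]
    n_dropped: int = 0

    def __len__(self) -> int:
        return len(self.edges)

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(self.edges)

    def vertices(self) -> set[str]:
        return {p for edge in self.edges for p in edge}


class GoAnnotationTable:
    """Per-protein GO term sets, split by aspect (BP / MF / CC).

    A protein absent from the table simply has empty term sets; proteins in
    the annotation table need not occur in the PPI network and vice versa.
    """

    def __init__(self) -> None:
        self._by_aspect: dict[str, dict[str, set[str]]] = {a: {} for a in ASPECTS}

    def add(self, protein: str, term: str, aspect: str) -> None:
        if aspect not in ASPECTS:
            raise ValueError(f"unknown GO aspect {aspect!r}; expected one of {ASPECTS}")
        self._by_aspect[aspect].setdefault(protein, set()).add(term)

    def terms(self, protein: str, aspect: str) -> frozenset[str]:
        """Term set of ``protein`` for ``aspect``; empty if unannotated."""
        if aspect not in ASPECTS:
            raise ValueError(f"unknown GO aspect {aspect!r}; expected one of {ASPECTS}")
        return frozenset(self._by_aspect[aspect].get(protein, ()))

    def proteins(self) -> set[str]:
        """All proteins carrying at least one annotation in any aspect."""
        out: set[str] = set()
        for table in self._by_aspect.values():
            out.update(table)
        return out

    def annotated(self, aspect: str) -> dict[str, frozenset[str]]:
        """Mapping protein -> term set for one aspect (annotated proteins only)."""
        return {p: frozenset(t) for p, t in self._by_aspect[aspect].items()}

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GoAnnotationTable):
            return NotImplemented
        return self._by_aspect == other._by_aspect


@dataclass(frozen=True)
class Complex:
    """A protein complex: a member set with optional score and provenance."""

    members: frozenset[str]
    score: float | None = None
    source: str | None = None

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("a complex must have at least one member")


def read_ppi_edgelist(path: str | Path) -> PpiEdgeList:
    """Load a two-column PPI edge list.

    Self-interactions are dropped and repeated (unordered) pairs collapsed;
    the number of dropped records is kept for logging.  Lines starting with
    ``#`` and blank lines are ignored.  Columns beyond the first two are
    ignored.
    """
    path = Path(path)
    seen: set[tuple[str, str]] = set()
    edges: list[tuple[str, str]] = []
    dropped = 0
    n_data = 0
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 2:
                raise ValueError(
                    f"{path}:{lineno}: expected at least two whitespace-separated "
                    f"fields, got {len(fields)}"
                )
            n_data += 1
            a, b = fields[0], fields[1]
            if a == b:
                dropped += 1
                continue
            pair = _normalise_pair(a, b)
            if pair in seen:
                dropped += 1
                continue
            seen.add(pair)
            edges.append(pair)
    if n_data == 0:
        raise ValueError(f"{path}: no interaction records found")
    if dropped:
        logger.info("%s: dropped %d self/duplicate interactions", path, dropped)
    return PpiEdgeList(edges=edges, n_dropped=dropped)


def _read_go_tsv(path: Path) -> GoAnnotationTable:
    table = GoAnnotationTable()
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: expected 3 columns (protein, term, aspect)"
                )
            protein, term, code = fields[0], fields[1], fields[2]
            if code not in ASPECT_CODES:
                raise ValueError(f"{path}:{lineno}: unknown aspect code {code!r}")
            table.add(protein, term, ASPECT_CODES[code])
    return table


def _read_go_gaf(path: Path) -> GoAnnotationTable:
    # GAF 2.x: tab-separated, 17 columns; DB object ID in col 2, GO ID in
    # col 5, aspect (P/F/C) in col 9.  Header/comment lines start with "!".
    table = GoAnnotationTable()
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            if not raw.strip() or raw.startswith("!"):
                continue
            fields = raw.rstrip("\n").split("\t")
            if len(fields) < 15:
                raise ValueError(
                    f"{path}:{lineno}: GAF line has {len(fields)} columns, "
                    "expected at least 15"
                )
            protein, term, code = fields[1], fields[4], fields[8]
            if code not in ASPECT_CODES:
                raise ValueError(f"{path}:{lineno}: unknown aspect code {code!r}")
            table.add(protein, term, ASPECT_CODES[code])
    return table


def read_go_annotations(path: str | Path, format: str = "tsv") -> GoAnnotationTable:
    """Load GO annotations from a GAF 2.x file or a 3-column TSV.

    Aspect codes P/F/C map onto BP/MF/CC; duplicate (protein, term, aspect)
    records collapse silently.
    """
    path = Path(path)
    if format == "tsv":
        return _read_go_tsv(path)
    if format == "gaf":
        return _read_go_gaf(path)
    raise ValueError(f"unknown GO annotation format {format!r}; expected 'gaf' or 'tsv'")


def read_complex_list(path: str | Path, source: str | None = None) -> list[Complex]:
    """Read complexes, one per line, whitespace-separated member IDs.

    Empty lines are skipped with a warning; members are deduplicated within
    a line.
    """
    path = Path(path)
    complexes: list[Complex] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if line.startswith("#"):
                continue
            if not line:
                logger.warning("%s:%d: empty line skipped", path, lineno)
                continue
            complexes.append(Complex(members=frozenset(line.split()), source=source))
    return complexes


def write_complex_list(complexes: Iterable[Complex], path: str | Path) -> None:
    """Write complexes one per line, members sorted and space-separated."""
    path = Path(path)
    with path.open("w") as fh:
        for c in complexes:
            fh.write(" ".join(sorted(c.members)) + "\n")


PREDICTION_HEADER = ("complex_id", "size", "weighted_density", "source_relation", "members")


def write_prediction_table(candidates: Sequence, path: str | Path) -> None:
    """Write predicted complexes as TSV.

    Columns: complex_id, size, weighted_density (6 decimals),
    source_relation, members (semicolon-joined, sorted).  ``candidates`` are
    objects exposing ``members``, ``wd`` and ``relation`` (e.g.
    :class:`minecomplex.mining.CandidateComplex`).
    """
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join(PREDICTION_HEADER) + "\n")
        for i, c in enumerate(candidates, start=1):
            fh.write(
                f"C{i:04d}\t{len(c.members)}\t{c.wd:.6f}\t{c.relation}\t"
                + ";".join(sorted(c.members))
                + "\n"
            )


def read_prediction_table(path: str | Path) -> list[Complex]:
    """Read a prediction TSV written by :func:`write_prediction_table`."""
    path = Path(path)
    complexes: list[Complex] = []
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != PREDICTION_HEADER:
            raise ValueError(f"{path}: not a prediction table (unexpected header)")
        for lineno, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(PREDICTION_HEADER):
                raise ValueError(f"{path}:{lineno}: expected {len(PREDICTION_HEADER)} columns")
            complexes.append(
                Complex(
                    members=frozenset(fields[4].split(";")),
                    score=float(fields[2]),
                    source=fields[3],
                )
            )
    return complexes


def read_complexes_auto(path: str | Path, source: str | None = None) -> list[Complex]:
    """Read complexes from either the prediction TSV or the one-per-line format."""
    path = Path(path)
    with path.open() as fh:
        first = fh.readline().rstrip("\n").split("\t")
    if tuple(first) == PREDICTION_HEADER:
        return read_prediction_table(path)
    return read_complex_list(path, source=source)
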