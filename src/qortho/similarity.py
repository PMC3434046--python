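"""All-vs-all similarity results: parsing, quality filtering, symmetric store.

Similarity search hits arrive in the 12-column tabular format (query,
subject, percent identity, alignment length, mismatches, gap opens,
qstart, qend, sstart, send, e-value, bit score).  Hits are filtered on
alignment coverage and bit score, then folded into a symmetric
:class:`SimilarityStore` holding one score per unordered protein pair.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from .registry import ProteinRegistry

__all__ = [
    "Hit",
    "SimilarityStore",
    "parse_blast_tab",
    "quality_filter",
    "build_store",
    "DEFAULT_BIT_THRESHOLD",
    "DEFAULT_COVERAGE_THRESHOLD",
]

DEFAULT_BIT_THRESHOLD = 50.0
DEFAULT_COVERAGE_THRESHOLD = 0.5


@dataclass(frozen=True)
class Hit:
    """One directional alignment hit with coverage fractions."""

    query: str
    subject: str
    bit_score: float
    query_cover_fraction: float
    subject_cover_fraction: float


def _span_fraction(start: int, end: int, length: int) -> float:
    # inclusive coordinates; reversed (minus-frame) coordinates handled by |end-start|
    return (abs(end - start) + 1) / length


def parse_blast_tab(hit_source, registry: ProteinRegistry) -> list[Hit]:
    """Parse 12-column tabular hits, computing coverage from registry lengths.

    Raises ``ValueError`` with the offending line number on malformed rows
    and on rows referencing proteins absent from the registry.
    """
    if isinstance(hit_source, (str, Path)):
        fh = open(hit_source, "rt")
        close = True
    else:
        fh = hit_source
        close = False
    hits: list[Hit] = []
    try:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ValueError(f"hits line {lineno}: expected 12 columns, got {len(fields)}")
            qid, sid = fields[0], fields[1]
            if qid not in registry:
                raise ValueError(f"hits line {lineno}: unknown query id {qid!r}")
            if sid not in registry:
                raise ValueError(f"hits line {lineno}: unknown subject id {sid!r}")
            try:
                qstart, qend = int(fields[6]), int(fields[7])
                sstart, send = int(fields[8]), int(fields[9])
                bit = float(fields[11])
            except ValueError:
                raise ValueError(f"hits line {lineno}: non-numeric coordinate or score") from None
            if bit < 0:
                raise ValueError(f"hits line {lineno}: negative bit score {bit}")
            hits.append(
                Hit(
                    query=qid,
                    subject=sid,
                    bit_score=bit,
                    query_cover_fraction=_span_fraction(qstart, qend, registry[qid].length),
                    subject_cover_fraction=_span_fraction(sstart, send, registry[sid].length),
                )
            )
    finally:
        if close:
            fh.close()
    return hits


def quality_filter(
    hits: Iterable[Hit],
    bit_threshold: float = DEFAULT_BIT_THRESHOLD,
    coverage_threshold: float = DEFAULT_COVERAGE_THRESHOLD,
) -> list[Hit]:
    """Keep hits whose alignment covers at least the coverage threshold of
    *both* sequences and whose bit score strictly exceeds the bit threshold.

    Self-hits are always dropped.  The default thresholds (coverage 0.5,
    bit score > 50) apply corpus-wide, before best-hit ranking.
    """
    return [
        h
        for h in hits
        if h.query != h.subject
        and h.query_cover_fraction >= coverage_threshold
        and h.subject_cover_fraction >= coverage_threshold
        and h.bit_score > bit_threshold
    ]


@dataclass
class SimilarityStore:
    """Symmetric map of unordered protein pairs to a single similarity score.

    Absence of a pair means "no similarity recorded" — never an implicit
    zero.  Within-species pairs are retained (needed for inparalog
    detection); self-pairs are not representable.
    """

    registry: ProteinRegistry
    _scores: dict[tuple[str, str], float] = field(default_factory=dict)
    _neighbors: dict[str, dict[str, float]] = field(default_factory=dict)

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def put(self, a: str, b: str, score: float) -> None:
        if a == b:
            raise ValueError(f"self-pair not allowed: {a!r}")
        if score < 0:
            raise ValueError(f"negative similarity for pair ({a!r}, {b!r})")
        self._scores[self._key(a, b)] = score
        self._neighbors.setdefault(a, {})[b] = score
        self._neighbors.setdefault(b, {})[a] = score

    def get(self, a: str, b: str) -> float | None:
        return self._scores.get(self._key(a, b))

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return self._key(*pair) in self._scores

    def __len__(self) -> int:
        return len(self._scores)

    def pairs(self) -> Iterator[tuple[str, str, float]]:
        for (a, b) in sorted(self._scores):
            yield a, b, self._scores[(a, b)]

    def neighbors(self, protein_id: str) -> dict[str, float]:
        """All stored partners of a protein with their scores."""
        return self._neighbors.get(protein_id, {})

    def neighbors_in_species(self, protein_id: str, species: str) -> dict[str, float]:
        return {
            p: s
            for p, s in self._neighbors.get(protein_id, {}).items()
            if self.registry.species_of(p) == species
        }


def build_store(filtered_hits: Iterable[Hit], registry: ProteinRegistry) -> SimilarityStore:
    """Symmetrize filtered hits into a similarity store.

    Per direction, the best HSP (highest bit score) is kept; the pair score
    is the arithmetic mean of the directional scores present (a single
    direction contributes its value unchanged).
    """
    best_directional: dict[tuple[str, str], float] = {}
    for h in filtered_hits:
        key = (h.query, h.subject)
        if key not in best_directional or h.bit_score > best_directional[key]:
            best_directional[key] = h.bit_score
    store = SimilarityStore(registry)
    seen: set[tuple[str, str]] = set()
    for (q, s), score in best_directional.items():
        pair = (q, s) if q <= s else (s, q)
        if pair in seen:
            continue
        seen.add(pair)
        reverse = best_directional.get((s, q))
        store.put(q, s, score if reverse is None else (score + reverse) / 2.0)
    return store
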