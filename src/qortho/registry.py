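"""Protein registry: identifiers, species assignments, lengths, annotations.

The registry is the corpus-wide index every downstream stage resolves
identifiers against.  Proteins are registered from a FASTA file (lengths
taken from the sequences) or from a two-column lengths table, together
with a species-assignment table; functional annotations (gene symbol,
description, GO accessions) can be attached afterwards.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO

__all__ = [
    "Annotation",
    "Protein",
    "ProteinRegistry",
    "read_species_table",
    "read_lengths_table",
    "read_annotation_table",
    "read_fasta_registry",
    "registry_from_lengths",
]


@dataclass(frozen=True)
class Annotation:
    """Functional annotation facets attached to a protein."""

    gene_symbol: str | None = None
    description: str | None = None
    go_terms: frozenset[str] = frozenset()


@dataclass(frozen=True)
class Protein:
    """A protein with its species assignment and residue length."""

    id: str
    species: str
    length: int
    annotation: Annotation | None = None

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError(f"protein {self.id!r}: length must be >= 1, got {self.length}")


@dataclass
class ProteinRegistry:
    """Corpus-wide index of proteins, keyed by unique identifier."""

    _proteins: dict[str, Protein] = field(default_factory=dict)
    _by_species: dict[str, list[str]] = field(default_factory=dict)

    def add(self, protein: Protein) -> None:
        if protein.id in self._proteins:
            raise ValueError(f"duplicate protein id {protein.id!r}")
        self._proteins[protein.id] = protein
        self._by_species.setdefault(protein.species, []).append(protein.id)

    def __len__(self) -> int:
        return len(self._proteins)

    def __contains__(self, protein_id: str) -> bool:
        return protein_id in self._proteins

    def __getitem__(self, protein_id: str) -> Protein:
        try:
            return self._proteins[protein_id]
        except KeyError:
            raise KeyError(f"unknown protein id {protein_id!r}") from None

    def __iter__(self) -> Iterator[Protein]:
        # deterministic order by id
        for pid in sorted(self._proteins):
            yield self._proteins[pid]

    def species_of(self, protein_id: str) -> str:
        return self[protein_id].species

    def species(self) -> list[str]:
        return sorted(self._by_species)

    def proteins_of(self, species: str) -> list[str]:
        return sorted(self._by_species.get(species, []))

    def annotate(self, protein_id: str, annotation: Annotation) -> None:
        p = self[protein_id]
        self._proteins[protein_id] = Protein(p.id, p.species, p.length, annotation)


def _open_text(source) -> io.TextIOBase:
    if isinstance(source, (str, Path)):
        return open(source, "rt")
    return source


def read_species_table(source) -> dict[str, str]:
    """Read a two-column TSV mapping protein id -> species id."""
    mapping: dict[str, str] = {}
    with _open_text(source) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"species table line {lineno}: expected 2 columns, got {len(parts)}")
            pid, species = parts
            if pid in mapping:
                raise ValueError(f"species table line {lineno}: duplicate protein id {pid!r}")
            mapping[pid] = species
    return mapping


def read_lengths_table(source) -> dict[str, int]:
    """Read a two-column TSV mapping protein id -> sequence length."""
    lengths: dict[str, int] = {}
    with _open_text(source) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"lengths table line {lineno}: expected 2 columns, got {len(parts)}")
            pid, raw = parts
            if pid in lengths:
                raise ValueError(f"lengths table line {lineno}: duplicate protein id {pid!r}")
            try:
                lengths[pid] = int(raw)
            except ValueError:
                raise ValueError(f"lengths table line {lineno}: non-integer length {raw!r}") from None
    return lengths


def read_annotation_table(source) -> dict[str, Annotation]:
    """Read a TSV of protein_id, gene_symbol, description, go_accessions.

    GO accessions are semicolon-separated; empty fields mean the facet is
    absent for that protein.
    """
    annotations: dict[str, Annotation] = {}
    with _open_text(source) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(f"annotation table line {lineno}: expected 4 columns, got {len(parts)}")
            pid, symbol, desc, go_raw = parts
            go = frozenset(t for t in go_raw.split(";") if t)
            annotations[pid] = Annotation(symbol or None, desc or None, go)
    return annotations


def read_fasta_registry(fasta_source, species_table: dict[str, str]) -> ProteinRegistry:
    """Build a registry from a protein FASTA, lengths from the sequences.

    Every record id must be unique and present in ``species_table``.
    """
    lengths: dict[str, int] = {}
    with _open_text(fasta_source) as fh:
        for record in SeqIO.parse(fh, "fasta"):
            if record.id in lengths:
                raise ValueError(f"duplicate protein id {record.id!r} in FASTA")
            lengths[record.id] = len(record.seq)
    return registry_from_lengths(lengths, species_table)


def registry_from_lengths(lengths: dict[str, int], species_table: dict[str, str]) -> ProteinRegistry:
    """Build a registry from an id -> length mapping plus species assignments."""
    registry = ProteinRegistry()
    for pid in sorted(lengths):
        if pid not in species_table:
            raise ValueError(f"protein id {pid!r} missing from species table")
        registry.add(Protein(pid, species_table[pid], lengths[pid]))
    return registry


def attach_annotations(registry: ProteinRegistry, annotations: dict[str, Annotation]) -> None:
    """Attach annotations to registered proteins; unknown ids are ignored."""
    for pid, ann in annotations.items():
        if pid in registry:
            registry.annotate(pid, ann)
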