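"""Directional best hits and bidirectional best-hit (BBH) pairs.

A protein's best hit in a target species is the stored partner with the
highest similarity; ties are broken by lexicographically smallest id so
results are reproducible across runs and platforms.  A BBH pair is a
mutual best hit across two species and constitutes a putative ortholog.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

from .similarity import SimilarityStore

__all__ = ["PutativeOrtholog", "best_hit", "bbh_partner", "bbh_pairs", "all_bbh_pairs"]


@dataclass(frozen=True)
class PutativeOrtholog:
    """A BBH pair in canonical order (lexicographically smaller id first).

    ``alpha_max`` is the stored maximum quartet duplication score over all
    third-species witnesses; ``None`` means no witness yielded evidence.
    It is unset (``None``) until scoring runs.
    """

    x: str
    y: str
    s_xy: float
    alpha_max: float | None = None

    def __post_init__(self) -> None:
        if self.x >= self.y:
            raise ValueError("PutativeOrtholog ids must be in canonical (sorted) order")


def best_hit(store: SimilarityStore, protein_id: str, target_species: str) -> str | None:
    """Best stored partner of ``protein_id`` in ``target_species``, or None.

    Ties on similarity are broken by lexicographically smallest partner id.
    """
    if store.registry.species_of(protein_id) == target_species:
        raise ValueError(f"target species equals query species for {protein_id!r}")
    best: str | None = None
    best_score = -1.0
    for partner, score in store.neighbors(protein_id).items():
        if store.registry.species_of(partner) != target_species:
            continue
        if score > best_score or (score == best_score and (best is None or partner < best)):
            best, best_score = partner, score
    return best


def bbh_partner(store: SimilarityStore, protein_id: str, target_species: str) -> str | None:
    """Bidirectional best-hit partner of a protein in a target species, if any."""
    candidate = best_hit(store, protein_id, target_species)
    if candidate is None:
        return None
    own_species = store.registry.species_of(protein_id)
    if best_hit(store, candidate, own_species) == protein_id:
        return candidate
    return None


def bbh_pairs(store: SimilarityStore, species_a: str, species_b: str) -> set[PutativeOrtholog]:
    """All BBH pairs between two distinct species (alpha_max unset)."""
    if species_a == species_b:
        raise ValueError(f"need two distinct species, got {species_a!r} twice")
    pairs: set[PutativeOrtholog] = set()
    for pid in store.registry.proteins_of(species_a):
        partner = best_hit(store, pid, species_b)
        if partner is None:
            continue
        if best_hit(store, partner, species_a) == pid:
            x, y = (pid, partner) if pid < partner else (partner, pid)
            pairs.add(PutativeOrtholog(x, y, store.get(x, y)))
    return pairs


def all_bbh_pairs(store: SimilarityStore) -> list[PutativeOrtholog]:
    """BBH pairs over every species pair, sorted canonically."""
    out: set[PutativeOrtholog] = set()
    for sp_a, sp_b in combinations(store.registry.species(), 2):
        out |= bbh_pairs(store, sp_a, sp_b)
    return sorted(out, key=lambda p: (p.x, p.y))
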