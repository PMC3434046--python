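"""Quartet duplication scoring of putative ortholog pairs.

For a candidate ortholog pair (x, y) and a third species carrying genes
z1 (BBH partner of x) and z2 (BBH partner of y, z1 != z2), the quartet
score

    alpha = 1/2 * min(S_xz1, S_yz2) - 1/4 * (S_xz2 + S_yz1 + S_xy + S_z1z2)

estimates the evidence that a gene duplication separates x from y: the
larger alpha, the more the quartet's similarities look like two
duplication-separated clades {x, z1} and {y, z2}.  The maximum alpha over
all third species is stored per pair, and a pair is called an ortholog
when that maximum is at most a cutoff omega — or when no witness exists
anywhere, in which case orthology is assumed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Literal

from .bbh import PutativeOrtholog, bbh_partner
from .similarity import SimilarityStore

__all__ = [
    "DEFAULT_OMEGA",
    "QuartetWitness",
    "alpha",
    "witnesses",
    "max_alpha",
    "score_pairs",
    "call_orthologs",
]

DEFAULT_OMEGA = 20.0

MissingPolicy = Literal["skip", "impute_zero"]


@dataclass(frozen=True)
class QuartetWitness:
    """A third-species gene pair (z1, z2) with its quartet score."""

    z1: str
    z2: str
    alpha: float


def alpha(s_xz1: float, s_yz2: float, s_xz2: float, s_yz1: float, s_xy: float, s_z1z2: float) -> float:
    """Quartet duplication score from the six pairwise similarities."""
    return 0.5 * min(s_xz1, s_yz2) - 0.25 * (s_xz2 + s_yz1 + s_xy + s_z1z2)


def witnesses(
    x: str,
    y: str,
    third_species: str,
    store: SimilarityStore,
    missing_policy: MissingPolicy = "skip",
) -> list[QuartetWitness]:
    """Witness pair for (x, y) in a third species, if one exists.

    z1 is the BBH partner of x in the third species and z2 that of y.  No
    witness is produced when either partner is absent, when z1 == z2 (a
    single shared partner cannot reveal a duplication), or — under the
    default "skip" policy — when any of the six similarities is absent
    from the store.  Under "impute_zero", absent similarities among the
    cross terms count as 0.
    """
    reg = store.registry
    if third_species in (reg.species_of(x), reg.species_of(y)):
        raise ValueError(f"third species {third_species!r} must differ from the pair's species")
    z1 = bbh_partner(store, x, third_species)
    z2 = bbh_partner(store, y, third_species)
    if z1 is None or z2 is None or z1 == z2:
        return []
    s_xz1 = store.get(x, z1)
    s_yz2 = store.get(y, z2)
    needed = {
        "s_xz2": store.get(x, z2),
        "s_yz1": store.get(y, z1),
        "s_xy": store.get(x, y),
        "s_z1z2": store.get(z1, z2),
    }
    if s_xz1 is None or s_yz2 is None:
        return []  # cannot happen for true BBH partners, but absence never imputes
    if any(v is None for v in needed.values()):
        if missing_policy == "skip":
            return []
        needed = {k: (0.0 if v is None else v) for k, v in needed.items()}
    a = alpha(s_xz1, s_yz2, needed["s_xz2"], needed["s_yz1"], needed["s_xy"], needed["s_z1z2"])
    return [QuartetWitness(z1, z2, a)]


def max_alpha(
    x: str,
    y: str,
    store: SimilarityStore,
    missing_policy: MissingPolicy = "skip",
) -> float | None:
    """Maximum quartet score over witnesses from every third species.

    Returns ``None`` (no evidence) when no species yields a witness.
    """
    reg = store.registry
    pair_species = {reg.species_of(x), reg.species_of(y)}
    best: float | None = None
    for species in reg.species():
        if species in pair_species:
            continue
        for w in witnesses(x, y, species, store, missing_policy):
            if best is None or w.alpha > best:
                best = w.alpha
    return best


def score_pairs(
    pairs: Iterable[PutativeOrtholog],
    store: SimilarityStore,
    missing_policy: MissingPolicy = "skip",
) -> list[PutativeOrtholog]:
    """Populate alpha_max on every putative ortholog pair."""
    return [replace(p, alpha_max=max_alpha(p.x, p.y, store, missing_policy)) for p in pairs]


def call_orthologs(pairs: Iterable[PutativeOrtholog], omega: float = DEFAULT_OMEGA) -> list[PutativeOrtholog]:
    """Pairs called orthologs at cutoff omega.

    A pair is an ortholog when its stored maximum alpha is <= omega
    (inclusive), or when no duplication evidence exists at all.
    """
    return [p for p in pairs if p.alpha_max is None or p.alpha_max <= omega]
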