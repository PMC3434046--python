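"""Within-species inparalog groups and co-ortholog expansion.

An inparalog group is a set of >= 2 same-species proteins whose every
internal pairwise similarity exceeds the similarity between any member
and any protein of any other species.  Such sets arise from gene
duplications more recent than the species' last speciation, so the whole
set is co-orthologous to each member's orthologs in other species.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable

import networkx as nx

from .bbh import PutativeOrtholog
from .similarity import SimilarityStore

__all__ = ["InparalogGroup", "external_ceiling", "inparalog_groups", "co_ortholog_expansion"]


@dataclass(frozen=True)
class InparalogGroup:
    """A within-species set whose internal similarity beats all external."""

    species: str
    members: tuple[str, ...]
    min_internal: float
    max_external: float


def external_ceiling(protein_id: str, store: SimilarityStore) -> float:
    """Highest similarity between a protein and any protein of another
    species; 0 when no cross-species pair is stored."""
    own = store.registry.species_of(protein_id)
    best = 0.0
    for partner, score in store.neighbors(protein_id).items():
        if store.registry.species_of(partner) != own and score > best:
            best = score
    return best


def _set_condition(members: list[str], store: SimilarityStore, ceilings: dict[str, float]) -> tuple[bool, float, float]:
    """Check min internal pairwise S > max member external ceiling.

    A missing internal pair counts as similarity 0: a set cannot claim
    internal cohesion on absent evidence.
    """
    min_internal = float("inf")
    for a, b in combinations(members, 2):
        s = store.get(a, b)
        min_internal = min(min_internal, 0.0 if s is None else s)
    max_external = max(ceilings[m] for m in members)
    return min_internal > max_external, min_internal, max_external


def inparalog_groups(species: str, store: SimilarityStore) -> list[InparalogGroup]:
    """Detect inparalog groups of a species.

    Construction: within-species edges (a, b) are kept when the stored
    (quality-filtered) similarity S(a, b) exceeds both members' external
    ceilings; connected components of size >= 2 are then verified against
    the set-level condition (minimum internal pairwise similarity, missing
    pairs counting as 0, strictly above every member's external ceiling).
    A failing component is split by removing its weakest internal edge and
    re-tested, until all surviving components qualify.
    """
    proteins = store.registry.proteins_of(species)
    ceilings = {p: external_ceiling(p, store) for p in proteins}

    g = nx.Graph()
    g.add_nodes_from(proteins)
    for a in proteins:
        for b, s in store.neighbors(a).items():
            if a < b and store.registry.species_of(b) == species:
                if s > ceilings[a] and s > ceilings[b]:
                    g.add_edge(a, b, weight=s)

    groups: list[InparalogGroup] = []
    # deterministic worklist: components ordered by smallest member id
    work = sorted((sorted(c) for c in nx.connected_components(g) if len(c) >= 2), key=lambda c: c[0])
    while work:
        members = work.pop(0)
        ok, min_internal, max_external = _set_condition(members, store, ceilings)
        if ok:
            groups.append(InparalogGroup(species, tuple(members), min_internal, max_external))
            continue
        sub = g.subgraph(members)
        # weakest edge; ties broken by smallest (a, b) id pair
        weakest = min(sub.edges(data="weight"), key=lambda e: (e[2], min(e[0], e[1]), max(e[0], e[1])))
        g.remove_edge(weakest[0], weakest[1])
        pieces = sorted(
            (sorted(c) for c in nx.connected_components(g.subgraph(members)) if len(c) >= 2),
            key=lambda c: c[0],
        )
        work = pieces + work
        work.sort(key=lambda c: c[0])
    return sorted(groups, key=lambda grp: grp.members)


def co_ortholog_expansion(
    called_pairs: Iterable[PutativeOrtholog],
    groups_by_species: dict[str, list[InparalogGroup]],
    registry,
) -> dict[tuple[str, str], tuple[tuple[str, ...], tuple[str, ...]]]:
    """Expand each called ortholog pair (x, y) to its co-ortholog sets
    {x plus inparalogs of x} x {y plus inparalogs of y}."""
    member_index: dict[str, tuple[str, ...]] = {}
    for species_groups in groups_by_species.values():
        for grp in species_groups:
            for m in grp.members:
                member_index[m] = grp.members
    out: dict[tuple[str, str], tuple[tuple[str, ...], tuple[str, ...]]] = {}
    for p in called_pairs:
        set_x = member_index.get(p.x, (p.x,))
        set_y = member_index.get(p.y, (p.y,))
        out[(p.x, p.y)] = (tuple(sorted(set(set_x) | {p.x})), tuple(sorted(set(set_y) | {p.y})))
    return out
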