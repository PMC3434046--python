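"""Orthologous groups: graph construction, group formation, consensus annotation.

Called ortholog pairs form a weighted undirected graph (edge weight =
pair similarity) which is partitioned by Markov clustering; clusters
spanning at least three distinct species become orthologous groups.
Group-level annotation adopts, facet by facet, any value shared by more
than 80% of the group's members.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx

from .bbh import PutativeOrtholog
from .registry import Annotation, ProteinRegistry

__all__ = [
    "OrthologousGroup",
    "ortholog_graph",
    "form_groups",
    "annotate_group",
    "conservation_curve",
    "MIN_GROUP_SPECIES",
    "CONSENSUS_FRACTION",
]

MIN_GROUP_SPECIES = 3
CONSENSUS_FRACTION = 0.8  # facet adopted when shared by MORE than this fraction


@dataclass
class OrthologousGroup:
    """An MCL cluster of mutually orthologous proteins from >= 3 species."""

    group_id: str
    members: list[str]
    species: list[str]
    consensus: Annotation | None = None

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def species_count(self) -> int:
        return len(self.species)


def ortholog_graph(called_pairs: Iterable[PutativeOrtholog], registry: ProteinRegistry) -> nx.Graph:
    """Weighted graph over called ortholog pairs (weight = similarity)."""
    g = nx.Graph()
    for p in called_pairs:
        if registry.species_of(p.x) == registry.species_of(p.y):
            raise ValueError(f"ortholog edge within one species: ({p.x!r}, {p.y!r})")
        if p.s_xy <= 0:
            raise ValueError(f"non-positive edge weight for ({p.x!r}, {p.y!r})")
        g.add_edge(p.x, p.y, weight=p.s_xy)
    return g


def form_groups(partition: Iterable[Sequence[str]], registry: ProteinRegistry) -> list[OrthologousGroup]:
    """Clusters spanning >= 3 species become groups with sequential QTS_ ids.

    Ids are assigned by decreasing group size, ties broken by smallest
    member id, so output is stable across runs.  Clusters on <= 2 species
    are dropped here (their pairwise orthologs remain in the pairwise table).
    """
    eligible = []
    for cluster in partition:
        members = sorted(cluster)
        species = sorted({registry.species_of(m) for m in members})
        if len(species) >= MIN_GROUP_SPECIES:
            eligible.append((members, species))
    eligible.sort(key=lambda ms: (-len(ms[0]), ms[0][0]))
    return [
        OrthologousGroup(f"QTS_{i}", members, species)
        for i, (members, species) in enumerate(eligible, 1)
    ]


def annotate_group(
    group: OrthologousGroup,
    registry: ProteinRegistry,
    consensus_fraction: float = CONSENSUS_FRACTION,
    annotated_only_denominator: bool = False,
) -> Annotation | None:
    """Consensus annotation for a group, facet by facet.

    A facet value (gene symbol, description, or an individual GO
    accession) is adopted when strictly more than ``consensus_fraction``
    of the group's members carry it.  By default members lacking the
    facet still count in the denominator; ``annotated_only_denominator``
    restricts the denominator to members annotated for that facet.
    """
    annotations = [registry[m].annotation for m in group.members]
    n_all = len(group.members)

    def consensus_value(values: list[str]) -> str | None:
        if not values:
            return None
        denom = len(values) if annotated_only_denominator else n_all
        value, count = Counter(values).most_common(1)[0]
        return value if count / denom > consensus_fraction else None

    symbol = consensus_value([a.gene_symbol for a in annotations if a and a.gene_symbol])
    desc = consensus_value([a.description for a in annotations if a and a.description])

    go_counts: Counter[str] = Counter()
    n_with_go = 0
    for a in annotations:
        if a and a.go_terms:
            n_with_go += 1
            go_counts.update(a.go_terms)
    go_denom = n_with_go if annotated_only_denominator else n_all
    go = frozenset(t for t, c in go_counts.items() if go_denom and c / go_denom > consensus_fraction)

    if symbol is None and desc is None and not go:
        return None
    consensus = Annotation(symbol, desc, go)
    group.consensus = consensus
    return consensus


def conservation_curve(groups: Iterable[OrthologousGroup], species_list: Sequence[str]) -> list[int]:
    """Number of groups containing orthologs in at least n of the listed
    species, for n = 1..len(species_list).  Non-increasing in n."""
    if not species_list:
        raise ValueError("species_list must be non-empty")
    wanted = set(species_list)
    overlaps = [len(wanted & set(g.species)) for g in groups]
    return [sum(1 for o in overlaps if o >= n) for n in range(1, len(species_list) + 1)]
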