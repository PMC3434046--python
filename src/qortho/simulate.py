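"""Gene-family evolution simulator with ground-truth orthology labels.

Gene families are evolved by a duplication/loss branching process down a
random ultrametric species tree.  Every internal node of the resulting
gene tree is labeled as a speciation or a duplication, so the true
relationship of any gene pair follows from its last common ancestor:
speciation => ortholog, duplication => paralog.  True inparalog sets are
the clades under duplications that occurred on a terminal branch of the
species tree, i.e. after the species' last speciation.

Similarity scores are simulated directly from gene-tree path distances
via a noisy exponential decay, standing in for bit scores of an
all-vs-all search; pairs falling below the quality floor are omitted
from the store, mimicking hits the search would not report.  Because the
species tree is clock-like, similarity ranks mirror divergence times,
which makes the truth labels exactly recoverable in the noise-free limit.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np

from .registry import Protein, ProteinRegistry
from .similarity import DEFAULT_BIT_THRESHOLD, SimilarityStore

__all__ = [
    "SpeciesNode",
    "SpeciesTree",
    "GeneNode",
    "SimulatedFamily",
    "TruthLabels",
    "SimulatedCorpus",
    "BenchmarkResult",
    "simulate_species_tree",
    "simulate_family",
    "simulate_corpus",
    "benchmark",
    "write_corpus",
]

# defaults emulate a prokaryote-scale protein corpus: bit scores of a few
# hundred between close relatives, decaying below the bit-score-50 floor
# for the most divergent pairs
DEFAULT_S0 = 500.0
DEFAULT_DECAY = 2.0
DEFAULT_NOISE_SD = 10.0
DEFAULT_DUP_RATE = 0.3
DEFAULT_LOSS_RATE = 0.1
DEFAULT_HEIGHT_SCALE = 0.4


@dataclass
class SpeciesNode:
    name: str
    time: float  # height above the present; leaves are at 0
    children: list["SpeciesNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class SpeciesTree:
    root: SpeciesNode

    def leaves(self) -> list[str]:
        out: list[str] = []

        def walk(v: SpeciesNode) -> None:
            if v.is_leaf:
                out.append(v.name)
            for c in v.children:
                walk(c)

        walk(self.root)
        return sorted(out)

    def newick(self) -> str:
        def fmt(v: SpeciesNode, parent_time: float | None) -> str:
            body = v.name if v.is_leaf else "(" + ",".join(fmt(c, v.time) for c in v.children) + ")" + v.name
            if parent_time is None:
                return body
            return f"{body}:{parent_time - v.time:.6f}"

        return fmt(self.root, None) + ";"


def simulate_species_tree(
    n_species: int,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    height_scale: float = DEFAULT_HEIGHT_SCALE,
) -> SpeciesTree:
    """Random ultrametric species tree via pairwise merges with exponential
    waiting times (coalescent-style); deterministic under seed."""
    if n_species < 2:
        raise ValueError(f"need at least 2 species, got {n_species}")
    if rng is None:
        rng = np.random.default_rng(seed)
    nodes: list[SpeciesNode] = [SpeciesNode(f"sp{i:02d}", 0.0) for i in range(1, n_species + 1)]
    t = 0.0
    anc = 0
    while len(nodes) > 1:
        k = len(nodes)
        t += rng.exponential(height_scale * 2.0 / (k * (k - 1)))
        i, j = sorted(int(v) for v in rng.choice(k, size=2, replace=False))
        anc += 1
        parent = SpeciesNode(f"anc{anc:02d}", t, [nodes[i], nodes[j]])
        del nodes[j], nodes[i]
        nodes.append(parent)
    return SpeciesTree(nodes[0])


@dataclass
class GeneNode:
    event: str  # "leaf" | "speciation" | "duplication"
    time: float
    species: str  # leaf/speciation: species-tree node; duplication: species-tree edge (child node) it occurred on
    children: list["GeneNode"] = field(default_factory=list)
    name: str | None = None

    @property
    def is_leaf(self) -> bool:
        return self.event == "leaf"


@dataclass
class SimulatedFamily:
    """One gene family: event-labeled gene tree plus derived truth."""

    family_id: str
    root: GeneNode | None
    leaves: list[GeneNode] = field(default_factory=list)
    # unordered leaf-name pair -> ("ortholog" | "paralog", gene-tree path distance)
    pair_info: dict[tuple[str, str], tuple[str, float]] = field(default_factory=dict)
    inparalog_sets: list[tuple[str, tuple[str, ...]]] = field(default_factory=list)

    def newick(self) -> str:
        if self.root is None:
            return ";"

        def fmt(v: GeneNode, parent_time: float | None) -> str:
            if v.is_leaf:
                body = v.name or ""
            else:
                label = "D" if v.event == "duplication" else "S"
                body = "(" + ",".join(fmt(c, v.time) for c in v.children) + ")" + label
            return body if parent_time is None else f"{body}:{parent_time - v.time:.6f}"

        return fmt(self.root, None) + ";"


def simulate_family(
    species_tree: SpeciesTree,
    dup_rate: float = DEFAULT_DUP_RATE,
    loss_rate: float = DEFAULT_LOSS_RATE,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    family_id: str = "F000",
) -> SimulatedFamily:
    """Evolve one gene family down the species tree.

    A single gene enters at the root; along each species-tree branch it
    duplicates (copying the lineage in place) at ``dup_rate`` and is lost
    at ``loss_rate`` per unit time.  Lost lineages are pruned and unary
    nodes suppressed, so surviving internal nodes are strictly binary.
    """
    if dup_rate < 0 or loss_rate < 0:
        raise ValueError("rates must be non-negative")
    if rng is None:
        rng = np.random.default_rng(seed)
    total_rate = dup_rate + loss_rate

    def at_node(v: SpeciesNode) -> GeneNode | None:
        if v.is_leaf:
            return GeneNode("leaf", 0.0, v.name)
        kids = [k for k in (evolve_to(c, v.time) for c in v.children) if k is not None]
        if not kids:
            return None
        if len(kids) == 1:
            return kids[0]
        return GeneNode("speciation", v.time, v.name, kids)

    def evolve_to(v: SpeciesNode, t_start: float) -> GeneNode | None:
        t = t_start
        while True:
            if total_rate <= 0:
                return at_node(v)
            dt = rng.exponential(1.0 / total_rate)
            if t - dt <= v.time:
                return at_node(v)
            t -= dt
            if rng.random() < dup_rate / total_rate:
                kids = [k for k in (evolve_to(v, t), evolve_to(v, t)) if k is not None]
                if not kids:
                    return None
                if len(kids) == 1:
                    return kids[0]
                return GeneNode("duplication", t, v.name, kids)
            return None  # loss

    root = at_node(species_tree.root)
    family = SimulatedFamily(family_id, root)
    if root is None:
        return family

    # deterministic leaf naming: preorder, per-species counters
    counters: dict[str, int] = {}
    leaves: list[GeneNode] = []

    def name_leaves(v: GeneNode) -> None:
        if v.is_leaf:
            counters[v.species] = counters.get(v.species, 0) + 1
            v.name = f"{v.species}_{family_id}_{counters[v.species]:02d}"
            leaves.append(v)
            return
        for c in v.children:
            name_leaves(c)

    name_leaves(root)
    family.leaves = leaves

    def collect(v: GeneNode) -> list[GeneNode]:
        if v.is_leaf:
            return [v]
        below = [collect(c) for c in v.children]
        label = "paralog" if v.event == "duplication" else "ortholog"
        for la, lb in combinations(below, 2):
            for a in la:
                for b in lb:
                    key = (a.name, b.name) if a.name < b.name else (b.name, a.name)
                    family.pair_info[key] = (label, 2.0 * v.time)
        return [leaf for sub in below for leaf in sub]

    collect(root)

    # true inparalog sets: maximal duplication clades whose surviving leaves
    # all belong to one species.  In the loss-pruned gene tree such a
    # duplication is necessarily more recent than every speciation that
    # separates the clade from surviving genes of other species (ancestors
    # are older than descendants), which is the defining property of
    # inparalogy; duplications on the species' terminal branch are the
    # loss-free special case.
    def find_inparalogs(v: GeneNode) -> None:
        if v.is_leaf:
            return
        if v.event == "duplication":
            below = _leaves_below(v)
            species_below = {leaf.species for leaf in below}
            if len(species_below) == 1:
                members = tuple(sorted(leaf.name for leaf in below))
                family.inparalog_sets.append((species_below.pop(), members))
                return  # maximal clade: do not descend
        for c in v.children:
            find_inparalogs(c)

    find_inparalogs(root)
    return family


def _leaves_below(v: GeneNode) -> list[GeneNode]:
    if v.is_leaf:
        return [v]
    return [leaf for c in v.children for leaf in _leaves_below(c)]


@dataclass
class TruthLabels:
    """Corpus-level ground truth aggregated over families."""

    orthologs: set[tuple[str, str]] = field(default_factory=set)
    paralogs: set[tuple[str, str]] = field(default_factory=set)
    inparalog_groups: dict[str, list[tuple[str, ...]]] = field(default_factory=dict)

    def label(self, a: str, b: str) -> str | None:
        key = (a, b) if a < b else (b, a)
        if key in self.orthologs:
            return "ortholog"
        if key in self.paralogs:
            return "paralog"
        return None


@dataclass
class SimulatedCorpus:
    species_tree: SpeciesTree
    families: list[SimulatedFamily]
    registry: ProteinRegistry
    store: SimilarityStore
    truth: TruthLabels
    seed: int | None
    params: dict


def simulate_corpus(
    n_species: int = 8,
    n_families: int = 30,
    dup_rate: float = DEFAULT_DUP_RATE,
    loss_rate: float = DEFAULT_LOSS_RATE,
    noise_sd: float = DEFAULT_NOISE_SD,
    s0: float = DEFAULT_S0,
    decay: float = DEFAULT_DECAY,
    min_score: float = DEFAULT_BIT_THRESHOLD,
    seed: int | None = 0,
    species_tree: SpeciesTree | None = None,
) -> SimulatedCorpus:
    """Simulate a corpus of gene families with similarities and truth labels.

    ``S(i, j) = max(0, s0 * exp(-decay * d_ij) + Normal(0, noise_sd))``
    where ``d_ij`` is the gene-tree path length; pairs at or below
    ``min_score`` are omitted from the store (the search would not have
    reported them as qualifying hits).  All randomness flows from one
    seeded generator.
    """
    rng = np.random.default_rng(seed)
    tree = species_tree if species_tree is not None else simulate_species_tree(n_species, rng=rng)

    families = []
    for i in range(n_families):
        fam = simulate_family(tree, dup_rate, loss_rate, rng=rng, family_id=f"F{i:03d}")
        if fam.root is not None:
            families.append(fam)

    registry = ProteinRegistry()
    for fam in families:
        for leaf in sorted(fam.leaves, key=lambda l: l.name):
            registry.add(Protein(leaf.name, leaf.species, int(rng.integers(200, 601))))

    store = SimilarityStore(registry)
    truth = TruthLabels()
    for fam in families:
        for (a, b) in sorted(fam.pair_info):
            label, d = fam.pair_info[(a, b)]
            s = s0 * math.exp(-decay * d)
            if noise_sd > 0:
                s += rng.normal(0.0, noise_sd)
            if s > min_score:
                store.put(a, b, s)
            if label == "ortholog":
                truth.orthologs.add((a, b))
            else:
                truth.paralogs.add((a, b))
        for species, members in fam.inparalog_sets:
            truth.inparalog_groups.setdefault(species, []).append(members)

    params = dict(
        n_species=n_species,
        n_families=n_families,
        dup_rate=dup_rate,
        loss_rate=loss_rate,
        noise_sd=noise_sd,
        s0=s0,
        decay=decay,
        min_score=min_score,
    )
    return SimulatedCorpus(tree, families, registry, store, truth, seed, params)


@dataclass
class BenchmarkResult:
    precision: float | None
    recall: float | None
    false_positive_rate: float | None
    tp: int
    fp: int
    fn: int
    tn: int


def benchmark(
    predicted: set[tuple[str, str]],
    truth: TruthLabels,
    universe: set[tuple[str, str]],
) -> BenchmarkResult:
    """Confusion-matrix ratios over the candidate universe.

    ``universe`` is the set of truth-labeled cross-species pairs the
    pipeline actually considered (its BBH pairs); positives are the
    universe's true orthologs, negatives its true paralogs.  Ratios with a
    zero denominator are reported as ``None``.
    """
    if predicted and universe:
        genes_pred = {g for p in predicted for g in p}
        genes_univ = {g for p in universe for g in p}
        if not genes_pred & genes_univ:
            raise ValueError("prediction and truth universes are disjoint")
    positives = {p for p in universe if truth.label(*p) == "ortholog"}
    negatives = {p for p in universe if truth.label(*p) == "paralog"}
    predicted = predicted & (positives | negatives)
    tp = len(predicted & positives)
    fp = len(predicted & negatives)
    fn = len(positives) - tp
    tn = len(negatives) - fp
    precision = tp / (tp + fp) if (tp + fp) else None
    recall = tp / len(positives) if positives else None
    fpr = fp / len(negatives) if negatives else None
    return BenchmarkResult(precision, recall, fpr, tp, fp, fn, tn)


def write_corpus(corpus: SimulatedCorpus, outdir) -> None:
    """Emit the corpus in the same plain-text formats the pipeline consumes.

    species.tsv, lengths.tsv, hits.tsv (12-column tabular, both
    directions per stored pair, full-length alignments), truth_pairs.tsv,
    truth_inparalogs.tsv, species_tree.nwk, gene_trees.nwk, meta.json.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    reg = corpus.registry

    with open(outdir / "species.tsv", "wt") as fh:
        for p in reg:
            fh.write(f"{p.id}\t{p.species}\n")
    with open(outdir / "lengths.tsv", "wt") as fh:
        for p in reg:
            fh.write(f"{p.id}\t{p.length}\n")

    s0 = corpus.params["s0"]
    with open(outdir / "hits.tsv", "wt") as fh:
        for a, b, s in corpus.store.pairs():
            pident = round(min(99.9, 100.0 * s / s0), 1)
            for q, t in ((a, b), (b, a)):
                ql, tl = reg[q].length, reg[t].length
                fh.write(
                    f"{q}\t{t}\t{pident}\t{ql}\t0\t0\t1\t{ql}\t1\t{tl}\t1e-10\t{s:.3f}\n"
                )

    with open(outdir / "truth_pairs.tsv", "wt") as fh:
        for pair in sorted(corpus.truth.orthologs | corpus.truth.paralogs):
            fh.write(f"{pair[0]}\t{pair[1]}\t{corpus.truth.label(*pair)}\n")
    with open(outdir / "truth_inparalogs.tsv", "wt") as fh:
        for species in sorted(corpus.truth.inparalog_groups):
            for i, members in enumerate(sorted(corpus.truth.inparalog_groups[species]), 1):
                fh.write(f"{species}\t{i}\t{';'.join(members)}\n")

    (outdir / "species_tree.nwk").write_text(corpus.species_tree.newick() + "\n")
    with open(outdir / "gene_trees.nwk", "wt") as fh:
        for fam in corpus.families:
            fh.write(fam.newick() + "\n")
    (outdir / "meta.json").write_text(
        json.dumps({"seed": corpus.seed, "params": corpus.params}, indent=2, sort_keys=True) + "\n"
    )
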