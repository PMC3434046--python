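import math
from itertools import combinations

import numpy as np
import pytest

from qortho.quartet import max_alpha
from qortho.bbh import all_bbh_pairs
from qortho.simulate import (
    TruthLabels,
    benchmark,
    simulate_corpus,
    simulate_family,
    simulate_species_tree,
)


class TestSpeciesTree:
    def test_two_species_is_a_cherry(self):
        tree = simulate_species_tree(2, seed=0)
        assert tree.leaves() == ["sp01", "sp02"]
        assert len(tree.root.children) == 2

    def test_internal_node_count(self):
        tree = simulate_species_tree(8, seed=3)

        def count_internal(v):
            return 0 if v.is_leaf else 1 + sum(count_internal(c) for c in v.children)

        assert count_internal(tree.root) == 7

    def test_deterministic_under_seed(self):
        assert simulate_species_tree(6, seed=5).newick() == simulate_species_tree(6, seed=5).newick()

    def test_ultrametric(self):
        tree = simulate_species_tree(8, seed=1)

        def depths(v, acc):
            if v.is_leaf:
                yield acc
            for c in v.children:
                yield from depths(c, acc + (v.time - c.time))

        d = list(depths(tree.root, 0.0))
        assert max(d) - min(d) < 1e-12

    def test_too_few_species_rejected(self):
        with pytest.raises(ValueError):
            simulate_species_tree(1)


def _lca_oracle(family):
    """Independent LCA walk: label every leaf pair from scratch via parent maps."""
    parent = {}

    def walk(v):
        for c in v.children:
            parent[id(c)] = v
            walk(c)

    walk(family.root)

    def path_to_root(leaf):
        path = [leaf]
        while id(path[-1]) in parent:
            path.append(parent[id(path[-1])])
        return path

    labels = {}
    leaves = family.leaves
    for a, b in combinations(leaves, 2):
        pa = path_to_root(a)
        ancestors_b = {id(n) for n in path_to_root(b)}
        lca = next(n for n in pa if id(n) in ancestors_b)
        key = (a.name, b.name) if a.name < b.name else (b.name, a.name)
        labels[key] = ("paralog" if lca.event == "duplication" else "ortholog", 2.0 * lca.time)
    return labels


class TestFamilySimulation:
    def test_no_duplication_one_gene_per_species_all_orthologs(self):
        tree = simulate_species_tree(6, seed=2)
        fam = simulate_family(tree, dup_rate=0.0, loss_rate=0.0, seed=7)
        species = [leaf.species for leaf in fam.leaves]
        assert sorted(species) == tree.leaves()
        assert all(label == "ortholog" for label, _ in fam.pair_info.values())
        assert fam.inparalog_sets == []

    def test_labels_match_independent_lca_oracle(self):
        tree = simulate_species_tree(6, seed=4)
        rng = np.random.default_rng(10)
        for _ in range(20):
            fam = simulate_family(tree, dup_rate=0.7, loss_rate=0.2, rng=rng)
            if fam.root is None or len(fam.leaves) < 2:
                continue
            assert fam.pair_info == _lca_oracle(fam)

    def test_inparalog_truth_sets_are_single_species(self):
        tree = simulate_species_tree(5, seed=8)
        rng = np.random.default_rng(3)
        for _ in range(20):
            fam = simulate_family(tree, dup_rate=1.2, loss_rate=0.2, rng=rng)
            for species, members in fam.inparalog_sets:
                assert len(members) >= 2
                assert all(m.startswith(species) for m in members)

    def test_newick_round_trips_through_dendropy(self):
        import dendropy

        tree = simulate_species_tree(5, seed=0)
        fam = simulate_family(tree, dup_rate=0.5, loss_rate=0.1, seed=1)
        parsed = dendropy.Tree.get(data=fam.newick(), schema="newick")
        assert sorted(l.taxon.label for l in parsed.leaf_node_iter()) == sorted(
            l.name.replace("_", " ") for l in fam.leaves
        )


class TestCorpus:
    def test_similarity_strictly_decreasing_in_distance_without_noise(self):
        corpus = simulate_corpus(n_species=6, n_families=5, noise_sd=0.0, seed=6)
        by_pair = {}
        for fam in corpus.families:
            by_pair.update(fam.pair_info)
        recorded = [
            (d, corpus.store.get(a, b))
            for (a, b), (_, d) in by_pair.items()
            if corpus.store.get(a, b) is not None
        ]
        recorded.sort()
        for (d1, s1), (d2, s2) in zip(recorded, recorded[1:]):
            if d2 > d1:
                assert s2 < s1

    def test_same_seed_bit_identical(self):
        c1 = simulate_corpus(seed=9)
        c2 = simulate_corpus(seed=9)
        assert dict(c1.store._scores) == dict(c2.store._scores)
        assert c1.species_tree.newick() == c2.species_tree.newick()
        assert [f.newick() for f in c1.families] == [f.newick() for f in c2.families]

    def test_scores_follow_exponential_decay(self):
        corpus = simulate_corpus(n_species=4, n_families=3, noise_sd=0.0, seed=12)
        s0, decay = corpus.params["s0"], corpus.params["decay"]
        for fam in corpus.families:
            for (a, b), (_, d) in fam.pair_info.items():
                s = corpus.store.get(a, b)
                expected = s0 * math.exp(-decay * d)
                if expected > corpus.params["min_score"]:
                    assert s == pytest.approx(expected)
                else:
                    assert s is None

    def test_duplication_free_corpus_has_no_paralogs_and_no_witnesses(self):
        corpus = simulate_corpus(n_species=6, n_families=10, dup_rate=0.0, seed=13)
        assert corpus.truth.paralogs == set()
        for p in all_bbh_pairs(corpus.store):
            assert max_alpha(p.x, p.y, corpus.store) is None


class TestBenchmark:
    def test_perfect_predictions(self):
        truth = TruthLabels(orthologs={("a", "b"), ("c", "d")})
        universe = {("a", "b"), ("c", "d")}
        r = benchmark(universe, truth, universe)
        assert r.precision == 1.0 and r.recall == 1.0

    def test_empty_predictions(self):
        truth = TruthLabels(orthologs={("a", "b")})
        r = benchmark(set(), truth, {("a", "b")})
        assert r.recall == 0.0 and r.precision is None

    def test_hand_built_confusion_counts(self):
        truth = TruthLabels(
            orthologs={("a", "b"), ("c", "d"), ("e", "f"), ("g", "h")},
            paralogs={("i", "j"), ("k", "l")},
        )
        universe = truth.orthologs | truth.paralogs
        predicted = {("a", "b"), ("c", "d"), ("e", "f"), ("i", "j")}  # TP=3, FP=1, FN=1
        r = benchmark(predicted, truth, universe)
        assert r.precision == pytest.approx(0.75)
        assert r.recall == pytest.approx(0.75)
        assert (r.tp, r.fp, r.fn, r.tn) == (3, 1, 1, 1)

    def test_disjoint_universes_rejected(self):
        truth = TruthLabels(orthologs={("a", "b")})
        with pytest.raises(ValueError):
            benchmark({("x", "y")}, truth, {("a", "b")})
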