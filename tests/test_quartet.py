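import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qortho.bbh import PutativeOrtholog, all_bbh_pairs
from qortho.quartet import alpha, call_orthologs, max_alpha, score_pairs, witnesses

from conftest import toy_registry, toy_store

scores = st.floats(min_value=0, max_value=1e6, allow_nan=False)


class TestAlpha:
    @pytest.mark.parametrize("s", [0.0, 1.0, 50.0, 100.0, 1e6])
    def test_equal_similarity_closed_form(self, s):
        assert alpha(s, s, s, s, s, s) == -s / 2

    def test_pure_duplication_signal(self):
        assert alpha(100, 100, 0, 0, 0, 0) == 50.0

    def test_hand_evaluated_example(self):
        # 1/2*min(200,300) - 1/4*(80+80+120+90) = 100 - 92.5
        assert alpha(200, 300, 80, 80, 120, 90) == pytest.approx(7.5)

    @given(scores, scores, scores, scores, scores, scores)
    @settings(derandomize=True, max_examples=200)
    def test_exchange_symmetry(self, a, b, c, d, e, f):
        # simultaneous swap x<->y, z1<->z2: (s_xz1,s_yz2)->(s_yz2,s_xz1), (s_xz2,s_yz1)->(s_yz1,s_xz2)
        assert alpha(a, b, c, d, e, f) == alpha(b, a, d, c, e, f)

    @given(scores, scores, scores, scores, scores, scores, st.floats(min_value=1e-3, max_value=1e3))
    @settings(derandomize=True, max_examples=200)
    def test_scale_equivariance(self, a, b, c, d, e, f, k):
        assert alpha(k * a, k * b, k * c, k * d, k * e, k * f) == pytest.approx(
            k * alpha(a, b, c, d, e, f), rel=1e-9, abs=1e-6
        )


def five_protein_store(include_z1z2=True):
    """x, y orthologs-in-question; z1, z2 duplicated pair in spC; w decoy."""
    registry = toy_registry({"spA": ["x"], "spB": ["y"], "spC": ["w", "z1", "z2"]})
    pairs = {
        ("x", "y"): 120.0,
        ("x", "z1"): 200.0,
        ("y", "z2"): 300.0,
        ("x", "z2"): 80.0,
        ("y", "z1"): 80.0,
        ("x", "w"): 10.0,
        ("y", "w"): 10.0,
    }
    if include_z1z2:
        pairs[("z1", "z2")] = 90.0
    return toy_store(registry, pairs)


class TestWitnesses:
    def test_single_witness_with_hand_computed_alpha(self):
        store = five_protein_store()
        ws = witnesses("x", "y", "spC", store)
        assert len(ws) == 1
        assert (ws[0].z1, ws[0].z2) == ("z1", "z2")
        assert ws[0].alpha == pytest.approx(7.5)

    def test_shared_partner_gives_no_witness(self):
        registry = toy_registry({"spA": ["x"], "spB": ["y"], "spC": ["z"]})
        store = toy_store(registry, {("x", "z"): 100.0, ("y", "z"): 100.0, ("x", "y"): 100.0})
        assert witnesses("x", "y", "spC", store) == []

    def test_missing_similarity_skips_witness(self):
        store = five_protein_store(include_z1z2=False)
        assert witnesses("x", "y", "spC", store) == []

    def test_missing_similarity_imputed_when_asked(self):
        store = five_protein_store(include_z1z2=False)
        ws = witnesses("x", "y", "spC", store, missing_policy="impute_zero")
        assert len(ws) == 1
        assert ws[0].alpha == pytest.approx(0.5 * 200 - 0.25 * (80 + 80 + 120 + 0))

    def test_third_species_must_differ(self):
        store = five_protein_store()
        with pytest.raises(ValueError):
            witnesses("x", "y", "spA", store)


class TestMaxAlpha:
    def test_maximum_over_witnesses(self):
        store = five_protein_store()
        assert max_alpha("x", "y", store) == pytest.approx(7.5)

    def test_no_evidence_is_none(self):
        registry = toy_registry({"spA": ["x"], "spB": ["y"]})
        store = toy_store(registry, {("x", "y"): 100.0})
        assert max_alpha("x", "y", store) is None


class TestCallOrthologs:
    def test_cutoff_is_inclusive(self):
        p = PutativeOrtholog("a", "b", 100.0, alpha_max=20.0)
        assert call_orthologs([p], 20.0) == [p]

    def test_no_evidence_is_assumed_ortholog(self):
        p = PutativeOrtholog("a", "b", 100.0, alpha_max=None)
        assert call_orthologs([p], -1e9) == [p]

    def test_just_above_cutoff_rejected(self):
        p = PutativeOrtholog("a", "b", 100.0, alpha_max=20.01)
        assert call_orthologs([p], 20.0) == []

    def test_called_sets_nested_in_omega(self):
        rng = np.random.default_rng(3)
        pairs = [
            PutativeOrtholog(f"a{i}", f"b{i}", 100.0, alpha_max=None if i % 5 == 0 else float(rng.normal(0, 30)))
            for i in range(50)
        ]
        previous: set = set()
        for omega in (-50.0, 0.0, 10.0, 20.0, 50.0, float("inf")):
            current = {(p.x, p.y) for p in call_orthologs(pairs, omega)}
            assert previous <= current
            previous = current


def _oracle_max_alpha(store, x, y):
    """Exhaustive enumeration over all third species and their BBH witness pairs."""
    reg = store.registry
    best = None
    for c in reg.species():
        if c in (reg.species_of(x), reg.species_of(y)):
            continue
        # brute-force BBH partner of a protein p in species c
        def partner(p):
            cands = [(s, z) for z in reg.proteins_of(c) if (s := store.get(p, z)) is not None]
            if not cands:
                return None
            z = min(z for s, z in cands if s == max(c0 for c0, _ in cands))
            back = [(s, q) for q in reg.proteins_of(reg.species_of(p)) if (s := store.get(q, z)) is not None]
            q = min(q for s, q in back if s == max(c0 for c0, _ in back))
            return z if q == p else None

        z1, z2 = partner(x), partner(y)
        if z1 is None or z2 is None or z1 == z2:
            continue
        six = [store.get(x, z1), store.get(y, z2), store.get(x, z2), store.get(y, z1), store.get(x, y), store.get(z1, z2)]
        if any(v is None for v in six):
            continue
        a = 0.5 * min(six[0], six[1]) - 0.25 * (six[2] + six[3] + six[4] + six[5])
        if best is None or a > best:
            best = a
    return best


def test_max_alpha_matches_exhaustive_enumeration():
    """On random small corpora, max_alpha equals brute-force enumeration."""
    rng = np.random.default_rng(11)
    for trial in range(50):
        n_species = int(rng.integers(3, 7))
        species = {f"sp{s}": [f"p{s}_{i}" for i in range(int(rng.integers(1, 5)))] for s in range(n_species)}
        registry = toy_registry(species)
        store = toy_store(registry, {})
        ids = [p.id for p in registry]
        for a, b in itertools.combinations(ids, 2):
            if rng.random() < 0.7:
                store.put(a, b, float(rng.integers(1, 12)) * 25.0)
        for p in all_bbh_pairs(store):
            assert max_alpha(p.x, p.y, store) == _oracle_max_alpha(store, p.x, p.y)


def test_score_pairs_populates_alpha():
    store = five_protein_store()
    [scored] = score_pairs([PutativeOrtholog("x", "y", 120.0)], store)
    assert scored.alpha_max == pytest.approx(7.5)
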