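import pytest

from qortho.registry import Protein, ProteinRegistry
from qortho.similarity import SimilarityStore


def toy_registry(species: dict[str, list[str]], length: int = 100) -> ProteinRegistry:
    """Registry from {species: [protein ids]}; all lengths equal."""
    registry = ProteinRegistry()
    for sp in sorted(species):
        for pid in species[sp]:
            registry.add(Protein(pid, sp, length))
    return registry


def toy_store(registry: ProteinRegistry, scores: dict[tuple[str, str], float]) -> SimilarityStore:
    store = SimilarityStore(registry)
    for (a, b), s in scores.items():
        store.put(a, b, s)
    return store


@pytest.fixture
def two_species_registry() -> ProteinRegistry:
    return toy_registry({"spA": ["x1", "x2"], "spB": ["y1", "y2"]})
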