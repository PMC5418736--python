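from __future__ import annotations

import pytest

import agelink as al


@pytest.fixture(scope="session")
def small_benchmark() -> al.Benchmark:
    """Default synthetic bundle at reduced scale, shared across tests."""
    return al.generate_benchmark(al.default_config(seed=42, n_genes=2000))


@pytest.fixture()
def chorded_square() -> al.InteractionGraph:
    """Square a-b-c-d-a plus chord a-c; mean local clustering 5/6."""
    return al.InteractionGraph.from_edges(
        [("a", "b"), ("b", "c"), ("c", "d"), ("d", "a"), ("a", "c")]
    )


@pytest.fixture()
def tiny_universe() -> al.GeneUniverse:
    genes = frozenset(f"G{i}" for i in range(20))
    return al.GeneUniverse(genes=genes)


@pytest.fixture()
def tiny_catalog() -> al.DiseaseCatalog:
    return al.DiseaseCatalog(
        diseases={
            "d1": frozenset({"G1", "G2", "G3"}),
            "d2": frozenset({"G2", "G4"}),
            "d3": frozenset({"G5", "G6", "G7"}),
        },
        disease_class={
            "d1": al.DiseaseClass.NEOPLASMS,
            "d2": al.DiseaseClass.CARDIOVASCULAR,
            "d3": al.DiseaseClass.NEOPLASMS,
        },
    )
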