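import itertools

import numpy as np
import pytest
from hypothesis import settings

from termwalk import (
    GeneSetCollection,
    SyntheticSpec,
    TermRecord,
    WalkConfig,
    build_graph,
    build_index,
    embed_collection,
    generate_collection,
)

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture
def toy_collection():
    """Three small terms over five genes; T1 and T2 overlap, T3 is disjoint."""
    return GeneSetCollection([
        TermRecord("T1", "first", frozenset({"G1", "G2", "G3"})),
        TermRecord("T2", "second", frozenset({"G2", "G3", "G4"})),
        TermRecord("T3", "third", frozenset({"G5"})),
    ])


@pytest.fixture
def toy_graph(toy_collection):
    index = build_index(toy_collection)
    return build_graph(toy_collection, index)


@pytest.fixture(scope="session")
def planted():
    """The default planted-module collection with its hidden labels."""
    collection, labels = generate_collection(SyntheticSpec())
    return collection, labels


@pytest.fixture(scope="session")
def planted_runs(planted):
    """Five full default-config embeddings of the planted collection.

    Shared by the module-recovery, clustering-validation and
    cross-species duplicate-recovery checks so the suite trains once.
    """
    collection, labels = planted
    runs = []
    for seed in range(5):
        graph, embeddings = embed_collection(collection, WalkConfig(seed=seed))
        runs.append((seed, graph, embeddings))
    return runs


def path_bipartite_graph(n_genes: int):
    """A path g0-t0-g1-t1-...: genes at even path positions, terms at odd.

    Valid under the index convention (genes 0..m-1, terms m..m+n-1) while
    being an ordinary path graph for walk-behavior checks.
    """
    n_terms = n_genes - 1
    collection = GeneSetCollection([
        TermRecord(f"T{i}", "", frozenset({f"G{i}", f"G{i + 1}"}))
        for i in range(n_terms)
    ])
    index = build_index(collection)
    return build_graph(collection, index)
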