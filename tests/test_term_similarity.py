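import itertools
import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from termwalk import (
    EmbeddingMatrix,
    SyntheticSpec,
    WalkConfig,
    build_graph,
    build_index,
    build_pair_table,
    embed_collection,
    generate_collection,
    hypergeometric_pvalue,
    jaccard_index,
    minmax_normalize,
    pairwise_term_distances,
    top_fraction_threshold,
    write_pair_table,
)

gene_sets = st.sets(st.sampled_from([f"G{i}" for i in range(12)]),
                    min_size=1, max_size=8)


class TestJaccard:
    @pytest.mark.parametrize("a, b, expected", [
        ({"g1", "g2"}, {"g1", "g2"}, 1.0),
        ({"g1"}, {"g2"}, 0.0),
        ({"a", "b", "c"}, {"c", "d"}, 0.25),
    ])
    def test_examples(self, a, b, expected):
        assert jaccard_index(a, b) == expected

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            jaccard_index(set(), {"g"})

    @given(gene_sets, gene_sets)
    def test_bounds_symmetry_identity(self, a, b):
        j = jaccard_index(a, b)
        assert 0.0 <= j <= 1.0
        assert j == jaccard_index(b, a)
        assert (j == 1.0) == (a == b)
        assert (j == 0.0) == (not a & b)

    @given(gene_sets, gene_sets)
    def test_adding_shared_gene_never_decreases(self, a, b):
        j = jaccard_index(a, b)
        assert jaccard_index(a | {"NEW"}, b | {"NEW"}) >= j


def enumerated_upper_tail(k, size_a, size_b, universe):
    """Oracle: exhaustive enumeration of all C(universe, size_b) draws."""
    population = range(universe)
    successes = set(range(size_a))
    hits = total = 0
    for draw in itertools.combinations(population, size_b):
        total += 1
        hits += len(successes & set(draw)) >= k
    return Fraction(hits, total)


class TestHypergeometric:
    def test_zero_overlap_is_one(self):
        assert hypergeometric_pvalue(0, 5, 5, 100) == 1.0

    @pytest.mark.parametrize("k, a, b, n, expected", [
        (5, 5, 5, 10, Fraction(1, 252)),
        (1, 2, 2, 4, Fraction(5, 6)),
    ])
    def test_exact_fractions(self, k, a, b, n, expected):
        assert enumerated_upper_tail(k, a, b, n) == expected  # oracle check
        assert hypergeometric_pvalue(k, a, b, n) == pytest.approx(
            float(expected), rel=1e-12)

    def test_matches_enumeration_small_universes(self):
        for universe in (6, 9, 12):
            for size_a in (2, universe // 2):
                for size_b in (2, universe // 3):
                    for k in range(min(size_a, size_b) + 1):
                        expected = enumerated_upper_tail(
                            k, size_a, size_b, universe)
                        got = hypergeometric_pvalue(k, size_a, size_b, universe)
                        assert got == pytest.approx(float(expected), rel=1e-10)

    @pytest.mark.parametrize("args", [(3, 2, 5, 10), (-1, 2, 2, 10),
                                      (1, 11, 2, 10)])
    def test_inconsistent_counts_rejected(self, args):
        with pytest.raises(ValueError):
            hypergeometric_pvalue(*args)


class TestPairwiseDistances:
    def _embedding(self, term_vectors, n_genes=0):
        from termwalk.graph_build import NodeIndex
        vecs = np.vstack([np.zeros((n_genes, term_vectors.shape[1])),
                          term_vectors])
        index = NodeIndex(
            {f"G{i}": i for i in range(n_genes)},
            {f"T{i}": n_genes + i for i in range(term_vectors.shape[0])},
        )
        return EmbeddingMatrix(vecs, vecs.shape[1]), index

    def test_three_four_five(self):
        emb, index = self._embedding(np.array([[0.0, 0.0], [3.0, 4.0]]))
        mat = pairwise_term_distances(emb, index, "euclidean")
        assert mat[0, 1] == mat[1, 0] == pytest.approx(5.0)
        assert mat[0, 0] == mat[1, 1] == 0.0

    def test_identical_vectors_distance_zero(self):
        emb, index = self._embedding(np.ones((2, 3)))
        assert pairwise_term_distances(emb, index, "euclidean")[0, 1] == 0.0

    @pytest.mark.parametrize("metric", ["euclidean", "cosine"])
    def test_matches_double_loop_oracle(self, metric):
        rng = np.random.default_rng(0)
        points = rng.normal(size=(10, 6))
        emb, index = self._embedding(points, n_genes=4)
        mat = pairwise_term_distances(emb, index, metric)
        for i in range(10):
            for j in range(10):
                if metric == "euclidean":
                    expected = math.sqrt(((points[i] - points[j]) ** 2).sum())
                else:
                    num = float(points[i] @ points[j])
                    den = (math.sqrt(points[i] @ points[i])
                           * math.sqrt(points[j] @ points[j]))
                    expected = 0.0 if i == j else 1 - num / den
                assert mat[i, j] == pytest.approx(expected, abs=1e-12)

    def test_unknown_metric_rejected(self):
        emb, index = self._embedding(np.ones((2, 2)))
        with pytest.raises(ValueError):
            pairwise_term_distances(emb, index, "manhattan")


class TestNormalizeAndThreshold:
    def test_minmax_example(self):
        assert minmax_normalize([2, 4, 6]).tolist() == [0.0, 0.5, 1.0]

    def test_constant_input_maps_to_zeros(self):
        assert minmax_normalize([7, 7]).tolist() == [0.0, 0.0]

    @given(st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=30))
    def test_extremes_map_to_unit_interval(self, values):
        out = minmax_normalize(values)
        assert out.min() >= 0.0 and out.max() <= 1.0
        if max(values) > min(values):
            assert out.min() == 0.0 and out.max() == 1.0

    def test_top_fraction_on_1_to_100(self):
        values = list(range(1, 101))
        assert top_fraction_threshold(values, 0.05) == 5.0

    def test_fraction_one_is_maximum(self):
        assert top_fraction_threshold([3.0, 1.0, 2.0], 1.0) == 3.0

    def test_selected_count_is_ceil(self):
        rng = np.random.default_rng(1)
        values = rng.random(333)
        thr = top_fraction_threshold(values, 0.05)
        assert (values <= thr).sum() == math.ceil(0.05 * 333)

    @pytest.mark.parametrize("fraction", [0.0, 1.5, -0.1])
    def test_fraction_out_of_range(self, fraction):
        with pytest.raises(ValueError):
            top_fraction_threshold([1.0], fraction)


@pytest.fixture(scope="module")
def small_run():
    coll, _ = generate_collection(SyntheticSpec(
        n_modules=2, terms_per_module=3, pool_size=10, genes_per_term=5,
        noise_genes_per_term=1, background_pool_size=20, seed=2))
    cfg = WalkConfig(dimensions=8, epochs=2, seed=2)
    graph, emb = embed_collection(coll, cfg)
    return coll, graph, emb


class TestPairTable:
    def test_row_count_is_n_choose_2(self, small_run):
        coll, graph, emb = small_run
        table = build_pair_table(coll, graph, emb)
        n = len(coll)
        assert len(table) == n * (n - 1) // 2

    def test_cells_match_independent_recomputation(self, small_run):
        coll, graph, emb = small_run
        table = build_pair_table(coll, graph, emb)
        sets = {t.term_id: t.genes for t in coll}
        universe = graph.index.m
        order = graph.index.term_to_index
        raw = []
        for row in table.itertuples():
            a, b = sets[row.term_a], sets[row.term_b]
            assert row.jaccard == pytest.approx(len(a & b) / len(a | b))
            assert row.hypergeom_p == pytest.approx(hypergeometric_pvalue(
                len(a & b), len(a), len(b), universe))
            va = emb.vectors[order[row.term_a]]
            vb = emb.vectors[order[row.term_b]]
            assert row.raw_distance == pytest.approx(
                float(np.linalg.norm(va - vb)))
            raw.append(row.raw_distance)
        expected_norm = (np.array(raw) - min(raw)) / (max(raw) - min(raw))
        assert table["norm_distance"].to_numpy() == pytest.approx(expected_norm)

    def test_identical_gene_sets_give_jaccard_one(self, small_run):
        from termwalk import GeneSetCollection, TermRecord
        coll, _, _ = small_run
        dup = GeneSetCollection([
            TermRecord("A", "", coll[0].genes),
            TermRecord("B", "", coll[0].genes),
            TermRecord("C", "", coll[1].genes),
        ])
        index = build_index(dup)
        graph = build_graph(dup, index)
        vecs = np.arange(index.n_nodes * 2, dtype=float).reshape(-1, 2)
        table = build_pair_table(dup, graph, EmbeddingMatrix(vecs, 2))
        row = table[(table.term_a == "A") & (table.term_b == "B")].iloc[0]
        assert row.jaccard == 1.0
        assert row.hypergeom_p == table.hypergeom_p.min()

    def test_bh_adjustment_optional(self, small_run):
        coll, graph, emb = small_run
        table = build_pair_table(coll, graph, emb, adjust_pvalues=True)
        assert "hypergeom_q" in table.columns
        assert (table.hypergeom_q >= table.hypergeom_p - 1e-15).all()

    def test_tsv_round_trip(self, small_run, tmp_path):
        coll, graph, emb = small_run
        table = build_pair_table(coll, graph, emb)
        path = tmp_path / "pairs.tsv"
        write_pair_table(table, path)
        back = pd.read_csv(path, sep="\t")
        assert len(back) == len(table)
        assert back["jaccard"].to_numpy() == pytest.approx(
            table["jaccard"].to_numpy())


def test_distance_anticorrelates_with_jaccard():
    """Closer in embedding space should mean more gene overlap on planted
    modules: Spearman rho between normalized distance and Jaccard < 0."""
    from scipy.stats import spearmanr
    coll, _ = generate_collection(SyntheticSpec(
        n_modules=3, terms_per_module=8, pool_size=30, genes_per_term=12,
        noise_genes_per_term=2, background_pool_size=60, seed=5))
    cfg = WalkConfig(dimensions=16, epochs=10, seed=5)
    graph, emb = embed_collection(coll, cfg)
    table = build_pair_table(coll, graph, emb)
    rho = spearmanr(table.norm_distance, table.jaccard).statistic
    assert rho < 0
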