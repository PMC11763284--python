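"""Evaluation metrics: ARI, compactness, DE calling, recovery, benchmark."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cciseq import (
    NormalizedMatrix,
    adjusted_rand_index,
    compactness,
    gene_recovery_correlation,
    set_metrics,
    snn_cluster,
    wilcoxon_de,
)


def pair_counting_ari(a, b) -> float:
    """Independent oracle: ARI from explicit enumeration of item pairs."""
    a, b = np.asarray(a), np.asarray(b)
    n = len(a)
    ss = sd = ds = dd = 0
    for i, j in itertools.combinations(range(n), 2):
        same_a, same_b = a[i] == a[j], b[i] == b[j]
        ss += same_a and same_b
        sd += same_a and not same_b
        ds += (not same_a) and same_b
        dd += (not same_a) and not same_b
    total = ss + sd + ds + dd
    expected = (ss + sd) * (ss + ds) / total
    maximum = ((ss + sd) + (ss + ds)) / 2
    if maximum == expected:
        return 1.0
    return (ss - expected) / (maximum - expected)


class TestAdjustedRandIndex:
    def test_identical_partitions(self):
        assert adjusted_rand_index([1, 1, 2, 2], [1, 1, 2, 2]) == 1.0

    def test_invariant_to_relabeling(self):
        a = [1, 1, 2, 2, 3]
        b = [9, 9, 4, 4, 7]
        assert adjusted_rand_index(a, b) == 1.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            adjusted_rand_index([1, 2], [1, 2, 3])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_pair_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(4, 13)
        a = rng.integers(0, 3, n)
        b = rng.integers(0, 3, n)
        assert adjusted_rand_index(a, b) == pytest.approx(pair_counting_ari(a, b), abs=1e-12)

    def test_contingency_2x2_example(self):
        # contingency [[2,1],[1,2]] on 6 items
        a = [0, 0, 0, 1, 1, 1]
        b = [0, 0, 1, 0, 1, 1]
        assert adjusted_rand_index(a, b) == pytest.approx(pair_counting_ari(a, b), abs=1e-12)


class TestCompactness:
    def test_point_clusters_give_one(self):
        pts = np.array([[0.0, 0.0]] * 5 + [[3.0, 4.0]] * 5)
        labels = [1] * 5 + [2] * 5
        assert compactness(pts, labels) == pytest.approx(1.0)

    def test_anova_decomposition_exact(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(200, 2))
        labels = rng.integers(0, 3, 200)
        grand = pts.mean(axis=0)
        tss = float(np.sum((pts - grand) ** 2))
        b = sum(
            (labels == u).sum() * float(np.sum((pts[labels == u].mean(axis=0) - grand) ** 2))
            for u in np.unique(labels)
        )
        w = sum(
            float(np.sum((pts[labels == u] - pts[labels == u].mean(axis=0)) ** 2))
            for u in np.unique(labels)
        )
        assert b + w == pytest.approx(tss, abs=1e-8)
        assert compactness(pts, labels) == pytest.approx(b / tss, abs=1e-12)

    def test_random_labels_on_one_cloud_near_zero(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(2000, 2))
        labels = rng.integers(0, 2, 2000)
        assert compactness(pts, labels) < 0.01

    def test_single_cluster_warns_and_returns_zero(self):
        with pytest.warns(UserWarning):
            assert compactness(np.zeros((4, 2)), [1, 1, 1, 1]) == 0.0


class TestWilcoxonDE:
    @pytest.fixture(scope="class")
    def shifted_matrix(self):
        rng = np.random.default_rng(6)
        values = rng.gamma(2.0, 1.0, (60, 200))
        labels = np.repeat([1, 2], 100)
        values[:10, labels == 2] *= 4.0  # strong DE in the first 10 genes
        values[20] = 0.0  # all-zero gene
        return NormalizedMatrix(np.log1p(values)), labels

    def test_strong_genes_declared(self, shifted_matrix):
        norm, labels = shifted_matrix
        res = wilcoxon_de(norm, labels)
        declared_idx = {norm.gene_ids.index(g) for g in res.declared}
        assert set(range(10)) <= declared_idx

    def test_all_zero_gene_never_declared(self, shifted_matrix):
        norm, labels = shifted_matrix
        res = wilcoxon_de(norm, labels)
        assert norm.gene_ids[20] not in res.declared
        assert res.table.loc[norm.gene_ids[20], "p"] == 1.0

    def test_infinite_lfc_threshold_empties_declared(self, shifted_matrix):
        norm, labels = shifted_matrix
        res = wilcoxon_de(norm, labels, lfc_min=np.inf)
        assert res.declared == set()

    def test_three_clusters_contrasts_largest_two(self, shifted_matrix):
        norm, labels = shifted_matrix
        labels3 = labels.copy()
        labels3[:4] = 3  # tiny third cluster
        res = wilcoxon_de(norm, labels3)
        assert len(res.table) == norm.n_genes

    def test_small_cluster_rejected(self, shifted_matrix):
        norm, _ = shifted_matrix
        labels = np.array([1] * 2 + [2] * (norm.n_cells - 2))
        with pytest.raises(ValueError):
            wilcoxon_de(norm, labels)

    def test_null_false_positive_rate_controlled(self):
        # Bonferroni-adjusted declarations under exchangeable groups are rare
        rng = np.random.default_rng(7)
        values = np.log1p(rng.gamma(2.0, 1.0, (300, 160)))
        labels = np.repeat([1, 2], 80)
        res = wilcoxon_de(values, labels)
        assert len(res.declared) <= 2
        # and raw p-values are calibrated at the nominal level
        assert abs((res.table["p"] < 0.05).mean() - 0.05) < 0.04


class TestSetMetrics:
    def test_perfect_agreement(self):
        universe = set(range(20))
        a = set(range(5))
        assert set_metrics(a, a, universe) == (1.0, 1.0, 1.0)

    def test_disjoint_sets(self):
        universe = set(range(20))
        j, s, sp = set_metrics({1, 2}, {3, 4}, universe)
        assert (j, s) == (0.0, 0.0)

    def test_worked_arithmetic_example(self):
        # 500 genes, 103 true, 55 recovered, 10 false declarations
        universe = {f"g{i}" for i in range(500)}
        truth = {f"g{i}" for i in range(103)}
        declared = {f"g{i}" for i in range(55)} | {f"g{i}" for i in range(103, 113)}
        j, s, sp = set_metrics(declared, truth, universe)
        assert j == pytest.approx(55 / 113)
        assert s == pytest.approx(55 / 103)
        assert sp == pytest.approx(387 / 397)

    def test_empty_truth_sensitivity_undefined(self):
        j, s, sp = set_metrics({1}, set(), set(range(5)))
        assert s is None

    def test_subset_violation_rejected(self):
        with pytest.raises(ValueError):
            set_metrics({99}, {1}, {1, 2})

    @given(
        st.sets(st.integers(0, 15)),
        st.sets(st.integers(0, 15)),
    )
    @settings(max_examples=50, deadline=None)
    def test_identities(self, declared, truth):
        universe = set(range(16))
        j, s, sp = set_metrics(declared, truth, universe)
        if truth:
            assert j <= s + 1e-12
            union = declared | truth
            assert j <= len(truth) / len(union) + 1e-12 if union else True
        all_one = j == 1.0 and s == 1.0 and sp == 1.0
        assert all_one == (declared == truth) or not truth


class TestGeneRecovery:
    def test_identical_matrices_give_one(self):
        rng = np.random.default_rng(8)
        x = rng.random((10, 30))
        assert gene_recovery_correlation(x, x, list(range(10))) == pytest.approx(1.0)

    def test_shuffled_cells_give_near_zero(self):
        rng = np.random.default_rng(9)
        x = rng.random((200, 100))
        y = x[:, rng.permutation(100)]
        assert abs(gene_recovery_correlation(x, y, list(range(200)))) < 0.05

    def test_constant_genes_excluded(self):
        x = np.vstack([np.ones(10), np.arange(10.0)])
        y = np.vstack([np.ones(10), np.arange(10.0)])
        assert gene_recovery_correlation(x, y, [0, 1]) == pytest.approx(1.0)

    def test_all_constant_raises(self):
        x = np.ones((2, 5))
        with pytest.raises(ValueError):
            gene_recovery_correlation(x, x, [0, 1])

    def test_empty_de_set_rejected(self):
        with pytest.raises(ValueError):
            gene_recovery_correlation(np.ones((2, 5)), np.ones((2, 5)), [])


class TestSNNCluster:
    def test_separated_blobs_recovered_exactly(self, blobs):
        values, labels = blobs
        res = snn_cluster(values, with_embedding=False)
        assert adjusted_rand_index(labels, res.labels) == 1.0

    def test_duplicated_dataset_keeps_partition(self, blobs):
        values, _ = blobs
        res = snn_cluster(values, with_embedding=False)
        doubled = np.concatenate([values, values], axis=1)
        res2 = snn_cluster(doubled, with_embedding=False)
        n = values.shape[1]
        assert adjusted_rand_index(res2.labels[:n], res2.labels[n:]) == 1.0

    def test_resolution_increases_cluster_count(self, small_norm):
        counts = [
            len(np.unique(snn_cluster(small_norm, resolution=r, with_embedding=False).labels))
            for r in (0.1, 0.8, 2.0)
        ]
        assert counts == sorted(counts)

    def test_embedding_returned_when_requested(self, blobs):
        values, labels = blobs
        res = snn_cluster(values, seed=1)
        assert res.embedding.shape == (values.shape[1], 2)
        assert compactness(res.embedding, res.labels) > 0.5

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            snn_cluster(np.ones((5, 2)))
        with pytest.raises(ValueError):
            snn_cluster(np.ones((5, 10)))


def test_benchmark_single_setting_shapes():
    from cciseq import CCIParams, SimParams, run_benchmark
    from cciseq.evaluate import summarize_benchmark

    grid = [SimParams(cells_per_group=60, n_genes=150, de_fac_loc=0.3, dropout_mid=2.0)]
    params = CCIParams(gene_pool=50, m=2, umap_n_epochs=50)
    rows = run_benchmark(
        grid, params=params, reps=1, seed=3, with_embedding=False,
        external={"passthrough": lambda sim, corrupted: corrupted},
    )
    assert set(rows["method"]) == {"without_dropout", "with_dropout", "cci", "passthrough"}
    assert len(rows) == 4
    # the external hook scores the corrupted matrix itself
    ext = rows[rows["method"] == "passthrough"].iloc[0]
    drop = rows[rows["method"] == "with_dropout"].iloc[0]
    assert ext["mean_spearman"] == pytest.approx(drop["mean_spearman"])
    clean = rows[rows["method"] == "without_dropout"].iloc[0]
    assert clean["mean_spearman"] == pytest.approx(1.0)
    summary = summarize_benchmark(rows)
    assert "ari_mean" in summary.columns
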