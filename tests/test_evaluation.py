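"""Clustering metrics against brute-force pair enumeration and library
cross-checks; K-means readout contracts; marker ranking."""

import numpy as np
import pytest
from sklearn.metrics import (
    adjusted_mutual_info_score,
    adjusted_rand_score,
    normalized_mutual_info_score,
)

from scdrmae.evaluation import clustering_metrics, kmeans_cluster, rank_markers
from scdrmae.types import OmicsMatrix


def brute_force_pair_counts(truth, pred):
    """Enumerate all unordered pairs and classify them."""
    n = len(truth)
    a = b = c = d = 0
    for i in range(n):
        for j in range(i + 1, n):
            same_t = truth[i] == truth[j]
            same_p = pred[i] == pred[j]
            if same_t and same_p:
                a += 1
            elif same_t:
                b += 1
            elif same_p:
                c += 1
            else:
                d += 1
    return a, b, c, d


def brute_force_ari(truth, pred):
    a, b, c, d = brute_force_pair_counts(truth, pred)
    denom = (a + b) * (b + d) + (a + c) * (c + d)
    return 1.0 if denom == 0 else 2.0 * (a * d - b * c) / denom


class TestClusteringMetrics:
    def test_perfect_agreement(self):
        r = clustering_metrics([0, 0, 1, 1, 2], [0, 0, 1, 1, 2])
        assert r.ari == r.nmi == r.ami == pytest.approx(1.0)

    def test_relabeling_invariance(self):
        r = clustering_metrics([0, 0, 1, 1], [1, 1, 0, 0])
        assert r.ari == pytest.approx(1.0)
        assert r.nmi == pytest.approx(1.0)
        assert r.ami == pytest.approx(1.0)

    def test_six_point_example_from_enumeration(self):
        truth = [0, 0, 0, 1, 1, 1]
        pred = [0, 0, 1, 0, 1, 1]
        r = clustering_metrics(truth, pred)
        counts = brute_force_pair_counts(truth, pred)
        assert r.pair_counts == counts
        assert sum(counts) == 15
        assert r.ari == pytest.approx(brute_force_ari(truth, pred), abs=1e-12)

    def test_pair_counts_partition_all_pairs(self, rng):
        truth = rng.integers(0, 4, 30)
        pred = rng.integers(0, 3, 30)
        r = clustering_metrics(truth, pred)
        assert sum(r.pair_counts) == 30 * 29 // 2

    def test_matches_brute_force_on_random_pairs(self, rng):
        for _ in range(50):
            n = int(rng.integers(5, 50))
            truth = rng.integers(0, int(rng.integers(2, 6)), n)
            pred = rng.integers(0, int(rng.integers(2, 6)), n)
            r = clustering_metrics(truth, pred)
            assert r.pair_counts == brute_force_pair_counts(truth, pred)
            assert r.ari == pytest.approx(brute_force_ari(truth, pred), abs=1e-10)

    def test_matches_reference_library(self, rng):
        """ARI/NMI/AMI agree with the scikit-learn implementations (the
        arithmetic-mean normalisations) on random labelings."""
        for _ in range(25):
            n = int(rng.integers(10, 60))
            truth = rng.integers(0, 5, n)
            pred = rng.integers(0, 4, n)
            r = clustering_metrics(truth, pred)
            assert r.ari == pytest.approx(adjusted_rand_score(truth, pred), abs=1e-10)
            assert r.nmi == pytest.approx(
                normalized_mutual_info_score(truth, pred), abs=1e-10
            )
            assert r.ami == pytest.approx(
                adjusted_mutual_info_score(truth, pred), abs=1e-8
            )

    def test_permutation_invariance(self, rng):
        truth = rng.integers(0, 4, 40)
        pred = rng.integers(0, 4, 40)
        base = clustering_metrics(truth, pred)
        for _ in range(20):
            relabel = rng.permutation(4)
            r = clustering_metrics(truth, relabel[pred])
            assert r.ari == pytest.approx(base.ari, abs=1e-12)
            assert r.nmi == pytest.approx(base.nmi, abs=1e-12)
            assert r.ami == pytest.approx(base.ami, abs=1e-12)

    def test_random_labeling_ari_centres_on_zero(self, rng):
        truth = rng.integers(0, 3, 60)
        aris = [
            clustering_metrics(truth, rng.integers(0, 3, 60)).ari
            for _ in range(1000)
        ]
        assert abs(float(np.mean(aris))) < 0.05

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            clustering_metrics([0, 1], [0, 1, 2])


class TestKmeansCluster:
    def test_k_equal_one_gives_single_cluster(self, rng):
        r = kmeans_cluster(rng.normal(size=(10, 3)), k=1, seed=0)
        assert set(r.labels) == {0}

    def test_k_equals_n_gives_singletons(self, rng):
        X = rng.normal(size=(6, 2)) * 10
        r = kmeans_cluster(X, k=6, seed=0, n_init=5)
        assert len(set(r.labels)) == 6

    def test_separated_blobs_recovered(self, rng):
        X = np.vstack(
            [rng.normal(0, 0.1, (20, 2)), rng.normal(5, 0.1, (20, 2))]
        )
        truth = np.repeat([0, 1], 20)
        r = kmeans_cluster(X, k=2, seed=0)
        assert clustering_metrics(truth, r.labels).ari == pytest.approx(1.0)

    def test_deterministic_for_fixed_seed(self, rng):
        X = rng.normal(size=(30, 4))
        a = kmeans_cluster(X, 3, seed=5).labels
        b = kmeans_cluster(X, 3, seed=5).labels
        np.testing.assert_array_equal(a, b)

    def test_k_larger_than_n_rejected(self, rng):
        with pytest.raises(ValueError):
            kmeans_cluster(rng.normal(size=(3, 2)), k=5, seed=0)


class TestRankMarkers:
    def test_planted_exclusive_feature_ranked_first(self, rng):
        """A feature expressed only inside one cluster maximises the
        rank-sum statistic for that cluster."""
        n = 60
        labels = np.repeat([0, 1, 2], 20)
        vals = np.abs(rng.normal(1.0, 0.2, (n, 10)))
        vals[:, 4] = 0.0
        vals[labels == 1, 4] = 5.0
        X = OmicsMatrix(vals, modality="rna")
        table = rank_markers(X, labels, top_n=3)
        top1 = table[(table.cluster == 1) & (table["rank"] == 1)]
        assert top1.feature.iloc[0] == "feature_4"
        assert top1.p.iloc[0] < 1e-6

    def test_constant_matrix_gives_unit_pvalues(self):
        X = OmicsMatrix(np.full((30, 5), 3.0), modality="adt")
        labels = np.repeat([0, 1], 15)
        table = rank_markers(X, labels, top_n=2)
        np.testing.assert_allclose(table.p, 1.0)
        np.testing.assert_allclose(table.statistic, 0.0)

    def test_output_contract_rows_per_cluster(self, rng):
        X = OmicsMatrix(rng.poisson(3.0, (40, 8)).astype(float), modality="rna")
        labels = rng.integers(0, 4, 40)
        table = rank_markers(X, labels, top_n=3)
        for c in np.unique(labels):
            sub = table[table.cluster == c]
            assert list(sub["rank"]) == [1, 2, 3]
            assert sub.feature.notna().all()

    def test_statistic_matches_scipy_normal_approximation(self, rng):
        from scipy.stats import mannwhitneyu

        vals = rng.normal(size=(50, 6))
        labels = (rng.random(50) < 0.4).astype(int)
        X = OmicsMatrix(np.abs(vals), modality="adt")
        table = rank_markers(X, labels, top_n=6)
        for _, row in table[table.cluster == 1].iterrows():
            j = int(str(row.feature).split("_")[1])
            u = mannwhitneyu(
                np.abs(vals)[labels == 1, j],
                np.abs(vals)[labels == 0, j],
                alternative="two-sided",
                method="asymptotic",
                use_continuity=False,
            )
            assert row.p == pytest.approx(u.pvalue, rel=1e-6)

    def test_tiny_cluster_skipped_with_warning(self, rng):
        X = OmicsMatrix(rng.poisson(2.0, (10, 4)).astype(float), modality="rna")
        labels = np.array([0] * 9 + [1])
        with pytest.warns(UserWarning, match="fewer than 2"):
            table = rank_markers(X, labels)
        assert set(table.cluster) == {0}
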