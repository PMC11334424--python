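"""Clustering, partition scores vs brute-force oracles, model selection."""

from __future__ import annotations

import numpy as np
import pytest
from sklearn.cluster import KMeans

from kofunclust import cluster_engine as ce
from oracles import adjusted_rand_brute, silhouette_brute, ward_merges_brute


def planted_blobs(rng, k=3, n_per=20, d=4, sep=10.0, sigma=0.1):
    # equidistant centers (scaled orthogonal axes) so no pair of planted
    # clusters is accidentally closer than another
    assert k <= d
    centers = sep * np.eye(k, d)
    X = np.vstack([rng.normal(c, sigma, size=(n_per, d)) for c in centers])
    labels = np.repeat(np.arange(k), n_per)
    return X, labels


class TestKMeans:
    def test_recovers_planted_blobs(self, rng):
        X, truth = planted_blobs(rng)
        model = ce.kmeans_fit(X, 3, seed=0)
        assert ce.adjusted_rand(model.labels, truth) == 1.0

    def test_each_point_own_cluster_when_k_equals_n(self, rng):
        X = rng.normal(size=(6, 2))
        model = ce.kmeans_fit(X, 6, seed=0)
        assert len(set(model.labels.tolist())) == 6
        assert model.inertia == pytest.approx(0.0, abs=1e-12)

    def test_deterministic_given_seed(self, rng):
        X, _ = planted_blobs(rng, sigma=1.0)
        a = ce.kmeans_fit(X, 4, seed=7)
        b = ce.kmeans_fit(X, 4, seed=7)
        assert np.array_equal(a.labels, b.labels)
        assert np.array_equal(a.centroids, b.centroids)

    def test_k_larger_than_n_raises(self, rng):
        with pytest.raises(ValueError):
            ce.kmeans_fit(rng.normal(size=(3, 2)), 4, seed=0)

    def test_objective_matches_sklearn(self, rng):
        # an independent k-means implementation should find the same optimum
        # on well-separated data
        X, _ = planted_blobs(rng, sigma=0.5)
        ours = ce.kmeans_fit(X, 3, seed=0)
        ref = KMeans(n_clusters=3, n_init=10, random_state=0).fit(X)
        assert ours.inertia == pytest.approx(ref.inertia_, rel=1e-6)


class TestWard:
    def test_one_dimensional_example(self):
        X = np.array([[0.0], [1.0], [10.0]])
        model = ce.ward_fit(X, 2)
        assert model.labels[0] == model.labels[1] != model.labels[2]

    def test_k_one_single_cluster(self, rng):
        X = rng.normal(size=(5, 2))
        model = ce.ward_fit(X, 1)
        assert set(model.labels.tolist()) == {0}

    def test_merge_heights_monotone(self, rng):
        X = rng.normal(size=(12, 3))
        model = ce.ward_fit(X, 2)
        heights = model.linkage_matrix[:, 2]
        assert (np.diff(heights) >= -1e-12).all()

    @pytest.mark.parametrize("n", [5, 6, 7, 8])
    def test_partitions_match_exhaustive_greedy_merges(self, rng, n):
        X = rng.normal(size=(n, 3))
        snapshots = ward_merges_brute(X)  # partitions after each merge
        for partition in snapshots:
            k = len(partition)
            model = ce.ward_fit(X, k)
            oracle_labels = np.empty(n, dtype=int)
            for c, members in enumerate(partition):
                for i in members:
                    oracle_labels[i] = c
            assert ce.adjusted_rand(model.labels, oracle_labels) == 1.0


class TestSilhouette:
    def test_two_tight_pairs(self):
        X = np.array([[0.0], [0.1], [10.0], [10.1]])
        s = ce.silhouette_mean(X, [0, 0, 1, 1])
        assert s == pytest.approx(0.990, abs=1e-3)
        assert s == pytest.approx(silhouette_brute(X, np.array([0, 0, 1, 1])), abs=1e-10)

    @pytest.mark.parametrize("n,k", [(12, 2), (30, 3), (50, 4)])
    def test_matches_brute_force(self, rng, n, k):
        X = rng.normal(size=(n, 3))
        labels = rng.integers(0, k, size=n)
        while len(set(labels.tolist())) < k:
            labels = rng.integers(0, k, size=n)
        assert ce.silhouette_mean(X, labels) == pytest.approx(
            silhouette_brute(X, labels), abs=1e-10
        )

    def test_random_split_of_one_population_near_zero(self, rng):
        vals = [
            ce.silhouette_mean(rng.normal(size=(60, 3)), rng.integers(0, 2, size=60) )
            for _ in range(20)
        ]
        assert abs(np.mean(vals)) < 0.05

    def test_well_separated_duplicated_points_approach_one(self):
        X = np.array([[0.0]] * 5 + [[100.0]] * 5)
        assert ce.silhouette_mean(X, [0] * 5 + [1] * 5) > 0.999

    def test_single_cluster_raises(self, rng):
        with pytest.raises(ValueError):
            ce.silhouette_mean(rng.normal(size=(4, 2)), [0, 0, 0, 0])


class TestAdjustedRand:
    def test_relabel_invariance(self):
        assert ce.adjusted_rand([1, 1, 2, 2], [2, 2, 1, 1]) == 1.0

    def test_small_example_matches_pair_counting(self):
        expected = adjusted_rand_brute([1, 1, 2, 2], [1, 2, 2, 2])
        assert ce.adjusted_rand([1, 1, 2, 2], [1, 2, 2, 2]) == pytest.approx(
            expected, abs=1e-10
        )

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_brute_force_on_random_partitions(self, rng, trial):
        n = 7
        a = rng.integers(0, 3, size=n)
        b = rng.integers(0, 4, size=n)
        assert ce.adjusted_rand(a, b) == pytest.approx(
            adjusted_rand_brute(a, b), abs=1e-10
        )

    def test_symmetry(self, rng):
        a = rng.integers(0, 3, size=30)
        b = rng.integers(0, 3, size=30)
        assert ce.adjusted_rand(a, b) == ce.adjusted_rand(b, a)

    def test_independent_labelings_near_zero(self, rng):
        vals = [
            ce.adjusted_rand(rng.integers(0, 3, 200), rng.integers(0, 3, 200))
            for _ in range(100)
        ]
        assert abs(np.mean(vals)) < 0.01

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            ce.adjusted_rand([0, 1], [0, 1, 2])


class TestBootstrapSelect:
    def test_recovers_planted_k(self, rng):
        X, _ = planted_blobs(rng, k=3, n_per=25, sep=8.0, sigma=0.5)
        report = ce.bootstrap_select(X, range(2, 7), B=15, seed=1)
        assert report.chosen_k == 3

    def test_stable_structure_gives_unit_ari(self, rng):
        X, _ = planted_blobs(rng, k=3, n_per=25, sep=20.0, sigma=0.01)
        report = ce.bootstrap_select(X, [3], methods=("kmeans",), B=10, seed=2)
        np.testing.assert_allclose(report.ari[("kmeans", 3)], 1.0)

    def test_stability_degrades_with_k_on_unstructured_data(self, rng):
        X = rng.normal(size=(80, 5))
        report = ce.bootstrap_select(X, [2, 6], methods=("kmeans",), B=15, seed=3)
        assert np.mean(report.ari[("kmeans", 2)]) > np.mean(report.ari[("kmeans", 6)])

    def test_too_few_replicates_raises(self, rng):
        with pytest.raises(ValueError):
            ce.bootstrap_select(rng.normal(size=(30, 2)), [2], B=1, seed=0)


class TestFitFinal:
    def test_held_out_samples_labeled_consistently(self, rng):
        X, truth = planted_blobs(rng, n_per=30)
        model = ce.fit_final(X, 3, seed=4, holdout_fraction=0.5)
        assert ce.adjusted_rand(model.labels, truth) == 1.0
        assert len(model.training_sample_ids or []) in (0, 45)  # ids absent for arrays

    def test_full_fraction_equivalent_to_plain_fit(self, rng):
        X, _ = planted_blobs(rng)
        full = ce.fit_final(X, 3, seed=5, holdout_fraction=1.0)
        plain = ce.kmeans_fit(X, 3, seed=ce._derive_seed(5, "final"))
        assert ce.adjusted_rand(full.labels, plain.labels) == 1.0

    def test_deterministic(self, rng):
        X, _ = planted_blobs(rng, sigma=1.5)
        a = ce.fit_final(X, 3, seed=6)
        b = ce.fit_final(X, 3, seed=6)
        assert np.array_equal(a.labels, b.labels)
        assert np.array_equal(a.centroids, b.centroids)

    def test_bad_fraction_raises(self, rng):
        with pytest.raises(ValueError):
            ce.fit_final(rng.normal(size=(10, 2)), 2, seed=0, holdout_fraction=0.0)


class TestSubcluster:
    def test_recovers_planted_sub_blobs(self, rng):
        # each parent cluster is itself a mixture of two blobs
        parents = []
        sub_truth = []
        for c in range(2):
            a = rng.normal([20 * c, 0], 0.2, size=(15, 2))
            b = rng.normal([20 * c, 8], 0.2, size=(15, 2))
            parents.append(np.vstack([a, b]))
            sub_truth.append(np.array([0] * 15 + [1] * 15))
        X = np.vstack(parents)
        labels = np.repeat([0, 1], 30)
        model = ce.ClusterModel("kmeans", 2, labels)
        subs = ce.subcluster(X, model, k_sub=2, seed=1)
        for c in range(2):
            assert ce.adjusted_rand(subs[c].labels, sub_truth[c]) == 1.0

    def test_sublabels_partition_parent_members(self, rng):
        X, truth = planted_blobs(rng)
        model = ce.kmeans_fit(X, 3, seed=0)
        subs = ce.subcluster(X, model, k_sub=2, seed=1)
        for c in range(3):
            assert len(subs[c].labels) == len(model.members(c))
            assert set(subs[c].labels.tolist()) == {0, 1}

    def test_k_sub_one_trivial(self, rng):
        X, _ = planted_blobs(rng)
        model = ce.kmeans_fit(X, 3, seed=0)
        subs = ce.subcluster(X, model, k_sub=1, seed=1)
        assert all(set(m.labels.tolist()) == {0} for m in subs.values())

    def test_undersized_parent_named_in_error(self, rng):
        X = rng.normal(size=(5, 2))
        labels = np.array([0, 0, 0, 0, 1])
        model = ce.ClusterModel("kmeans", 2, labels)
        with pytest.raises(ValueError, match="cluster 1"):
            ce.subcluster(X, model, k_sub=2, seed=0)


class TestPCA:
    def test_rank_one_data_single_component(self, rng):
        u = rng.normal(size=(40, 1))
        v = rng.normal(size=(1, 10))
        X = u @ v
        scores = ce.pca_project(X, 2)
        total = ((X - X.mean(axis=0)) ** 2).sum()
        assert (scores[:, 0] ** 2).sum() / total > 0.999

    def test_scores_orthogonal(self, rng):
        X = rng.normal(size=(30, 8))
        scores = ce.pca_project(X, 5)
        gram = scores.T @ scores
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8

    def test_cluster_separability_retained(self, rng):
        X, truth = planted_blobs(rng, d=20)
        scores = ce.pca_project(X, 5)
        model = ce.kmeans_fit(scores, 3, seed=0)
        assert ce.adjusted_rand(model.labels, truth) == 1.0

    def test_too_many_components_raises(self, rng):
        with pytest.raises(ValueError):
            ce.pca_project(rng.normal(size=(5, 3)), 4)
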