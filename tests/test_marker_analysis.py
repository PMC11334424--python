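"""Rank tests vs oracles, the composite marker criterion, permutation FDR."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats

from kofunclust import marker_analysis as ma
from kofunclust.profiles_io import PathwayMap
from oracles import dunn_brute


class TestKruskalWallis:
    def test_three_group_anchor(self):
        h, p = ma.kruskal_wallis([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        assert h == pytest.approx(7.2, abs=1e-10)
        assert 0 < p < 1

    def test_identical_groups_h_zero(self):
        h, _ = ma.kruskal_wallis([[1, 2, 3]] * 3)
        assert h == pytest.approx(0.0, abs=1e-10)

    def test_all_values_tied_degenerate(self):
        assert ma.kruskal_wallis([[5, 5], [5, 5, 5]]) == (0.0, 1.0)

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_scipy_with_ties(self, rng, trial):
        # mix of continuous values and deliberate ties
        groups = [
            np.round(rng.normal(size=rng.integers(3, 10)), 1) for _ in range(3)
        ]
        h, p = ma.kruskal_wallis(groups)
        h_ref, p_ref = stats.kruskal(*groups)
        assert h == pytest.approx(h_ref, abs=1e-10)
        assert p == pytest.approx(p_ref, abs=1e-10)

    def test_large_shift_significant(self, rng):
        a = rng.normal(size=40)
        b = rng.normal(loc=5.0, size=40)
        _, p = ma.kruskal_wallis([a, b])
        assert p < 1e-6

    def test_needs_two_nonempty_groups(self):
        with pytest.raises(ValueError):
            ma.kruskal_wallis([[1, 2, 3]])
        with pytest.raises(ValueError):
            ma.kruskal_wallis([[1, 2], []])


class TestDunn:
    def test_group_swap_negates_z(self, rng):
        a, b, c = rng.normal(size=(3, 8))
        fwd = ma.dunn_posthoc([a, b, c])
        rev = ma.dunn_posthoc([b, a, c])
        z_ab, p_ab = fwd[(0, 1)]
        z_ba, p_ba = rev[(0, 1)]
        assert z_ba == pytest.approx(-z_ab, abs=1e-12)
        assert p_ba == pytest.approx(p_ab, abs=1e-12)

    def test_three_groups_three_pairs(self, rng):
        out = ma.dunn_posthoc([rng.normal(size=5) for _ in range(3)])
        assert set(out) == {(0, 1), (0, 2), (1, 2)}
        assert all(0 <= p <= 1 for _, p in out.values())

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_brute_force_oracle(self, rng, trial):
        groups = [
            np.round(rng.normal(size=rng.integers(4, 9)), 1) for _ in range(3)
        ]
        ours = ma.dunn_posthoc(groups)
        ref = dunn_brute(groups)
        for pair in ref:
            assert ours[pair][0] == pytest.approx(ref[pair][0], abs=1e-10)
            assert ours[pair][1] == pytest.approx(ref[pair][1], abs=1e-10)

    def test_all_tied_gives_p_one(self):
        out = ma.dunn_posthoc([[2, 2, 2], [2, 2]])
        assert out[(0, 1)] == (0.0, 1.0)

    def test_type_one_error_controlled_under_null(self, rng):
        # fraction of null features with Bonferroni p < alpha stays near
        # alpha * n_pairs in expectation (Bonferroni is conservative)
        alpha = 0.01
        hits = total = 0
        labels = np.repeat([0, 1, 2], 15)
        for _ in range(50):
            X = rng.normal(size=(45, 40))
            table = ma.call_markers(
                X, labels, ma.MarkerCriterion(alpha=alpha, min_lfc=0.0)
            )
            pcols = [c for c in table.frame.columns if c.startswith("dunn_p_")]
            hits += int((table.frame[pcols] < alpha).to_numpy().sum())
            total += len(table.frame) * len(pcols)
        assert hits / total < 3 * alpha


class TestMedianLFC:
    def test_constant_groups(self):
        X = np.array([[5.0], [5.0], [5.0], [1.0], [1.0], [1.0]])
        labels = np.array([0, 0, 0, 1, 1, 1])
        assert ma.median_lfc(X, labels, 0, 0, 1) == pytest.approx(4.0)

    def test_same_cluster_zero(self, rng):
        X = rng.normal(size=(10, 2))
        labels = np.zeros(10, dtype=int)
        assert ma.median_lfc(X, labels, 0, 0, 0) == 0.0

    def test_unknown_cluster_raises(self, rng):
        with pytest.raises(ValueError):
            ma.median_lfc(rng.normal(size=(4, 1)), np.array([0, 0, 1, 1]), 0, 0, 5)

    def test_planted_shift_recovered(self, rng):
        delta = 3.0
        X = rng.normal(size=(120, 1))
        labels = np.repeat([0, 1], 60)
        X[labels == 0, 0] += delta
        est = ma.median_lfc(X, labels, 0, 0, 1)
        assert est == pytest.approx(delta, abs=0.5)

    def test_modes_agree_on_symmetric_data(self, rng):
        X = rng.normal(size=(40, 1))
        labels = np.repeat([0, 1], 20)
        a = ma.median_lfc(X, labels, 0, 0, 1, mode="difference_of_medians")
        b = ma.median_lfc(X, labels, 0, 0, 1, mode="median_of_differences")
        assert a == pytest.approx(b, abs=0.3)


def planted_marker_data(rng, n_per=60, n_kos=200, n_markers=10, delta=4.0, k=3):
    X = rng.normal(scale=0.5, size=(n_per * k, n_kos))
    labels = np.repeat(np.arange(k), n_per)
    planted = {}
    for c in range(k):
        cols = np.arange(c * n_markers, (c + 1) * n_markers)
        X[np.ix_(np.flatnonzero(labels == c), cols)] += delta
        planted[c] = set(str(j) for j in cols)
    return X, labels, planted


class TestCallMarkers:
    def test_perfect_recovery_of_planted_markers(self, rng):
        X, labels, planted = planted_marker_data(rng)
        table = ma.call_markers(X, labels)
        for c in range(3):
            assert set(table.markers_of(c)) == planted[c]
        assert table.n_markers == 30

    def test_shuffled_labels_produce_no_markers(self, rng):
        X, labels, _ = planted_marker_data(rng)
        table = ma.call_markers(X, rng.permutation(labels))
        assert table.n_markers == 0

    def test_infinite_lfc_threshold_gives_no_markers(self, rng):
        X, labels, _ = planted_marker_data(rng)
        table = ma.call_markers(X, labels, ma.MarkerCriterion(min_lfc=np.inf))
        assert table.n_markers == 0

    def test_invariant_to_sample_order(self, rng):
        X, labels, _ = planted_marker_data(rng, n_per=20, n_kos=60)
        perm = rng.permutation(len(labels))
        a = ma.call_markers(X, labels)
        b = ma.call_markers(X[perm], labels[perm])
        assert a.frame["marker_of"].tolist() == b.frame["marker_of"].tolist()

    def test_marker_of_follows_cluster_relabeling(self, rng):
        X, labels, _ = planted_marker_data(rng, n_per=20, n_kos=60)
        relabel = np.array([2, 0, 1])
        a = ma.call_markers(X, labels)
        b = ma.call_markers(X, relabel[labels])
        mapped = a.frame["marker_of"].map(lambda c: relabel[c] if c >= 0 else -1)
        assert mapped.tolist() == b.frame["marker_of"].tolist()

    def test_vectorized_stats_match_scalar_functions(self, rng):
        X, labels, _ = planted_marker_data(rng, n_per=10, n_kos=8, n_markers=2, delta=1.0)
        table = ma.call_markers(X, labels)
        for j in range(X.shape[1]):
            groups = [X[labels == c, j] for c in range(3)]
            h, p = ma.kruskal_wallis(groups)
            assert table.frame["H"].iloc[j] == pytest.approx(h, abs=1e-10)
            assert table.frame["kw_p"].iloc[j] == pytest.approx(p, abs=1e-10)
            dunn = ma.dunn_posthoc(groups)
            for (a, b), (z, pz) in dunn.items():
                assert table.frame[f"dunn_z_{a}_vs_{b}"].iloc[j] == pytest.approx(z, abs=1e-10)
                assert table.frame[f"dunn_p_{a}_vs_{b}"].iloc[j] == pytest.approx(pz, abs=1e-10)

    def test_undersized_cluster_raises(self, rng):
        X = rng.normal(size=(5, 3))
        with pytest.raises(ValueError):
            ma.call_markers(X, np.array([0, 0, 0, 0, 1]))

    def test_recall_monotone_in_effect_size(self, rng):
        recalls = []
        for delta in (1.0, 2.0, 3.0, 4.0):
            rec = []
            for _ in range(20):
                X, labels, planted = planted_marker_data(
                    rng, n_per=20, n_kos=60, n_markers=5, delta=delta
                )
                table = ma.call_markers(X, labels)
                found = set(table.frame.index[table.frame["marker_of"] >= 0])
                truth = set().union(*planted.values())
                rec.append(len(found & truth) / len(truth))
            recalls.append(np.mean(rec))
        assert all(b >= a - 0.05 for a, b in zip(recalls, recalls[1:]))
        assert recalls[-1] > recalls[0]


class TestPermutationFDR:
    def test_planted_data_zero_fdr(self, rng):
        X, labels, _ = planted_marker_data(rng, n_per=30, n_kos=100)
        out = ma.permutation_fdr(X, labels, ma.MarkerCriterion(n_perm=30), seed=1)
        assert out.observed_markers == 30
        assert out.fdr_estimate == 0.0
        assert not out.no_observed_markers

    def test_null_data_all_counts_zero(self, rng):
        X = rng.normal(size=(60, 50))
        labels = np.repeat([0, 1, 2], 20)
        out = ma.permutation_fdr(X, labels, ma.MarkerCriterion(n_perm=20), seed=2)
        assert out.observed_markers == 0
        assert out.no_observed_markers
        assert out.fdr_estimate == 0.0
        assert (out.permutation_counts == 0).all()

    def test_deterministic_given_seed(self, rng):
        X, labels, _ = planted_marker_data(rng, n_per=15, n_kos=40)
        a = ma.permutation_fdr(X, labels, ma.MarkerCriterion(n_perm=10), seed=3)
        b = ma.permutation_fdr(X, labels, ma.MarkerCriterion(n_perm=10), seed=3)
        assert np.array_equal(a.permutation_counts, b.permutation_counts)


class TestPathwayRollup:
    def table_with_markers(self, rng, markers_by_cluster):
        n_kos = sum(len(v) for v in markers_by_cluster.values()) + 5
        X, labels, _ = planted_marker_data(rng, n_per=30, n_kos=n_kos, n_markers=0)
        table = ma.call_markers(X, labels)
        table.frame["marker_of"] = -1
        for c, kos in markers_by_cluster.items():
            table.frame.loc[kos, "marker_of"] = c
        return table

    def test_three_markers_one_pathway(self, rng):
        table = self.table_with_markers(rng, {0: ["0", "1", "2"]})
        pmap = PathwayMap({(k, "map1", "P", "Cat") for k in ["0", "1", "2"]})
        out = ma.map_markers_to_pathways(table, pmap)
        assert out.per_pathway.loc[0, "n_markers"] == 3
        assert out.per_category.loc[0, "n_markers"] == 3

    def test_unmapped_marker_tallied(self, rng):
        table = self.table_with_markers(rng, {0: ["0", "1"]})
        pmap = PathwayMap({("0", "map1", None, None)})
        out = ma.map_markers_to_pathways(table, pmap)
        assert out.unmapped[0] == 1

    def test_multi_pathway_ko_counts_once_per_pathway(self, rng):
        table = self.table_with_markers(rng, {1: ["3"]})
        pmap = PathwayMap({("3", "mapA", None, "CatA"), ("3", "mapB", None, "CatA")})
        out = ma.map_markers_to_pathways(table, pmap)
        assert len(out.per_pathway) == 2
        cat = out.per_category
        assert cat.loc[(cat.cluster == 1) & (cat.category == "CatA"), "n_markers"].item() == 1

    def test_planted_category_total(self, rng):
        kos = [str(j) for j in range(76)]
        table = self.table_with_markers(rng, {0: kos})
        pmap = PathwayMap({(k, f"map{int(k) % 7}", None, "PlantedCat") for k in kos})
        out = ma.map_markers_to_pathways(table, pmap)
        cat = out.per_category
        assert cat.loc[(cat.cluster == 0) & (cat.category == "PlantedCat"), "n_markers"].item() == 76


class TestTopMarkers:
    def test_returns_all_when_fewer_than_n(self, rng):
        X, labels, planted = planted_marker_data(rng, n_per=30, n_kos=60, n_markers=3)
        table = ma.call_markers(X, labels)
        tops = ma.top_markers(table, n=15)
        for c in range(3):
            assert set(tops[c].index) == planted[c]

    def test_strongest_marker_ranks_first(self, rng):
        X, labels, planted = planted_marker_data(rng, n_per=40, n_kos=60, n_markers=3)
        boost_ko = 0  # marker of cluster 0; raise its effect above its peers
        X[np.flatnonzero(labels == 0), boost_ko] += 4.0
        table = ma.call_markers(X, labels)
        tops = ma.top_markers(table, n=15)
        assert tops[0].index[0] == str(boost_ko)

    def test_deterministic_tie_break(self, rng):
        X, labels, _ = planted_marker_data(rng, n_per=30, n_kos=40, n_markers=4)
        table = ma.call_markers(X, labels)
        a = ma.top_markers(table, n=4)
        b = ma.top_markers(table, n=4)
        for c in range(3):
            assert a[c].index.tolist() == b[c].index.tolist()
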