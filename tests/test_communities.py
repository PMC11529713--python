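"""Community detection, agglomeration, matching, and profiling."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

import spatialcomm as sc
from spatialcomm.communities import (CommunityLabeling, agglomerate,
                                     cluster_profiles, make_labeling,
                                     match_communities, rank_by_cell_type,
                                     window_kmeans, zscore_profile)
from spatialcomm.io_model import ParameterError
from oracles import brute_force_average_linkage


def gaussian_profiles(n_per, centers, sigma, seed):
    rng = np.random.default_rng(seed)
    mats, labels = [], []
    for k, c in enumerate(centers):
        mats.append(rng.normal(c, sigma, size=(n_per, len(c))))
        labels.extend([k] * n_per)
    return np.vstack(mats), np.array(labels)


class TestClusterProfiles:
    def test_recovers_three_well_separated_gaussians(self):
        """Fine communities are a pure refinement of 3 well-separated blobs;
        agglomerating to 3 recovers the planted partition exactly."""
        centers = np.eye(3) * 0.8
        mat, truth = gaussian_profiles(1000, centers, sigma=0.01, seed=0)
        lab = cluster_profiles(mat, knn_k=50, seed=0)
        assert lab.n_communities >= 3
        # every fine community lies entirely inside one planted blob
        for cid in lab.community_ids:
            assert len(set(truth[lab.labels == cid])) == 1
        agg, _ = agglomerate(lab, 3)
        assert adjusted_rand_score(truth, agg.labels) == 1.0

    def test_identical_profiles_form_single_community(self):
        mat = np.ones((200, 4)) * 0.25
        lab = cluster_profiles(mat, knn_k=10, seed=0)
        assert lab.n_communities == 1

    def test_fixed_seed_is_deterministic(self, tissue):
        table, _, _, prof = tissue
        a = cluster_profiles(prof, knn_k=50, seed=9, cells=table)
        b = cluster_profiles(prof, knn_k=50, seed=9, cells=table)
        assert np.array_equal(a.labels, b.labels)

    def test_leiden_variant_runs_and_is_deterministic(self):
        mat, truth = gaussian_profiles(300, np.eye(3), sigma=0.02, seed=1)
        a = cluster_profiles(mat, knn_k=20, seed=4, method="leiden")
        b = cluster_profiles(mat, knn_k=20, seed=4, method="leiden")
        assert np.array_equal(a.labels, b.labels)
        agg, _ = agglomerate(a, 3) if a.n_communities > 3 else (a, None)
        assert adjusted_rand_score(truth, agg.labels) == 1.0

    def test_knn_k_must_be_below_n_cells(self):
        with pytest.raises(ParameterError):
            cluster_profiles(np.zeros((10, 3)), knn_k=10, seed=0)

    def test_ids_are_canonical_by_descending_size(self, communities5):
        fine, _, _ = communities5
        assert list(fine.sizes.index) == sorted(fine.sizes.index)
        assert fine.sizes.is_monotonic_decreasing


def labeling_from_composition(comp: np.ndarray, sizes=None
                              ) -> CommunityLabeling:
    k = len(comp)
    sizes = sizes if sizes is not None else np.full(k, 10)
    labels = np.repeat(np.arange(1, k + 1), sizes)
    cols = [f"t{j}" for j in range(comp.shape[1])]
    return CommunityLabeling(
        labels=labels,
        sizes=pd.Series(sizes, index=pd.Index(range(1, k + 1),
                                              name="community")),
        cell_type_composition=pd.DataFrame(
            comp, index=pd.Index(range(1, k + 1), name="community"),
            columns=cols))


class TestAgglomerate:
    def test_identical_compositions_merge_first(self):
        comp = np.array([[1, 0, 0], [0.2, 0.4, 0.4], [1, 0, 0],
                         [0, 0.1, 0.9]], dtype=float)
        _, tree = agglomerate(labeling_from_composition(comp), 3)
        a, b, _, d = tree.merges[0]
        assert {a, b} == {1, 3} and d == 0.0

    def test_single_merge_when_target_is_count_minus_one(self):
        comp = np.random.default_rng(0).dirichlet(np.ones(4), size=5)
        merged, tree = agglomerate(labeling_from_composition(comp), 4)
        assert len(tree.merges) == 1
        assert merged.n_communities == 4

    def test_merge_order_matches_brute_force_average_linkage(self):
        comp = np.random.default_rng(3).dirichlet(np.ones(5), size=8)
        lab = labeling_from_composition(comp)
        _, tree = agglomerate(lab, 1)
        expected = brute_force_average_linkage(comp)
        assert len(tree.merges) == len(expected)
        for (a, b, _, d), (ea, eb, ed) in zip(tree.merges, expected):
            assert {a, b} == {ea + 1, eb + 1}
            assert d == pytest.approx(ed)

    def test_sizes_and_label_cover_are_preserved(self, communities5):
        fine, agg, tree = communities5
        assert agg.sizes.sum() == fine.sizes.sum()
        assert len(agg.labels) == len(fine.labels)
        assert set(agg.labels) == set(agg.sizes.index)
        assert len(tree.merges) == fine.n_communities - 5

    def test_invalid_target_rejected(self):
        comp = np.random.default_rng(0).dirichlet(np.ones(3), size=4)
        lab = labeling_from_composition(comp)
        with pytest.raises(ParameterError):
            agglomerate(lab, 0)
        with pytest.raises(ParameterError):
            agglomerate(lab, 4)


class TestMatchCommunities:
    def test_self_match_is_diagonal_with_unit_correlation(self):
        comp = np.random.default_rng(1).dirichlet(np.ones(4), size=5)
        lab = labeling_from_composition(comp)
        m = match_communities(lab, lab)
        assert m.assignment == {i: i for i in range(1, 6)}
        assert np.allclose(m.matched_correlation, 1.0)

    def test_permuted_ids_are_recovered(self):
        comp = np.random.default_rng(2).dirichlet(np.ones(4), size=5)
        a = labeling_from_composition(comp)
        perm = [2, 4, 0, 1, 3]
        b = labeling_from_composition(comp[perm])
        m = match_communities(a, b)
        # community i of `a` sits at position perm.index(i-1) in `b`
        assert m.assignment == {i + 1: perm.index(i) + 1 for i in range(5)}


class TestRankByCellType:
    def test_concentrated_type_gives_full_coverage(self, make_table):
        table = make_table([(i, 0) for i in range(6)],
                           ["CD8_T", "CD8_T", "Tumor", "Tumor", "DC", "DC"])
        lab = make_labeling(np.array([1, 1, 2, 2, 3, 3]), cells=table)
        top, coverage = rank_by_cell_type(lab, table, "CD8_T", top_n=1)
        assert list(top.index) == [1] and coverage == 1.0

    def test_uniform_spread_top5_of_10_covers_half(self, make_table):
        n = 100
        table = make_table([(i, 0) for i in range(n)], ["CD8_T"] * n)
        lab = make_labeling(np.repeat(np.arange(1, 11), 10), cells=table)
        _, coverage = rank_by_cell_type(lab, table, "CD8_T", top_n=5)
        assert coverage == pytest.approx(0.5)

    def test_matches_counting_oracle_on_random_labels(self, make_table):
        rng = np.random.default_rng(5)
        n = 400
        types = rng.choice(["CD8_T", "Tumor", "DC"], n)
        table = make_table(rng.uniform(0, 100, (n, 2)), types)
        labels = rng.integers(1, 8, n)
        lab = make_labeling(labels, cells=table)
        top, coverage = rank_by_cell_type(lab, table, "CD8_T", top_n=3)
        counts = pd.Series(labels[types == "CD8_T"]).value_counts()
        assert list(top.to_numpy()) == list(counts.iloc[:3].to_numpy())
        assert coverage == pytest.approx(counts.iloc[:3].sum() / counts.sum())

    def test_absent_type_warns_and_returns_empty(self, make_table):
        table = make_table([(0, 0), (1, 0)], ["Tumor", "DC"])
        lab = make_labeling(np.array([1, 1]), cells=table)
        with pytest.warns(UserWarning):
            top, cov = rank_by_cell_type(lab, table, "CD8_T")
        assert top.empty and np.isnan(cov)


class TestWindowKmeans:
    def _blocks_table(self):
        from conftest import build_table
        rng = np.random.default_rng(7)
        pos, types, block = [], [], []
        for b, (ox, t) in enumerate(zip((0, 500, 1000, 1500),
                                        ("Tumor", "CD8_T", "DC", "B_cell"))):
            pos.extend(rng.uniform((ox, 0), (ox + 100, 100), (150, 2)))
            types.extend([t] * 150)
            block.extend([b] * 150)
        return build_table(pos, types), np.array(block)

    def test_recovers_four_segregated_blocks(self):
        table, block = self._blocks_table()
        wins = sc.knn_windows(table, window_k=10)
        lab = window_kmeans(wins, n_clusters=4, seed=0, cells=table)
        assert adjusted_rand_score(block, lab.labels) == 1.0

    def test_one_cluster_labels_everything_together(self):
        table, _ = self._blocks_table()
        wins = sc.knn_windows(table, window_k=10)
        lab = window_kmeans(wins, n_clusters=1, seed=0)
        assert lab.n_communities == 1

    def test_fixed_seed_is_deterministic(self):
        table, _ = self._blocks_table()
        wins = sc.knn_windows(table, window_k=10)
        a = window_kmeans(wins, n_clusters=4, seed=3)
        b = window_kmeans(wins, n_clusters=4, seed=3)
        assert np.array_equal(a.labels, b.labels)


class TestZscoreProfile:
    def test_two_point_standardization(self):
        comp = np.array([[0.2, 0.8], [0.4, 0.6]])
        z = zscore_profile(labeling_from_composition(comp))
        assert z.iloc[0, 0] == pytest.approx(-np.sqrt(0.5))
        assert z.iloc[1, 0] == pytest.approx(np.sqrt(0.5))

    def test_columns_are_standardized(self):
        comp = np.random.default_rng(4).dirichlet(np.ones(5), size=7)
        z = zscore_profile(labeling_from_composition(comp))
        np.testing.assert_allclose(z.mean(axis=0), 0, atol=1e-12)
        np.testing.assert_allclose(z.std(axis=0, ddof=1), 1, atol=1e-12)

    def test_zero_variance_column_warns_and_zeroes(self):
        comp = np.array([[0.5, 0.2, 0.3], [0.5, 0.3, 0.2],
                         [0.5, 0.25, 0.25]])
        with pytest.warns(UserWarning, match="zero-variance"):
            z = zscore_profile(labeling_from_composition(comp))
        assert (z.iloc[:, 0] == 0).all()
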