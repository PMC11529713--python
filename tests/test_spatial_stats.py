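"""Distance, cross-section, correlation, clustering, and density statistics."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import fcluster

import spatialcomm as sc
from spatialcomm.communities import make_labeling
from spatialcomm.io_model import ParameterError
from spatialcomm.spatial_stats import (CellPredicate, cluster_rois,
                                       co_occurrence, community_density,
                                       community_proportions,
                                       covariate_correlation,
                                       cross_section_profile,
                                       distance_comparison, min_distance,
                                       pairwise_correlation)
from oracles import brute_force_average_linkage


class TestMinDistance:
    def test_three_four_five_triangle(self, make_table):
        table = make_table([(0, 0), (3, 4), (30, 40)],
                           ["DC", "CD8_T", "CD8_T"])
        rec = min_distance(table, CellPredicate("DC"),
                           CellPredicate("CD8_T"), 800.0)
        assert rec.iloc[0]["distance"] == pytest.approx(5.0)

    def test_target_beyond_cap_is_dropped_and_flagged(self, make_table):
        table = make_table([(0, 0), (801, 0)], ["DC", "CD8_T"])
        rec = min_distance(table, CellPredicate("DC"),
                           CellPredicate("CD8_T"), 800.0)
        assert not rec.iloc[0]["target_found"]
        assert np.isnan(rec.iloc[0]["distance"])

    def test_source_that_is_also_target_skips_itself(self, make_table):
        table = make_table([(0, 0), (7, 0)], ["DC", "DC"],
                           markers={"CXCL9": [1.0, 1.0]})
        rec = min_distance(table, CellPredicate("DC"), CellPredicate("DC"),
                           800.0)
        np.testing.assert_allclose(rec["distance"], 7.0)

    def test_marker_predicate_splits_high_low(self, make_table):
        table = make_table([(0, 0), (10, 0), (20, 0)], ["DC", "DC", "CD8_T"],
                           markers={"CXCL9": [2.0, 0.1, 0.0]})
        high = CellPredicate("DC", "CXCL9", 0.5, ">")
        assert high.mask(table).tolist() == [True, False, False]
        low = CellPredicate("DC", "CXCL9", 0.5, "<=")
        assert low.mask(table).tolist() == [False, True, False]

    def test_planted_near_class_wins_rank_sum(self):
        """Sources planted ~20 µm from targets vs ~60 µm: one-sided
        rank-sum p < 0.001 at n = 200 per class."""
        from conftest import build_table
        rng = np.random.default_rng(0)
        pos, types, marker = [], [], []
        for i in range(200):
            t = rng.uniform(0, 4000, 2)
            pos.append(t)
            types.append("CD8_T")
            marker.append(0.0)
            for mean, val in ((20.0, 1.0), (60.0, 0.0)):
                ang = rng.uniform(0, 2 * math.pi)
                d = max(1.0, rng.normal(mean, 5.0))
                pos.append(t + [d * math.cos(ang), d * math.sin(ang)])
                types.append("DC")
                marker.append(val)
        table = build_table(pos, types, markers={"CXCL9": marker})
        high = CellPredicate("DC", "CXCL9", 0.5, ">")
        low = CellPredicate("DC", "CXCL9", 0.5, "<=")
        _, _, p = distance_comparison(table, high, low,
                                      CellPredicate("CD8_T"),
                                      alternative="less")
        assert p < 0.001


class TestCrossSection:
    def test_interface_community_profile_is_bimodal(self, tissue):
        table, truth, _, _ = tissue
        codes, uniq = pd.factorize(truth.planted)
        lab = make_labeling(codes + 1, cells=table)
        prof = cross_section_profile(table, lab, n_bins=40)
        interface_id = int(np.flatnonzero(uniq == "bg_interface")[0]) + 1
        row = prof.loc[interface_id]
        pos = row.index.to_numpy(dtype=float)
        spec = sc.default_tissue_spec()
        # an annulus projected on an axis peaks near ±tumor radius while
        # remaining nonzero (chords) around position 0
        ring = (np.abs(pos) >= spec.tumor_radius) \
            & (np.abs(pos) <= spec.tumor_radius + spec.interface_width)
        core = np.abs(pos) < spec.tumor_radius / 2
        assert row[(pos > 0) & ring].max() > 1.5 * row[core].mean()
        assert row[(pos < 0) & ring].max() > 1.5 * row[core].mean()
        # and essentially vanishes beyond the outer ring
        beyond = np.abs(pos) > spec.tumor_radius + spec.interface_width + 40
        assert row[beyond].sum() <= 0.02 * row.sum()

    def test_counts_sum_to_community_sizes(self, tissue):
        table, truth, _, _ = tissue
        codes, _ = pd.factorize(truth.planted)
        lab = make_labeling(codes + 1, cells=table)
        prof = cross_section_profile(table, lab, n_bins=25)
        pd.testing.assert_series_equal(
            prof.sum(axis=1).sort_index().astype("int64"),
            lab.sizes.sort_index().astype("int64"),
            check_names=False)

    def test_single_center_cell_lands_in_zero_bin(self, make_table):
        table = make_table([(50, 50), (10, 50), (90, 50)],
                           ["Tumor", "DC", "DC"])
        lab = make_labeling(np.array([1, 2, 2]), cells=table)
        prof = cross_section_profile(table, lab, axis="x", n_bins=5)
        mid_bin = prof.columns[2]
        assert prof.loc[1, mid_bin] == 1


class TestPairwiseCorrelation:
    def test_perfectly_covarying_pair_has_unit_correlation(self):
        comp = pd.DataFrame({"A": [0.1, 0.2, 0.3, 0.4],
                             "B": [0.2, 0.4, 0.6, 0.8],
                             "C": [0.7, 0.4, 0.1, -0.2]})
        res = pairwise_correlation(comp)
        assert res.r.loc["A", "B"] == pytest.approx(1.0)

    def test_constant_type_is_masked(self):
        comp = pd.DataFrame({"A": [0.1, 0.2, 0.3], "B": [0.5, 0.5, 0.5],
                             "C": [0.4, 0.3, 0.2]})
        res = pairwise_correlation(comp)
        assert np.isnan(res.r.loc["A", "B"])

    def test_matches_closed_form_on_five_unit_fixture(self):
        rng = np.random.default_rng(8)
        comp = pd.DataFrame(rng.dirichlet(np.ones(3), size=5),
                            columns=["A", "B", "C"])
        res = pairwise_correlation(comp)
        x, y = comp["A"].to_numpy(), comp["B"].to_numpy()
        n = len(x)
        r = ((x - x.mean()) * (y - y.mean())).sum() / math.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
        t = r * math.sqrt((n - 2) / (1 - r * r))
        from scipy.stats import t as tdist
        p = 2 * tdist.sf(abs(t), n - 2)
        assert res.r.loc["A", "B"] == pytest.approx(r)
        assert res.p.loc["A", "B"] == pytest.approx(p)

    def test_tier_symbols_follow_pvalue(self):
        comp = pd.DataFrame({"A": [0.1, 0.2, 0.3, 0.4, 0.5],
                             "B": [0.1, 0.2, 0.3, 0.4, 0.5],
                             "C": [0.9, 0.1, 0.5, 0.2, 0.6]})
        res = pairwise_correlation(comp)
        assert res.tiers.loc["A", "B"] == "***"


class TestClusterRois:
    def test_identical_rois_merge_first_at_zero(self):
        props = pd.DataFrame([[0.5, 0.5], [0.5, 0.5], [0.9, 0.1]],
                             index=["r1", "r2", "r3"])
        _, _, z, _ = cluster_rois(props)
        assert z[0, 2] == pytest.approx(0.0)
        assert sorted(z[0, :2]) == [0, 1]

    def test_linkage_matches_brute_force_on_six_rois(self):
        rng = np.random.default_rng(6)
        props = pd.DataFrame(rng.dirichlet(np.ones(4), size=6))
        _, _, z, _ = cluster_rois(props)
        expected = brute_force_average_linkage(props.to_numpy())
        assert len(z) == len(expected)
        for row, (_, _, ed) in zip(z, expected):
            assert row[2] == pytest.approx(ed)

    def test_arm_specific_communities_split_top_level(self):
        """Two arms whose community frequencies differ separate into the two
        top-level branches of the ROI dendrogram."""
        spec = sc.default_tissue_spec(seed=2)
        effects = {"vehicle": {}, "treated": {"hub_count_scale": 3.0}}
        cohort = sc.generate_cohort(spec, 6, effects, seed=2)
        frames, planted = [], []
        for t, g in cohort:
            frames.append(t.df)
            planted.append(g.df)
        table = sc.CellTable(pd.concat(frames, ignore_index=True),
                             spec.palette)
        truth = pd.concat(planted, ignore_index=True)
        codes, _ = pd.factorize(truth["planted_community"])
        lab = make_labeling(codes + 1, cells=table)
        props = community_proportions(table, lab)
        _, _, z, _ = cluster_rois(props)
        two = fcluster(z, 2, criterion="maxclust")
        arms = table.df.groupby("image_id")["group"].first() \
            .reindex(props.index)
        split = pd.Series(two, index=props.index)
        assert all(split[arms == "vehicle"].nunique() == 1
                   for _ in [0]) and split[arms == "vehicle"].iloc[0] != \
            split[arms == "treated"].iloc[0]
        assert split[arms == "treated"].nunique() == 1


class TestDensityAndCoOccurrence:
    def test_density_arithmetic_and_inclusive_presence(self, make_table):
        table = make_table([(i % 10 * 150, i // 10 * 150)
                            for i in range(100)], ["Tumor"] * 100)
        lab = make_labeling(np.ones(100, dtype=int), cells=table)
        dens = community_density(table, lab,
                                 areas_mm2=pd.Series({"img0": 2.0}))
        row = dens.iloc[0]
        assert row["density"] == pytest.approx(50.0)
        assert row["present"]
        # boundary: exactly 25 cells/mm² counts as present
        dens25 = community_density(table, lab,
                                   areas_mm2=pd.Series({"img0": 4.0}))
        assert dens25.iloc[0]["density"] == pytest.approx(25.0)
        assert dens25.iloc[0]["present"]

    def test_zero_area_rejected(self, make_table):
        table = make_table([(0, 0), (1, 0), (0, 1)], ["Tumor"] * 3)
        lab = make_labeling(np.ones(3, dtype=int), cells=table)
        with pytest.raises(ParameterError):
            community_density(table, lab, areas_mm2=pd.Series({"img0": 0.0}))

    def test_co_occurrence_truth_table(self):
        dens = pd.DataFrame({
            "image_id": ["i1", "i1", "i2", "i2", "i3", "i3", "i4", "i4"],
            "community": [1, 2] * 4,
            "density": [30, 30, 30, 5, 5, 30, 5, 5],
        })
        assert co_occurrence(dens, [1], [2], 25.0) == pytest.approx(0.25)


class TestCovariateCorrelation:
    def test_monotone_pairs_give_unit_rho(self):
        d = pd.Series([1.0, 2, 3, 4, 5], index=list("abcde"))
        c = pd.Series([10.0, 20, 31, 44, 60], index=list("abcde"))
        rho, p = covariate_correlation(d, c)
        assert rho == pytest.approx(1.0)

    def test_reversed_ranks_give_minus_one(self):
        d = pd.Series([1.0, 2, 3, 4], index=list("abcd"))
        c = pd.Series([9.0, 7, 5, 3], index=list("abcd"))
        rho, _ = covariate_correlation(d, c)
        assert rho == pytest.approx(-1.0)

    def test_matches_rank_based_recomputation(self):
        d = pd.Series([3.0, 1, 4, 1.5, 5, 9], index=list("abcdef"))
        c = pd.Series([2.0, 7, 1, 8, 2.8, 1.8], index=list("abcdef"))
        rho, _ = covariate_correlation(d, c)
        rd, rc = d.rank().to_numpy(), c.rank().to_numpy()
        expected = np.corrcoef(rd, rc)[0, 1]
        assert rho == pytest.approx(expected)

    def test_constant_input_flagged(self):
        d = pd.Series([2.0, 2, 2, 2], index=list("abcd"))
        c = pd.Series([1.0, 2, 3, 4], index=list("abcd"))
        with pytest.warns(UserWarning, match="constant"):
            rho, p = covariate_correlation(d, c)
        assert np.isnan(rho)
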