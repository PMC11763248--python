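"""Refinement, hypothesis testing with BY control, ranking, target overlap."""

import numpy as np
import pandas as pd
import pytest

from parcelcam.atlas import TargetSet, default_parcel_table
from parcelcam.stats import (
    RefinedSets, benjamini_yekutieli, parcelwise_tests, rank_top_parcels,
    refine_rv_sets, subset_and_target_report,
)


def rv_table(rows):
    return pd.DataFrame(rows, columns=["session_id", "subject_id",
                                       "class_label", "parcel_id", "rv"])


def predictions(rows):
    return pd.DataFrame(rows, columns=["session_id", "true_label",
                                       "predicted_label"])


def make_sets(ad: np.ndarray, hc: np.ndarray) -> RefinedSets:
    """RefinedSets from raw (subjects x parcels) arrays."""
    parcels = list(range(1, ad.shape[1] + 1))
    return RefinedSets(
        ad=pd.DataFrame(ad, columns=parcels),
        hc=pd.DataFrame(hc, columns=parcels),
    )


class TestRefinement:
    def test_clean_cohort_passes_through_regrouped(self):
        table = rv_table([
            ("s1", "a", "AD", 1, 0.5), ("s1", "a", "HC", 1, 0.1),
            ("s2", "b", "AD", 1, 0.2), ("s2", "b", "HC", 1, 0.9),
        ])
        preds = predictions([("s1", "AD", "AD"), ("s2", "HC", "HC")])
        out = refine_rv_sets(table, preds)
        assert out.ad.loc["a", 1] == 0.5
        assert out.hc.loc["b", 1] == 0.9
        assert out.audit["removed_misclassified"] == 0

    def test_repeated_sessions_average_within_class(self):
        table = rv_table([
            ("s1", "a", "AD", 7, 0.2), ("s2", "a", "AD", 7, 0.4),
            ("s3", "b", "HC", 7, 0.6),
        ])
        preds = predictions([("s1", "AD", "AD"), ("s2", "AD", "AD"),
                             ("s3", "HC", "HC")])
        out = refine_rv_sets(table, preds)
        assert out.ad.loc["a", 7] == pytest.approx(0.3)

    def test_misclassified_sessions_removed_first(self):
        table = rv_table([
            ("s1", "a", "AD", 1, 0.9), ("s2", "a", "AD", 1, 0.1),
            ("s3", "b", "HC", 1, 0.5),
        ])
        preds = predictions([("s1", "AD", "HC"), ("s2", "AD", "AD"),
                             ("s3", "HC", "HC")])
        out = refine_rv_sets(table, preds)
        assert out.ad.loc["a", 1] == pytest.approx(0.1)  # s1 dropped
        assert out.audit["removed_misclassified"] == 1

    def test_dual_class_subject_absent_from_both_samples(self):
        table = rv_table([
            ("s1", "a", "AD", 1, 0.9), ("s2", "a", "HC", 1, 0.1),
            ("s3", "b", "AD", 1, 0.5), ("s4", "c", "HC", 1, 0.4),
        ])
        preds = predictions([("s1", "AD", "AD"), ("s2", "HC", "HC"),
                             ("s3", "AD", "AD"), ("s4", "HC", "HC")])
        out = refine_rv_sets(table, preds)
        assert "a" not in out.ad.index and "a" not in out.hc.index

    def test_audit_counts_reconcile(self):
        table = rv_table([
            ("s1", "a", "AD", 1, 0.9), ("s2", "a", "HC", 1, 0.1),
            ("s3", "b", "AD", 1, 0.5), ("s4", "c", "HC", 1, 0.4),
            ("s5", "d", "HC", 1, 0.3),
        ])
        preds = predictions([("s1", "AD", "AD"), ("s2", "HC", "HC"),
                             ("s3", "AD", "AD"), ("s4", "HC", "AD"),
                             ("s5", "HC", "HC")])
        out = refine_rv_sets(table, preds)
        a = out.audit
        assert (a["retained_sessions"] + a["removed_misclassified"]
                + a["removed_dual_class_sessions"]) == a["input_sessions"]

    def test_empty_class_after_refinement_reports_class(self):
        table = rv_table([("s1", "a", "AD", 1, 0.9), ("s2", "b", "HC", 1, 0.4)])
        preds = predictions([("s1", "AD", "HC"), ("s2", "HC", "HC")])
        with pytest.raises(ValueError, match="AD"):
            refine_rv_sets(table, preds)


class TestParcelwiseTests:
    def test_adjusted_p_never_below_raw(self, rng):
        sets = make_sets(rng.standard_normal((30, 20)),
                         rng.standard_normal((30, 20)))
        out = parcelwise_tests(sets)
        assert (out["p_adj"] >= out["p_raw"] - 1e-15).all()
        assert (out["p_adj"] <= 1.0).all()

    def test_large_shift_detected_with_direction(self, rng):
        ad = rng.standard_normal((40, 10))
        hc = rng.standard_normal((40, 10))
        ad[:, 2] += 2.0  # two pooled SDs
        out = parcelwise_tests(make_sets(ad, hc))
        assert bool(out.loc[3, "significant"])
        assert out.loc[3, "direction"] == "AD"

    def test_normal_samples_take_t_branch_heavy_tails_take_mw(self, rng):
        ad = np.column_stack([rng.standard_normal(60),
                              rng.standard_t(df=1, size=60)])
        hc = np.column_stack([rng.standard_normal(60),
                              rng.standard_t(df=1, size=60)])
        out = parcelwise_tests(make_sets(ad, hc))
        assert out.loc[1, "test"] == "t"
        assert out.loc[2, "test"] == "mann_whitney"

    def test_constant_sample_warns_and_uses_mw(self, rng):
        ad = np.column_stack([np.full(10, 0.5)])
        hc = np.column_stack([rng.standard_normal(10)])
        with pytest.warns(RuntimeWarning, match="constant"):
            out = parcelwise_tests(make_sets(ad, hc))
        assert out.loc[1, "test"] == "mann_whitney"

    def test_tiny_samples_rejected(self, rng):
        with pytest.raises(ValueError, match=">= 3"):
            parcelwise_tests(make_sets(rng.standard_normal((2, 4)),
                                       rng.standard_normal((10, 4))))


class TestBenjaminiYekutieli:
    @staticmethod
    def by_reference(p):
        """Independent step-up implementation of the BY procedure."""
        p = np.asarray(p, dtype=float)
        m = len(p)
        c_m = np.sum(1.0 / np.arange(1, m + 1))
        order = np.argsort(p)
        adj = p[order] * m * c_m / np.arange(1, m + 1)
        adj = np.minimum.accumulate(adj[::-1])[::-1]
        out = np.empty(m)
        out[order] = np.minimum(adj, 1.0)
        return out

    def test_matches_independent_reference_on_random_vectors(self, rng):
        for _ in range(1000):
            p = rng.uniform(size=rng.integers(3, 40))
            _, adj = benjamini_yekutieli(p)
            assert np.abs(adj - self.by_reference(p)).max() < 1e-12

    def test_is_more_conservative_than_bh(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(size=50)
        _, by_adj = benjamini_yekutieli(p)
        bh_adj = multipletests(p, method="fdr_bh")[1]
        assert (by_adj >= bh_adj - 1e-15).all()


class TestRanking:
    def test_fifteenth_percentile_of_132_parcels_is_20(self, rng):
        sets = make_sets(rng.standard_normal((10, 132)),
                         rng.standard_normal((10, 132)))
        rank = rank_top_parcels(sets, fraction=0.15)
        assert len(rank.top["AD"]) == 20
        assert len(rank.top["HC"]) == 20

    def test_ceil_on_small_parcel_counts(self, rng):
        sets = make_sets(rng.standard_normal((5, 10)),
                         rng.standard_normal((5, 10)))
        assert len(rank_top_parcels(sets, fraction=0.15).top["AD"]) == 2

    def test_ties_break_by_ascending_parcel_id(self):
        sets = make_sets(np.ones((4, 10)), np.ones((4, 10)))
        rank = rank_top_parcels(sets, fraction=0.2)
        assert rank.top["AD"] == [1, 2]

    def test_ranking_follows_mean_rv(self, rng):
        ad = rng.standard_normal((20, 6))
        ad[:, 4] += 10.0
        sets = make_sets(ad, rng.standard_normal((20, 6)))
        assert rank_top_parcels(sets, fraction=0.16).top["AD"] == [5]

    def test_invalid_fraction_rejected(self, rng):
        sets = make_sets(np.ones((3, 4)), np.ones((3, 4)))
        with pytest.raises(ValueError, match="fraction"):
            rank_top_parcels(sets, fraction=0.0)


class TestTargetReport:
    def _tests_frame(self, n, significant, direction="AD"):
        return pd.DataFrame({
            "test": "t", "p_raw": 0.5, "p_adj": 0.9,
            "direction": direction,
            "significant": [p in significant for p in range(1, n + 1)],
        }, index=pd.Index(range(1, n + 1), name="parcel_id"))

    def _rank(self, top_ad, top_hc):
        from parcelcam.stats import RankingResult

        return RankingResult(order={"AD": top_ad, "HC": top_hc},
                             top={"AD": top_ad, "HC": top_hc}, fraction=0.15)

    def test_disjoint_target_has_zero_overlap(self):
        rank = self._rank([1, 2], [2, 3])
        tests = self._tests_frame(10, significant={1, 2})
        target = TargetSet(name="T", parcel_ids=frozenset({7, 8}))
        rep = subset_and_target_report(rank, tests, [target])
        assert rep["targets"]["T"]["n_significant"] == 0

    def test_subsets_partition_top_set(self):
        rank = self._rank([1, 2, 3], [3, 4, 5])
        tests = self._tests_frame(10, significant={2, 9})
        rep = subset_and_target_report(rank, tests, [])
        ad = rep["classes"]["AD"]
        assert set(ad["top_significant"]) | set(ad["top_non_significant"]) \
            == {1, 2, 3}
        assert rep["common_non_significant"] == [3]

    def test_bilateral_collapse_halves_unit_count(self):
        table = default_parcel_table()
        mtl_ids = frozenset(
            table.loc[table["name"].isin(["Hippocampus", "Amygdala"]),
                      "parcel_id"])
        target = TargetSet(name="MTL-core", parcel_ids=mtl_ids)
        rank = self._rank([], [])
        tests = self._tests_frame(132, significant=set(mtl_ids))
        rep = subset_and_target_report(rank, tests, [target],
                                       parcel_table=table)
        entry = rep["targets"]["MTL-core"]
        assert entry["n_parcels"] == 4
        assert entry["n_units_collapsed"] == 2
        assert entry["fraction_significant_collapsed"] == 1.0


class TestNullRanking:
    def test_null_top_set_overlap_with_random_target_is_hypergeometric(self, rng):
        """With exchangeable RVs the top-20-of-132 set overlaps a fixed
        8-parcel target like a random draw (mean 20*8/132 ~ 1.2)."""
        target = set(range(1, 9))
        overlaps = []
        for seed in range(40):
            r = np.random.default_rng(seed)
            sets = make_sets(r.standard_normal((20, 132)),
                             r.standard_normal((20, 132)))
            top = set(rank_top_parcels(sets).top["AD"])
            overlaps.append(len(top & target))
        mean = float(np.mean(overlaps))
        assert 0.4 <= mean <= 2.4  # hypergeometric mean 1.21
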