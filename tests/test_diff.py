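"""ROC AUC against the brute-force pairwise oracle, DM calling semantics,
summary tables and cross-time-point overlap."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ovimsi.diff import (
    CTRL_VS_HFHS,
    HFHS_VS_CTRL,
    DiscriminativeMass,
    detect_dms,
    dm_intensity_summary,
    overlap_dms,
    roc_auc,
    summarize_dms,
    summary_from_counts,
)
from ovimsi.peaks import FeatureTable, PeakSet


def pairwise_auc(pos, neg):
    """O(n^2) oracle: mean over all (p, n) pairs of 1[p>n] + 0.5*1[p==n]."""
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestRocAuc:
    def test_complete_separation(self):
        assert roc_auc([3, 4], [1, 2]) == 1.0

    def test_all_ties(self):
        assert roc_auc([1, 1, 1], [1, 1, 1]) == 0.5

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([], [1.0])
        with pytest.raises(ValueError):
            roc_auc([1.0], [])

    def test_matches_pairwise_oracle_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n_p = int(rng.integers(1, 51))
            n_n = int(rng.integers(1, 51))
            # integer draws force ties to occur
            pos = rng.integers(0, 10, n_p).astype(float)
            neg = rng.integers(0, 10, n_n).astype(float)
            assert abs(roc_auc(pos, neg) - pairwise_auc(pos, neg)) <= 1e-12

    @given(
        st.lists(st.integers(0, 8), min_size=1, max_size=30),
        st.lists(st.integers(0, 8), min_size=1, max_size=30),
    )
    @settings(max_examples=60, deadline=None)
    def test_complement_identity_exact(self, pos, neg):
        assert roc_auc(pos, neg) + roc_auc(neg, pos) == pytest.approx(1.0, abs=0)

    def test_null_distribution_centered(self):
        rng = np.random.default_rng(42)
        pos = rng.normal(0, 1, 200)
        neg = rng.normal(0, 1, 200)
        se = np.sqrt((200 + 200 + 1) / (12 * 200 * 200))
        assert abs(roc_auc(pos, neg) - 0.5) < 3 * se


def make_table(ctrl_vals, hfhs_vals, centers=None):
    """FeatureTable with one CTRL and one HFHS sample."""
    ctrl_vals = np.atleast_2d(np.asarray(ctrl_vals, float))
    hfhs_vals = np.atleast_2d(np.asarray(hfhs_vals, float))
    k = ctrl_vals.shape[1]
    centers = np.asarray(centers, float) if centers is not None else 700.0 + 10.0 * np.arange(k)
    spots = pd.concat(
        [
            pd.DataFrame(
                {
                    "sample_id": sid,
                    "group": grp,
                    "timepoint": "16w",
                    "mode": "positive",
                    "x": range(v.shape[0]),
                    "y": 0,
                }
            )
            for sid, grp, v in (("c1", "CTRL", ctrl_vals), ("h1", "HFHS", hfhs_vals))
        ],
        ignore_index=True,
    )
    ps = PeakSet(centers, np.full(k, 0.75), 0.25)
    return FeatureTable(spots=spots, values=np.vstack([ctrl_vals, hfhs_vals]), peak_set=ps)


def full_rois(table):
    return {sid: np.ones(int(table.rows_for_sample(sid).sum()), bool) for sid in table.sample_ids()}


class TestDetectDms:
    def test_planted_up_effect_called(self):
        rng = np.random.default_rng(0)
        ctrl = rng.normal(10, 0.5, (30, 1))
        hfhs = rng.normal(30, 0.5, (30, 1))
        t = make_table(ctrl, hfhs)
        dms = detect_dms(t, full_rois(t))
        assert len(dms) == 1
        assert dms[0].direction == HFHS_VS_CTRL
        assert dms[0].auc >= 0.7

    def test_null_features_not_called(self):
        vals = np.tile(np.arange(1.0, 11.0)[:, None], (1, 3))
        t = make_table(vals, vals)
        assert detect_dms(t, full_rois(t)) == []

    def test_down_effect_called_with_complement_auc(self):
        rng = np.random.default_rng(1)
        ctrl = rng.normal(30, 0.5, (20, 1))
        hfhs = rng.normal(10, 0.5, (20, 1))
        t = make_table(ctrl, hfhs)
        dms = detect_dms(t, full_rois(t))
        assert dms[0].direction == CTRL_VS_HFHS
        auc_h = roc_auc(t.values[20:, 0], t.values[:20, 0])
        assert dms[0].auc == pytest.approx(1.0 - auc_h)

    def test_calling_monotone_in_threshold(self):
        rng = np.random.default_rng(2)
        ctrl = rng.normal(10, 2, (25, 40))
        hfhs = rng.normal(11, 2, (25, 40))
        t = make_table(ctrl, hfhs)
        at_07 = {(d.center_mz, d.direction) for d in detect_dms(t, full_rois(t), 0.7)}
        at_08 = {(d.center_mz, d.direction) for d in detect_dms(t, full_rois(t), 0.8)}
        assert at_08 <= at_07

    def test_at_most_one_direction_per_peak(self):
        rng = np.random.default_rng(3)
        t = make_table(rng.normal(10, 1, (25, 50)), rng.normal(10, 1, (25, 50)))
        dms = detect_dms(t, full_rois(t), threshold=0.51)
        keys = [d.center_mz for d in dms]
        assert len(keys) == len(set(keys))

    def test_empty_roi_rejected(self):
        t = make_table(np.ones((5, 2)), np.ones((5, 2)))
        rois = full_rois(t)
        rois["c1"][:] = False
        with pytest.raises(ValueError, match="empty ROI"):
            detect_dms(t, rois)

    def test_threshold_validation(self):
        t = make_table(np.ones((5, 1)), np.ones((5, 1)))
        with pytest.raises(ValueError):
            detect_dms(t, full_rois(t), threshold=0.5)


class TestSummaries:
    def test_empty_input_all_zero(self):
        out = summarize_dms([])
        assert out.empty

    def test_row_totals_sum_components(self):
        counts = {
            "16w": {
                ("negative", HFHS_VS_CTRL): 27,
                ("negative", CTRL_VS_HFHS): 83,
                ("positive", HFHS_VS_CTRL): 18,
                ("positive", CTRL_VS_HFHS): 99,
            },
            "3d": {("negative", CTRL_VS_HFHS): 10, ("positive", CTRL_VS_HFHS): 1},
        }
        out = summary_from_counts(counts).set_index("timepoint")
        assert out.loc["16w", "total_dms"] == 227
        assert out.loc["16w", f"total_{HFHS_VS_CTRL}"] == 45
        assert out.loc["16w", f"total_{CTRL_VS_HFHS}"] == 182
        assert out.loc["3d", "total_dms"] == 11

    def test_summarize_counts_dm_objects(self):
        dms = [
            DiscriminativeMass(700.0, 0.8, HFHS_VS_CTRL, "positive", "3d"),
            DiscriminativeMass(710.0, 0.9, CTRL_VS_HFHS, "positive", "3d"),
            DiscriminativeMass(710.0, 0.9, CTRL_VS_HFHS, "negative", "3d"),
        ]
        out = summarize_dms(dms).set_index("timepoint")
        assert out.loc["3d", "total_dms"] == 3
        assert out.loc["3d", f"positive_{CTRL_VS_HFHS}"] == 1


class TestOverlap:
    def mk(self, mzs, mode="positive", tp="16w"):
        return [DiscriminativeMass(m, 0.8, HFHS_VS_CTRL, mode, tp) for m in mzs]

    def test_identical_lists_fully_matched(self):
        a = self.mk([700.0, 710.0, 720.0])
        b = self.mk([700.0, 710.0, 720.0], tp="12w")
        assert len(overlap_dms(a, b, 0.1)) == 3

    def test_disjoint_sets_unmatched(self):
        assert overlap_dms(self.mk([700.0]), self.mk([750.0]), 0.1) == []

    def test_modes_never_cross_match(self):
        a = self.mk([700.0], mode="positive")
        b = self.mk([700.0], mode="negative")
        assert overlap_dms(a, b, 0.1) == []

    def test_each_dm_matched_at_most_once(self):
        a = self.mk([700.0])
        b = self.mk([700.02, 700.05])
        pairs = overlap_dms(a, b, 0.1)
        assert len(pairs) == 1
        assert pairs[0][1].center_mz == 700.02  # nearest wins


class TestDmIntensitySummary:
    def test_single_dm_equals_column(self):
        t = make_table([[1.0, 5.0], [2.0, 6.0]], [[3.0, 7.0], [4.0, 8.0]])
        dm = DiscriminativeMass(700.0, 0.9, HFHS_VS_CTRL, "positive", "16w", peak_index=0)
        out = dm_intensity_summary(t, full_rois(t), [dm], HFHS_VS_CTRL)
        np.testing.assert_allclose(out["mean_dm_intensity"], [1.0, 2.0, 3.0, 4.0])

    def test_planted_fold_two_effect(self):
        ctrl = np.tile([[2.0, 4.0]], (10, 1))
        hfhs = 2 * ctrl
        t = make_table(ctrl, hfhs)
        dms = [
            DiscriminativeMass(700.0, 0.9, HFHS_VS_CTRL, "positive", "16w", peak_index=0),
            DiscriminativeMass(710.0, 0.9, HFHS_VS_CTRL, "positive", "16w", peak_index=1),
        ]
        out = dm_intensity_summary(t, full_rois(t), dms, HFHS_VS_CTRL)
        med = out.groupby("group")["mean_dm_intensity"].median()
        assert med["HFHS"] == pytest.approx(2 * med["CTRL"])

    def test_direction_without_dms_rejected(self):
        t = make_table(np.ones((3, 1)), np.ones((3, 1)))
        dm = DiscriminativeMass(700.0, 0.9, HFHS_VS_CTRL, "positive", "16w", peak_index=0)
        with pytest.raises(ValueError):
            dm_intensity_summary(t, full_rois(t), [dm], CTRL_VS_HFHS)
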