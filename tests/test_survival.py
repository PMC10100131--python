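"""Distance maps, location features, Kaplan-Meier/log-rank, the six-gene
risk score, and the time-dependent (IPCW) AUC."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import gliomap as gm
from gliomap import synth
from gliomap.survival import (RiskModel, build_feature_table, distance_map,
                              km_curve, logrank_test, mean_tumor_distance,
                              median_split, quartile_groups, risk_score,
                              roi_center_mask, time_dependent_auc)


class TestDistanceMap:
    def test_zero_on_target(self, space16):
        target = space16.ventricle_mask
        dm = distance_map(space16, target)
        assert np.all(dm[target] == 0)

    def test_single_voxel_offset_distance(self, space16):
        target = np.zeros(space16.dims, dtype=bool)
        target[8, 8, 8] = True
        dm = distance_map(space16, target)
        # offset (1,2,2) at 2 mm voxels: 2*sqrt(1+4+4) = 6 mm
        assert dm[9, 10, 10] == pytest.approx(6.0)

    def test_matches_brute_force_nearest_voxel(self, space16, rng):
        target = rng.random(space16.dims) < 0.01
        target[4, 5, 6] = True
        dm = distance_map(space16, target)
        vs = np.asarray(space16.voxel_size)
        tc = np.argwhere(target) * vs
        pts = np.array(list(itertools.product(range(12), repeat=3))) * vs
        brute = np.sqrt(((pts[:, None] - tc[None]) ** 2).sum(-1)).min(1)
        assert np.allclose(dm[:12, :12, :12].ravel(), brute, atol=1e-9)

    def test_axis_permutation_symmetry(self, space16):
        target = np.zeros(space16.dims, dtype=bool)
        target[3, 7, 11] = True
        dm = distance_map(space16, target)
        dm_perm = distance_map(space16, target.transpose(2, 0, 1))
        assert np.allclose(dm.transpose(2, 0, 1), dm_perm, atol=1e-12)

    def test_empty_target_rejected(self, space16):
        with pytest.raises(gm.ValidationError):
            distance_map(space16, np.zeros(space16.dims, bool))


class TestRoiCenterMask:
    def test_symmetric_cube_centers(self, space16):
        roi = np.zeros(space16.dims, dtype=bool)
        roi[6:11, 6:11, 6:11] = True  # center (8,8,8)
        center = roi_center_mask(roi, space16, radius_mm=1.0)
        assert center[8, 8, 8]
        assert center.sum() == 1

    def test_center_of_mass_matches_brute_force(self, space16, cohort16):
        roi = cohort16.masks[0]
        com = np.argwhere(roi).mean(axis=0)
        center = roi_center_mask(roi, space16, radius_mm=1.0)
        assert center[tuple(np.round(com).astype(int))]

    def test_empty_roi_rejected(self, space16):
        with pytest.raises(gm.ValidationError):
            roi_center_mask(np.zeros(space16.dims, bool), space16)


class TestMeanTumorDistance:
    def test_contained_lesion_is_zero(self, space16):
        target = space16.ventricle_mask
        dm = distance_map(space16, target)
        assert mean_tumor_distance(target, dm) == 0.0

    def test_single_voxel_reads_the_map(self, space16):
        target = np.zeros(space16.dims, dtype=bool)
        target[8, 8, 8] = True
        dm = distance_map(space16, target)
        lesion = np.zeros(space16.dims, dtype=bool)
        lesion[9, 10, 10] = True
        assert mean_tumor_distance(lesion, dm) == dm[9, 10, 10]

    def test_matches_loop_mean(self, space16, cohort16):
        dm = distance_map(space16, space16.ventricle_mask)
        lesion = cohort16.masks[3]
        loop = np.mean([dm[i] for i in zip(*np.nonzero(lesion))])
        assert mean_tumor_distance(lesion, dm) == pytest.approx(loop, abs=1e-12)


class TestFeatureTable:
    def test_lesion_equal_to_roi(self, space16, cohort16):
        roi = cohort16.masks[0]
        rec = cohort16.records[0]
        single = gm.LesionCohort(space16, [roi], [rec])
        table = build_feature_table(single, roi, roi, roi)
        row = table.iloc[0]
        assert row["overlap_prop_roi1"] == 1.0
        assert row["dist_roi1_mm"] < 6.0  # lesion contains its center sphere

    def test_deterministic(self, space16, cohort16):
        pred = cohort16.masks[0]
        roi1, roi2 = cohort16.masks[1], cohort16.masks[2]
        t1 = build_feature_table(cohort16, pred, roi1, roi2)
        t2 = build_feature_table(cohort16, pred, roi1, roi2)
        pd.testing.assert_frame_equal(t1, t2)

    def test_columns_match_independent_calls(self, space16, cohort16):
        from gliomap.frequency import overlap_metrics

        pred = cohort16.masks[0]
        roi1, roi2 = cohort16.masks[1], cohort16.masks[2]
        table = build_feature_table(cohort16, pred, roi1, roi2)
        dm_svz = distance_map(space16, space16.ventricle_mask)
        for i in [0, 7, 19]:
            mask = cohort16.masks[i]
            pid = cohort16.patient_ids[i]
            vol, prop = overlap_metrics(mask, pred, space16)
            assert table.loc[pid, "overlap_volume_pred_cm3"] == vol
            assert table.loc[pid, "overlap_prop_pred"] == prop
            assert table.loc[pid, "dist_svz_mm"] == pytest.approx(
                mean_tumor_distance(mask, dm_svz))

    def test_empty_roi_yields_flagged_nan_columns(self, space16, cohort16):
        empty = np.zeros(space16.dims, dtype=bool)
        table = build_feature_table(cohort16, cohort16.masks[0],
                                    cohort16.masks[1], empty)
        assert table["dist_roi2_mm"].isna().all()
        assert table["dist_roi1_mm"].notna().all()
        assert table.attrs["empty_rois"] == ["roi2"]


class TestKaplanMeier:
    def test_uncensored_quarter_drops(self):
        t, s = km_curve([1, 2, 3, 4], [1, 1, 1, 1])
        assert np.allclose(s, [1.0, 0.75, 0.5, 0.25, 0.0])

    def test_all_censored_flat_at_one(self):
        _, s = km_curve([5, 6, 7], [0, 0, 0])
        assert np.all(s == 1.0)

    def test_hand_computed_product_limit(self):
        # times 2,3+,4,5: S(2)=3/4, S(4)=3/4*1/2, censored at 3 leaves S flat
        t, s = km_curve([2, 3, 4, 5], [1, 0, 1, 1])
        lookup = dict(zip(t, s))
        assert lookup[2.0] == pytest.approx(0.75)
        assert lookup[4.0] == pytest.approx(0.375)
        assert lookup[5.0] == pytest.approx(0.0)

    def test_empty_input_rejected(self):
        with pytest.raises(gm.ValidationError):
            km_curve([], [])


class TestLogRank:
    def test_identical_groups_not_significant(self):
        g = ([5, 6, 7, 8, 9], [1, 1, 1, 0, 1])
        chi2, p = logrank_test(g, g)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0, abs=1e-12)

    def test_matches_risk_set_table_computation(self, rng):
        # brute force: O-E and hypergeometric variance over joint event times
        for _ in range(10):
            ta = rng.exponential(10, 20).round(1)
            tb = rng.exponential(15, 25).round(1)
            ea = (rng.random(20) < 0.8).astype(int)
            eb = (rng.random(25) < 0.8).astype(int)
            if ea.sum() + eb.sum() == 0:
                continue
            chi2, p = logrank_test((ta, ea), (tb, eb))
            times = np.unique(np.concatenate([ta[ea == 1], tb[eb == 1]]))
            o_minus_e, var = 0.0, 0.0
            for t in times:
                na = (ta >= t).sum()
                nb = (tb >= t).sum()
                da = ((ta == t) & (ea == 1)).sum()
                db = ((tb == t) & (eb == 1)).sum()
                n, d = na + nb, da + db
                o_minus_e += da - d * na / n
                if n > 1:
                    var += d * (na / n) * (nb / n) * (n - d) / (n - 1)
            assert chi2 == pytest.approx(o_minus_e**2 / var, abs=1e-10)

    def test_no_events_rejected(self):
        with pytest.raises(gm.ValidationError):
            logrank_test(([1, 2], [0, 0]), ([3, 4], [0, 0]))


class TestQuartileGroups:
    def test_eight_distinct_values(self):
        s = pd.Series(np.arange(8.0), index=list("abcdefgh"))
        top, bottom = quartile_groups(s)
        assert set(top) == {"g", "h"} and set(bottom) == {"a", "b"}

    def test_matches_sorted_selection(self, rng):
        s = pd.Series(rng.normal(size=40))
        top, bottom = quartile_groups(s)
        q1, q3 = np.quantile(s, [0.25, 0.75])
        assert set(top) == set(s.index[s >= q3])
        assert set(bottom) == set(s.index[s <= q1])

    def test_translation_invariant(self, rng):
        s = pd.Series(rng.normal(size=30))
        assert quartile_groups(s) == quartile_groups(s + 100.0)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=8, max_size=40,
                    unique=True))
    def test_groups_partition_extremes(self, values):
        s = pd.Series(values)
        top, bottom = quartile_groups(s)
        assert s.idxmax() in top and s.idxmin() in bottom
        assert set(top).isdisjoint(bottom)
        assert s[top].min() > s[bottom].max()

    def test_constant_feature_rejected(self):
        with pytest.raises(gm.ValidationError):
            quartile_groups(pd.Series(np.ones(10)))


class TestRiskScore:
    def test_zero_expression_scores_zero(self):
        genes = list(RiskModel().coefficients)
        expr = pd.DataFrame(0.0, index=["a", "b"], columns=genes)
        assert np.all(risk_score(expr) == 0.0)

    def test_unit_sncb_scores_its_coefficient(self):
        genes = list(RiskModel().coefficients)
        expr = pd.DataFrame(0.0, index=["a"], columns=genes)
        expr.loc["a", "SNCB"] = 1.0
        assert risk_score(expr).iloc[0] == pytest.approx(0.1507)

    def test_matches_hand_computation_and_split_sizes(self, rng):
        model = RiskModel()
        genes = list(model.coefficients)
        expr = pd.DataFrame(rng.normal(size=(31, 6)), columns=genes)
        scores = risk_score(expr, model)
        hand = expr.to_numpy() @ np.array(
            [model.coefficients[g] for g in genes])
        assert np.allclose(scores.to_numpy(), hand, atol=1e-12)
        high, low = median_split(scores)
        assert abs(len(high) - len(low)) <= 1
        assert min(scores[high]) > max(scores[low])

    def test_missing_gene_named_in_error(self):
        expr = pd.DataFrame({"SNCB": [1.0]})
        with pytest.raises(gm.ValidationError, match="GRIN1"):
            risk_score(expr)


class TestTimeDependentAUC:
    def test_perfect_separation_without_censoring(self, rng):
        times = np.r_[rng.uniform(1, 10, 50), rng.uniform(14, 40, 50)]
        events = np.ones(100, int)
        scores = -times
        assert time_dependent_auc(scores, times, events, 12.0) == 1.0

    def test_equals_rank_sum_auc_without_censoring(self, rng):
        from sklearn.metrics import roc_auc_score

        times = rng.exponential(20, 300)
        scores = -times + rng.normal(0, 10, 300)
        auc = time_dependent_auc(scores, times, np.ones(300, int), 12.0)
        plain = roc_auc_score((times <= 12).astype(int), scores)
        assert auc == pytest.approx(plain, abs=1e-12)

    def test_matches_reference_ipcw_estimator(self, rng):
        from sksurv.metrics import cumulative_dynamic_auc
        from sksurv.util import Surv

        times = rng.exponential(20, 250)
        scores = -times + rng.normal(0, 10, 250)
        cens = rng.random(250) < 0.3
        t_obs = np.where(cens, times * rng.random(250), times)
        e_obs = np.where(cens, 0, 1)
        ours = time_dependent_auc(scores, t_obs, e_obs, 12.0)
        sv = Surv.from_arrays(e_obs.astype(bool), t_obs)
        ref, _ = cumulative_dynamic_auc(sv, sv, scores, [12.0])
        assert ours == pytest.approx(ref[0], abs=1e-10)

    def test_random_scores_near_half(self, rng):
        times = rng.exponential(20, 500)
        scores = rng.normal(size=500)
        auc = time_dependent_auc(scores, times, np.ones(500, int), 12.0)
        assert 0.45 < auc < 0.55

    def test_no_cases_rejected(self):
        with pytest.raises(gm.ValidationError):
            time_dependent_auc([1, 2], [20, 30], [1, 1], 12.0)


class TestQuartileSurvivalCoupling:
    def test_planted_distance_hazard_detected(self, space24):
        # single strong-effect world; the power study lives in acceptance
        field = synth.make_occurrence_field(space24, n_foci=4,
                                            autocorr_length=12, seed=3)
        cfg = synth.SimulationConfig(n_gbm=300, n_lgg=2, seed=11,
                                     volume_lognormal=(0.3, 0.5))
        cohort = synth.sample_cohort(space24, field, field, cfg)
        cohort = cohort.subset([r.grade == "GBM" for r in cohort.records])
        dm = distance_map(space24, space24.ventricle_mask)
        feat = pd.Series([mean_tumor_distance(m, dm) for m in cohort.masks],
                         index=cohort.patient_ids)
        top, bottom = quartile_groups(feat)
        clin = cohort.clinical_frame()
        _, p = logrank_test(
            (clin.loc[top, "survival_time"], clin.loc[top, "event"]),
            (clin.loc[bottom, "survival_time"], clin.loc[bottom, "event"]))
        assert p < 0.05
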