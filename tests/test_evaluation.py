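"""Metrics and experiment drivers: Dice, peak consistency, LOSOCV,
parameter grid, Steiger's Z."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import froimal as fm
from helpers import cuboid_atlas, make_grid


class TestDice:
    def test_identity_and_half_overlap(self):
        assert fm.dice_coefficient({(0, 0, 0)}, {(0, 0, 0)}) == 1.0
        a = {(1, 1, 1), (2, 2, 2)}
        b = {(2, 2, 2), (3, 3, 3)}
        assert fm.dice_coefficient(a, b) == 0.5

    def test_both_empty_is_undefined(self):
        assert np.isnan(fm.dice_coefficient(set(), set()))

    def test_one_empty_is_zero(self):
        assert fm.dice_coefficient({(1, 1, 1)}, set()) == 0.0

    def test_matches_counting_oracle_on_random_sets(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = {tuple(v) for v in rng.integers(0, 6, size=(50, 3))}
            b = {tuple(v) for v in rng.integers(0, 6, size=(50, 3))}
            expected = 2 * len(a & b) / (len(a) + len(b))
            assert fm.dice_coefficient(a, b) == pytest.approx(expected)

    def test_boolean_volume_form_agrees_with_set_form(self):
        rng = np.random.default_rng(1)
        va = rng.random((5, 5, 5)) > 0.6
        vb = rng.random((5, 5, 5)) > 0.6
        sa = {tuple(v) for v in np.argwhere(va)}
        sb = {tuple(v) for v in np.argwhere(vb)}
        assert fm.dice_coefficient(va, vb) == pytest.approx(fm.dice_coefficient(sa, sb))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.sets(st.integers(0, 30)), st.sets(st.integers(0, 30)))
    def test_symmetric_and_bounded(self, a, b):
        d = fm.dice_coefficient(a, b)
        if a or b:
            assert 0.0 <= d <= 1.0
            assert d == fm.dice_coefficient(b, a)


class TestPeakConsistency:
    def _setup(self, auto_box, manual_box, act_values):
        g = make_grid(shape=(8, 8, 8))
        auto = np.zeros(g.shape, dtype=int)
        auto[auto_box] = 1
        manual = np.zeros(g.shape, dtype=int)
        manual[manual_box] = 1
        return (
            fm.LabelMap(g, auto, {1: "r"}),
            fm.LabelMap(g, manual, {1: "r"}),
            fm.ActivationMap(g, act_values, "s"),
            g,
        )

    def test_identical_regions_match(self):
        g = make_grid(shape=(8, 8, 8))
        rng = np.random.default_rng(2)
        act = rng.random(g.shape) + 3
        box = (slice(2, 5),) * 3
        auto, manual, amap, _ = self._setup(box, box, act)
        assert fm.peak_consistency(auto, manual, amap, 1) is True

    def test_disjoint_regions_with_distinct_peaks_fail_at_radius_zero(self):
        g = make_grid(shape=(8, 8, 8))
        act = np.zeros(g.shape)
        act[2, 2, 2] = 5.0
        act[6, 6, 6] = 4.0
        auto, manual, amap, _ = self._setup(
            (slice(5, 8),) * 3, (slice(1, 4),) * 3, act
        )
        assert fm.peak_consistency(auto, manual, amap, 1) is False

    def test_radius_relaxation_in_mm(self):
        g = make_grid(shape=(8, 8, 8))  # 2 mm voxels
        act = np.zeros(g.shape)
        act[2, 2, 2] = 5.0
        act[3, 2, 2] = 4.0  # auto peak one voxel (2 mm) away
        auto, manual, amap, _ = self._setup(
            (slice(3, 5), slice(2, 4), slice(2, 4)), (slice(1, 3),) * 3, act
        )
        assert fm.peak_consistency(auto, manual, amap, 1, radius_mm=0.0) is False
        assert fm.peak_consistency(auto, manual, amap, 1, radius_mm=2.0) is True

    def test_empty_manual_region_is_undefined(self):
        g = make_grid(shape=(8, 8, 8))
        act = np.ones(g.shape)
        auto, manual, amap, _ = self._setup((slice(1, 3),) * 3, (slice(0, 0),) * 3, act)
        assert fm.peak_consistency(auto, manual, amap, 1) is None

    def test_empty_auto_region_is_false(self):
        g = make_grid(shape=(8, 8, 8))
        act = np.ones(g.shape)
        auto, manual, amap, _ = self._setup((slice(0, 0),) * 3, (slice(1, 3),) * 3, act)
        assert fm.peak_consistency(auto, manual, amap, 1) is False

    def test_matches_brute_force_argmax_oracle(self):
        rng = np.random.default_rng(3)
        g = make_grid(shape=(6, 6, 6))
        for _ in range(10):
            act = rng.random(g.shape)
            auto = np.where(rng.random(g.shape) > 0.7, 1, 0)
            manual = np.where(rng.random(g.shape) > 0.7, 1, 0)
            if not manual.any():
                continue
            got = fm.peak_consistency(
                fm.LabelMap(g, auto, {1: "r"}), fm.LabelMap(g, manual, {1: "r"}),
                fm.ActivationMap(g, act, "s"), 1, radius_mm=2.0,
            )
            if not auto.any():
                assert got is False
                continue
            def brute_peak(region):
                best, best_v = None, -np.inf
                for idx in sorted(map(tuple, np.argwhere(region))):
                    if act[idx] > best_v:
                        best, best_v = idx, act[idx]
                return np.asarray(best)
            pa, pm_ = brute_peak(auto == 1), brute_peak(manual == 1)
            expected = bool(np.linalg.norm((pa - pm_) * 2.0) <= 2.0 + 1e-9)
            assert got == expected


class TestLosocv:
    def test_identical_two_subject_database_scores_perfect_dice(self):
        g = make_grid(shape=(14, 14, 14))
        box = {1: (slice(2, 6),) * 3, 2: (slice(8, 12),) * 3}
        db = fm.AtlasDatabase([cuboid_atlas(g, box, s) for s in ("a", "b")])
        cfg = fm.ExperimentConfig(n_selected_atlases=0)
        records = fm.losocv(db, {1, 2}, cfg, methods=("mal",))
        assert all(r.dice == pytest.approx(1.0) for r in records)

    def test_record_bookkeeping(self, zero_var):
        cfg = fm.ExperimentConfig(n_selected_atlases=0)
        records = fm.losocv(zero_var.db, zero_var.labels, cfg, methods=("mal",))
        assert len(records) == len(zero_var.db) * len(zero_var.labels)
        assert {r.target_subject for r in records} == set(zero_var.db.subject_ids)

    def test_unknown_method_rejected(self, zero_var):
        with pytest.raises(ValueError, match="unknown method"):
            fm.losocv(zero_var.db, zero_var.labels, fm.ExperimentConfig(), methods=("svm",))

    def test_summary_layout(self, zero_var):
        cfg = fm.ExperimentConfig(n_selected_atlases=0)
        frame = fm.records_to_frame(
            fm.losocv(zero_var.db, zero_var.labels, cfg, methods=("mal",))
        )
        summary = fm.summarize_records(frame)
        assert set(summary["roi_label"]) == zero_var.labels
        assert (summary["mean_dice"] <= 1.0).all()
        assert (summary["peak_consistency"] <= 1.0).all()


class TestForestParamGrid:
    def test_one_by_one_grid_equals_plain_losocv(self):
        g = make_grid(shape=(14, 14, 14))
        box = {1: (slice(2, 6),) * 3, 2: (slice(8, 12),) * 3}
        db = fm.AtlasDatabase([cuboid_atlas(g, box, s) for s in ("a", "b", "c")])
        cfg = fm.ExperimentConfig(n_selected_atlases=0)
        grid = fm.forest_param_grid(db, {1, 2}, cfg, [30], [20])
        recs = fm.losocv(db, {1, 2}, cfg.with_forest(30, 20), methods=("mal",))
        expected = np.nanmean([r.dice for r in recs])
        assert grid.shape == (1, 1)
        assert grid.iloc[0, 0] == pytest.approx(expected)

    def test_matrix_shape(self):
        g = make_grid(shape=(14, 14, 14))
        box = {1: (slice(2, 6),) * 3}
        db = fm.AtlasDatabase([cuboid_atlas(g, box, s) for s in ("a", "b")])
        cfg = fm.ExperimentConfig(n_selected_atlases=0)
        grid = fm.forest_param_grid(db, {1}, cfg, [5, 10], [4, 8, 12])
        assert grid.shape == (2, 3)


class TestSteigerZ:
    def test_identical_correlations_give_zero(self):
        z, p = fm.steiger_z(0.6, 0.6, 0.5, 50)
        assert z == 0.0 and p == 1.0

    def test_sign_follows_correlation_difference(self):
        z_pos, _ = fm.steiger_z(0.8, 0.4, 0.5, 50)
        z_neg, _ = fm.steiger_z(0.4, 0.8, 0.5, 50)
        assert z_pos > 0 > z_neg
        assert z_pos == pytest.approx(-z_neg)

    def test_larger_n_gives_larger_magnitude(self):
        z_small, _ = fm.steiger_z(0.7, 0.4, 0.5, 20)
        z_large, _ = fm.steiger_z(0.7, 0.4, 0.5, 200)
        assert abs(z_large) > abs(z_small)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            fm.steiger_z(0.5, 0.4, 0.3, 3)
        with pytest.raises(ValueError):
            fm.steiger_z(1.5, 0.4, 0.3, 50)


class TestIntensityConcordance:
    def test_identical_automated_series_give_z_zero(self):
        rng = np.random.default_rng(4)
        manual = rng.normal(5, 1, 30)
        auto = manual + rng.normal(0, 0.5, 30)
        r1, r2, z, p = fm.intensity_concordance(manual, auto, auto.copy())
        assert r1 == pytest.approx(r2)
        assert z == 0.0 and p == 1.0

    def test_perfect_first_method_yields_positive_z(self):
        rng = np.random.default_rng(5)
        manual = rng.normal(5, 1, 40)
        noisy = manual + rng.normal(0, 2.0, 40)
        r1, r2, z, p = fm.intensity_concordance(manual, manual.copy(), noisy)
        assert r1 == pytest.approx(1.0)
        assert z > 0

    def test_nan_subjects_excluded_pairwise(self):
        rng = np.random.default_rng(6)
        manual = rng.normal(5, 1, 20)
        a1 = manual + rng.normal(0, 0.5, 20)
        a2 = manual + rng.normal(0, 1.0, 20)
        manual_nan = manual.copy()
        manual_nan[3] = np.nan
        r1, r2, z, p = fm.intensity_concordance(manual_nan, a1, a2)
        keep = np.ones(20, dtype=bool)
        keep[3] = False
        r1_ref = np.corrcoef(manual[keep], a1[keep])[0, 1]
        assert r1 == pytest.approx(r1_ref)

    def test_errors(self):
        with pytest.raises(ValueError, match="at least 4"):
            fm.intensity_concordance([1, 2, 3], [1, 2, 3], [1, 2, 3])
        with pytest.raises(ValueError, match="constant"):
            fm.intensity_concordance([1, 1, 1, 1, 1], [1, 2, 3, 4, 5], [2, 3, 4, 5, 6])

    def test_mean_region_intensity(self):
        g = make_grid(shape=(4, 4, 4))
        lab = np.zeros(g.shape, dtype=int)
        lab[0, 0, :2] = 1
        act = np.zeros(g.shape)
        act[0, 0, 0], act[0, 0, 1] = 3.0, 5.0
        lm = fm.LabelMap(g, lab, {1: "r"})
        amap = fm.ActivationMap(g, act, "s")
        assert fm.mean_region_intensity(amap, lm, 1) == pytest.approx(4.0)
        assert np.isnan(fm.mean_region_intensity(amap, lm, 2))


class TestPairwiseEncodedSimilarity:
    def test_atlas_with_itself_scores_one_on_both(self):
        g = make_grid(shape=(14, 14, 14))
        box = {1: (slice(2, 6),) * 3, 2: (slice(8, 12),) * 3}
        a1 = cuboid_atlas(g, box, "a")
        a2 = cuboid_atlas(g, box, "b")  # identical geometry, distinct subject
        db = fm.AtlasDatabase([a1, a2])
        mask = fm.build_collective_mask(db, {1, 2})
        cfg = fm.ExperimentConfig(n_selected_atlases=0)
        out = fm.pairwise_encoded_similarity(a1, a2, mask, {1, 2}, cfg)
        for label in (1, 2):
            d_orig, d_enc = out[label]
            assert d_orig == pytest.approx(1.0)
            assert d_enc >= 0.95  # forest boundary wiggles only

    def test_disjoint_raw_labels_score_zero_before_encoding(self):
        g = make_grid(shape=(16, 16, 16))
        a1 = cuboid_atlas(g, {1: (slice(2, 5),) * 3}, "a")
        a2 = cuboid_atlas(g, {1: (slice(9, 12),) * 3}, "b")
        db = fm.AtlasDatabase([a1, a2])
        mask = fm.build_collective_mask(db, {1})
        cfg = fm.ExperimentConfig(n_selected_atlases=0)
        out = fm.pairwise_encoded_similarity(a1, a2, mask, {1}, cfg)
        assert out[1][0] == 0.0
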