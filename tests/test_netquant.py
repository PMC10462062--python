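"""Per-segment measurement, tracking, and statistics."""

import numpy as np
import pandas as pd
import pytest

from actnet import (
    DataError,
    ImageStack,
    ParameterError,
    RenderParams,
    StateWindow,
    count_peaks_linescan,
    detect_transitions,
    linfit,
    match_segments,
    max_fold_change,
    measure,
    measure_roi,
    netsim,
    normalize_per_trial,
    paired_compare,
    pfc_census,
    quadrant_fraction,
    ratio_image,
    render,
    time_average,
    welch_test,
)
from actnet.io import read_table, write_table

from conftest import make_two_bundle_scene


def stack_from_frames(frames, channels=("actin",)):
    data = np.stack(frames)[..., None]
    if len(channels) > 1:
        data = np.repeat(data, len(channels), axis=-1)
    return ImageStack(data=data, channels=channels)


class TestTimeAverage:
    def test_two_point_mean(self):
        stack = stack_from_frames([np.full((4, 4), 1.0), np.full((4, 4), 3.0)])
        avg = time_average(stack, StateWindow(0, 0, 2))
        assert (avg == 2.0).all()

    def test_single_frame_identity(self):
        f = np.arange(16.0).reshape(4, 4)
        stack = stack_from_frames([f, f + 5])
        avg = time_average(stack, StateWindow(0, 1, 2))
        assert np.array_equal(avg[..., 0], f + 5)

    def test_mean_of_average_equals_mean_of_frame_means(self):
        rng = np.random.default_rng(0)
        frames = [rng.random((6, 6)) for _ in range(5)]
        stack = stack_from_frames(frames)
        avg = time_average(stack, StateWindow(0, 0, 5))
        assert avg.mean() == pytest.approx(
            np.mean([f.mean() for f in frames]), rel=1e-12
        )

    def test_window_outside_stack_rejected(self):
        stack = stack_from_frames([np.zeros((3, 3))] * 2)
        with pytest.raises(ParameterError):
            time_average(stack, StateWindow(0, 0, 5))


class TestDetectTransitions:
    def test_constant_stack_single_window(self):
        stack = stack_from_frames([np.full((5, 5), 2.0)] * 8)
        windows = detect_transitions(stack, 0)
        assert len(windows) == 1
        assert (windows[0].start, windows[0].stop) == (0, 8)

    def test_abrupt_change_marks_boundary(self):
        frames = [np.zeros((6, 6))] * 10 + [np.full((6, 6), 50.0)] * 10
        windows = detect_transitions(stack_from_frames(frames), 0)
        bounds = [(w.start, w.stop) for w in windows]
        assert (0, 10) in bounds and (10, 20) in bounds

    def test_windows_tile_the_stack(self):
        rng = np.random.default_rng(1)
        frames = [rng.random((5, 5)) for _ in range(12)]
        windows = detect_transitions(stack_from_frames(frames), 0, z_threshold=1.0)
        covered = []
        for w in windows:
            covered.extend(range(w.start, w.stop))
        assert covered == list(range(12))


class TestMeasure:
    def test_uniform_ratio(self):
        masks = np.zeros((6, 6), dtype=int)
        masks[1:4, 1:4] = 1
        t = measure(masks, np.full((6, 6), 10.0), np.full((6, 6), 5.0))
        assert len(t) == 1
        assert t.loc[0, "ratio"] == pytest.approx(0.5)
        assert t.loc[0, "area_px"] == 9

    def test_proportional_channels(self):
        rng = np.random.default_rng(2)
        actin = rng.random((8, 8)) + 1
        masks = (np.arange(64).reshape(8, 8) % 3).astype(int)
        t = measure(masks, actin, 2 * actin)
        assert np.allclose(t["ratio"], 2.0)

    def test_force_condition_orders_ratios_by_bundle_size(self):
        """With force-activated binding, a single filament shows a higher
        ABP:actin ratio than a 4-filament bundle."""
        scene = make_two_bundle_scene(n_a=1, n_b=4)
        rp = RenderParams(
            shot_noise=False, read_noise_sigma=0.0, background=0.0
        )
        stack = render(scene, rp)
        masks = np.zeros(scene.pattern.image_shape, dtype=int)
        masks[scene.segment_mask(0, 5)] = 1
        masks[scene.segment_mask(1, 5)] = 2
        t = measure(masks, stack.data[0, ..., 0], stack.data[0, ..., 1])
        r1 = t.set_index("segment_id").loc[1, "ratio"]
        r4 = t.set_index("segment_id").loc[2, "ratio"]
        assert r1 > r4

    def test_nonpositive_actin_flagged(self):
        masks = np.zeros((4, 4), dtype=int)
        masks[0:2, 0:2] = 1
        t = measure(masks, np.zeros((4, 4)), np.ones((4, 4)))
        assert not t.loc[0, "ratio_valid"]
        assert np.isnan(t.loc[0, "ratio"])

    def test_shape_mismatch_rejected(self):
        with pytest.raises(DataError):
            measure(np.zeros((3, 3), int), np.zeros((3, 3)), np.zeros((4, 4)))

    def test_csv_round_trip(self, tmp_path):
        masks = (np.arange(36).reshape(6, 6) % 4).astype(int)
        rng = np.random.default_rng(3)
        t = measure(masks, rng.random((6, 6)) + 1, rng.random((6, 6)))
        path = tmp_path / "seg.csv"
        write_table(t, path)
        back = read_table(path)
        assert back["segment_id"].tolist() == t["segment_id"].tolist()
        for col in ("mean_actin", "mean_abp", "ratio"):
            assert np.allclose(back[col], t[col], atol=1e-9, equal_nan=True)


class TestRatioImage:
    def test_proportional_channels_constant_heatmap(self):
        actin = np.random.default_rng(0).random((5, 5)) + 1
        heat = ratio_image(actin, 2 * actin)
        assert np.allclose(heat, 2.0)

    def test_empty_mask_all_nan(self):
        heat = ratio_image(np.ones((4, 4)), np.ones((4, 4)),
                           mask=np.zeros((4, 4), bool))
        assert np.isnan(heat).all()

    def test_matches_per_pixel_loop(self):
        rng = np.random.default_rng(4)
        actin = rng.random((7, 7)) + 0.5
        abp = rng.random((7, 7))
        mask = rng.random((7, 7)) > 0.4
        heat = ratio_image(actin, abp, mask=mask)
        vals = []
        for r in range(7):
            for c in range(7):
                if mask[r, c]:
                    vals.append(abp[r, c] / actin[r, c])
        assert np.nanmean(heat) == pytest.approx(np.mean(vals), rel=1e-12)


class TestMatchSegments:
    def test_identity_mapping(self):
        labels = (np.arange(64).reshape(8, 8) % 3).astype(int)
        m = match_segments(labels, labels)
        assert (m["iou"] == 1.0).all()
        assert m["label_a"].tolist() == m["label_b"].tolist()

    def test_disjoint_no_matches(self):
        a = np.zeros((6, 6), int)
        b = np.zeros((6, 6), int)
        a[0:2, 0:2] = 1
        b[4:6, 4:6] = 1
        assert len(match_segments(a, b)) == 0

    def test_one_pixel_translation_iou(self):
        a = np.zeros((20, 20), int)
        b = np.zeros((20, 20), int)
        a[5:10, 5:15] = 1          # 5 x 10 rectangle
        b[5:10, 6:16] = 1          # shifted 1 px along its length
        m = match_segments(a, b, min_iou=0.5)
        assert len(m) == 1
        assert m.loc[0, "iou"] == pytest.approx(45 / 55)


class TestFoldChange:
    @pytest.mark.parametrize(
        "series, expected",
        [([1, 2, 3], 3.0), ([5, 5, 5], 1.0), ([2, 1, 5, 4], 2.5)],
    )
    def test_values(self, series, expected):
        assert max_fold_change(series) == pytest.approx(expected)

    def test_nonpositive_baseline_flagged(self):
        assert np.isnan(max_fold_change([0, 2, 3]))

    def test_empty_rejected(self):
        with pytest.raises(ParameterError):
            max_fold_change([])


class TestNormalizePerTrial:
    def _table(self):
        return pd.DataFrame(
            {
                "trial": [0, 0, 0, 1, 1, 1],
                "mean_actin": [1.0, 2.0, 3.0, 10.0, 20.0, 30.0],
                "mean_abp": [2.0, 4.0, 6.0, 5.0, 10.0, 15.0],
            }
        )

    def test_scale_invariance(self):
        t = self._table()
        scaled = t.copy()
        scaled[["mean_actin", "mean_abp"]] *= 7.0
        a = normalize_per_trial(t)
        b = normalize_per_trial(scaled)
        assert np.allclose(a["mean_actin"], b["mean_actin"])

    def test_trial_medians_become_one(self):
        norm = normalize_per_trial(self._table())
        for _, group in norm.groupby("trial"):
            assert group["mean_actin"].median() == pytest.approx(1.0)
            assert group["mean_abp"].median() == pytest.approx(1.0)

    def test_gain_difference_removed(self):
        t = self._table()
        norm = normalize_per_trial(t)
        t0 = norm[norm.trial == 0]["mean_actin"].to_numpy()
        t1 = norm[norm.trial == 1]["mean_actin"].to_numpy()
        assert np.allclose(t0, t1)

    def test_zero_median_rejected(self):
        t = pd.DataFrame({"trial": [0, 0], "mean_actin": [0.0, 0.0],
                          "mean_abp": [1.0, 2.0]})
        with pytest.raises(DataError):
            normalize_per_trial(t)


class TestQuadrantFraction:
    def test_anticorrelated_hand_example(self):
        t = pd.DataFrame(
            {"mean_actin": [1, 2, 3, 4], "mean_abp": [4, 3, 2, 1]}
        )
        res = quadrant_fraction(t)
        assert res.fraction == pytest.approx(0.5)
        assert res.actin_median == 2.5 and res.abp_median == 2.5

    def test_concordant_ranks_give_zero(self):
        t = pd.DataFrame({"mean_actin": [1, 2, 3, 4], "mean_abp": [1, 2, 3, 4]})
        assert quadrant_fraction(t).fraction == 0.0

    def test_too_few_rows_rejected(self):
        with pytest.raises(ParameterError):
            quadrant_fraction(pd.DataFrame({"mean_actin": [1], "mean_abp": [1]}))


class TestLinfit:
    def test_exact_line(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        fit = linfit(x, 2 * x + 1)
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.r == pytest.approx(1.0)

    def test_constant_response(self):
        fit = linfit([1, 2, 3], [5, 5, 5])
        assert fit.slope == 0.0 and fit.r == 0.0

    def test_matches_normal_equations(self):
        x = np.array([0.3, 1.1, 2.7, 3.4, 5.2])
        y = np.array([1.9, 2.4, 4.8, 5.1, 8.3])
        sxx = ((x - x.mean()) ** 2).sum()
        sxy = ((x - x.mean()) * (y - y.mean())).sum()
        syy = ((y - y.mean()) ** 2).sum()
        slope = sxy / sxx
        intercept = y.mean() - slope * x.mean()
        r = sxy / np.sqrt(sxx * syy)
        fit = linfit(x, y)
        assert fit.slope == pytest.approx(slope, abs=1e-12)
        assert fit.intercept == pytest.approx(intercept, abs=1e-12)
        assert fit.r == pytest.approx(r, abs=1e-12)

    def test_degenerate_x_rejected(self):
        with pytest.raises(ParameterError):
            linfit([1, 1, 1], [1, 2, 3])


class TestWelch:
    def test_identical_groups(self):
        res = welch_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_hand_computed_example(self):
        res = welch_test([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])
        assert res.t == pytest.approx(-np.sqrt(3 / 2), abs=1e-4)
        assert res.df == pytest.approx(4.0, abs=1e-9)

    def test_matches_closed_form(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0, 1, 12)
        b = rng.normal(0.5, 2, 17)
        va, vb = a.var(ddof=1), b.var(ddof=1)
        se2 = va / len(a) + vb / len(b)
        t = (a.mean() - b.mean()) / np.sqrt(se2)
        df = se2**2 / (
            (va / len(a)) ** 2 / (len(a) - 1) + (vb / len(b)) ** 2 / (len(b) - 1)
        )
        from scipy import stats

        p = 2 * stats.t.sf(abs(t), df)
        res = welch_test(a, b)
        assert res.t == pytest.approx(t, abs=1e-12)
        assert res.df == pytest.approx(df, abs=1e-12)
        assert res.p == pytest.approx(p, abs=1e-12)

    def test_degenerate_groups_rejected(self):
        with pytest.raises(ParameterError):
            welch_test([1.0, 1.0], [1.0, 1.0])


class TestPairedCompare:
    def _tables(self):
        pre = pd.DataFrame(
            {
                "region_id": [0, 0, 1, 1],
                "ratio": [0.5, 0.7, 0.4, 0.6],
                "mean_actin": [10.0, 12.0, 9.0, 11.0],
                "ratio_valid": True,
            }
        )
        return pre

    def test_identical_tables_zero_deltas(self):
        pre = self._tables()
        delta, summary = paired_compare(pre, pre.copy())
        assert np.allclose(delta["delta_ratio"], 0.0)
        assert np.allclose(delta["delta_actin"], 0.0)
        assert summary["n_regions"] == 2

    def test_uniform_ratio_shift_recovered(self):
        pre = self._tables()
        post = pre.copy()
        post["ratio"] += 0.1
        delta, summary = paired_compare(pre, post)
        assert np.allclose(delta["delta_ratio"], 0.1)
        assert summary["mean_delta_ratio"] == pytest.approx(0.1)

    def test_unmatched_regions_listed(self):
        pre = self._tables()
        post = pre[pre.region_id == 0].copy()
        post["region_id"] = post["region_id"].replace({0: 0})
        extra = pre.copy()
        extra["region_id"] = extra["region_id"].replace({1: 2})
        delta, summary = paired_compare(pre, extra)
        assert summary["unmatched_keys"] == [1, 2]
        assert delta["region_id"].tolist() == [0]


class TestLineScanAndRoi:
    def test_flat_profile_no_peaks(self):
        assert count_peaks_linescan(np.zeros(50), 1.0) == 0

    def test_three_gaussians_counted(self):
        x = np.arange(300.0)
        profile = sum(
            100 * np.exp(-((x - c) ** 2) / (2 * 6**2)) for c in (50, 150, 250)
        )
        assert count_peaks_linescan(profile, 10.0) == 3

    def test_monotone_ramp_no_peaks(self):
        assert count_peaks_linescan(np.arange(40.0), 0.5) == 0

    def test_uniform_roi(self):
        assert measure_roi(np.full((50, 50), 7.0), (25, 25), (21, 6)) == 7.0

    def test_gradient_roi_matches_loop(self):
        img = np.add.outer(np.arange(40.0), np.arange(40.0) * 0.5)
        got = measure_roi(img, (20, 20), (21, 6))
        acc = []
        for r in range(20 - 10, 20 - 10 + 21):
            for c in range(20 - 3, 20 - 3 + 6):
                acc.append(img[r, c])
        assert got == pytest.approx(np.mean(acc), rel=1e-12)

    def test_single_pixel_box(self):
        img = np.arange(25.0).reshape(5, 5)
        assert measure_roi(img, (2, 3), (1, 1)) == img[2, 3]

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ParameterError):
            measure_roi(np.zeros((10, 10)), (1, 1), (21, 6))


class TestPfcCensus:
    def test_paired_fraction(self):
        records = [{"type": "paired", "last_intact_frame": 20}] * 9 + [
            {"type": "single", "last_intact_frame": 20}
        ]
        res = pfc_census(records)
        assert res["paired_fraction"] == pytest.approx(0.9)

    def test_constant_rupture_times(self):
        records = [{"type": "paired", "last_intact_frame": 23}] * 6
        res = pfc_census(records, frame_interval=2.0, reference_frame=10)
        assert res["median_rupture_s"] == pytest.approx(26.0)

    def test_survival_curve_monotone(self):
        times = [12, 15, 20, 30, 45, 60]
        records = [
            {"type": "paired", "last_intact_frame": 10 + t / 2} for t in times
        ]
        res = pfc_census(records)
        surv = res["survival"]["survival"].to_numpy()
        assert (np.diff(surv) <= 0).all()

    def test_negative_times_rejected(self):
        with pytest.raises(DataError):
            pfc_census([{"type": "paired", "last_intact_frame": 5}])
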