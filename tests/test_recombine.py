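import numpy as np
import pytest

from conftest import random_peaks
from homolseries import DetectionParams, EpsilonModel, Peak, PlantedSeriesSpec, detect_series, generate
from homolseries.recombine import (
    filter_subtuples,
    merge_step,
    smoothing_spline_fit,
    spline_check,
)
from homolseries.seriesdef import SeriesContext
from homolseries.simulate import planted_member_ids

CH2 = 14.015650064

PARAMS = DetectionParams(
    dmz_min=10.0, dmz_max=60.0, drt_min=5.0, drt_max=120.0,
    ddrt_max=20.0, n_min=3, epsilon=EpsilonModel("absolute", 0.002),
)


def chain_ctx(n=4, rt_step=30.0, params=PARAMS):
    peaks = [
        Peak(i + 1, 200.0 + i * CH2, 300.0 + i * rt_step, 1.0) for i in range(n)
    ]
    return SeriesContext(peaks, params)


class TestSmoothingSpline:
    @pytest.mark.parametrize("lam", [1e-4, 1.0, 100.0])
    def test_matches_scipy_for_five_plus_points(self, lam):
        from scipy.interpolate import make_smoothing_spline

        rng = np.random.default_rng(5)
        x = np.sort(rng.uniform(0, 10, 9))
        y = np.sin(x) + rng.normal(0, 0.1, 9)
        ours = smoothing_spline_fit(x, y, lam)
        ref = make_smoothing_spline(x, y, lam=lam)(x)
        assert np.allclose(ours, ref, atol=1e-8)

    def test_zero_penalty_interpolates(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([5.0, 1.0, 4.0, 2.0])
        assert np.array_equal(smoothing_spline_fit(x, y, 0.0), y)

    def test_large_penalty_approaches_straight_line(self):
        x = np.linspace(0, 10, 8)
        y = x * 2.0 + 1.0
        # a line has zero curvature, so any penalty leaves it untouched
        assert np.allclose(smoothing_spline_fit(x, y, 1e6), y, atol=1e-6)


class TestSplineCheck:
    def test_monotone_linear_trend_passes_interpolation(self):
        mz = np.arange(4, dtype=float)
        rt = 10.0 + 3.0 * mz
        ok, r2 = spline_check(mz, rt, 0.0, 0.9)
        assert ok and r2 == pytest.approx(1.0)

    def test_constant_rt_passes_by_convention(self):
        ok, r2 = spline_check(np.arange(5, dtype=float), np.full(5, 7.0), 10.0, 0.99)
        assert ok and r2 == 1.0

    def test_gross_outlier_fails_at_high_penalty(self):
        mz = np.arange(6, dtype=float)
        rt = np.array([0.0, 3.0, 6.0, 9.0, 60.0, 15.0])
        ok, r2 = spline_check(mz, rt, 1e4, 0.9)
        assert not ok and r2 < 0.9

    def test_triplets_skip_the_check(self):
        ok, r2 = spline_check(np.arange(3, dtype=float), np.array([0.0, 50.0, 0.0]), 1e4, 0.99)
        assert ok and r2 is None


class TestMergeStep:
    def test_overlapping_triplets_merge(self):
        ctx = chain_ctx(4)
        s4, retained = merge_step({(0, 1, 2), (1, 2, 3)}, ctx)
        assert s4 == {(0, 1, 2, 3)}
        assert retained == set()

    def test_disjoint_triplets_stay(self):
        ctx = chain_ctx(8)
        s3 = {(0, 1, 2), (4, 5, 6)}
        s4, retained = merge_step(s3, ctx)
        assert s4 == set()
        assert retained == s3

    def test_branching_keeps_both_extensions(self):
        # two isobaric-like successors for the same triplet
        peaks = [
            Peak(1, 200.0, 300.0, 1.0),
            Peak(2, 200.0 + CH2, 330.0, 1.0),
            Peak(3, 200.0 + 2 * CH2, 360.0, 1.0),
            Peak(4, 200.0 + 3 * CH2, 388.0, 1.0),
            Peak(5, 200.0 + 3 * CH2 + 0.0005, 392.0, 1.0),
        ]
        ctx = SeriesContext(peaks, PARAMS)
        s3 = {(0, 1, 2), (1, 2, 3), (1, 2, 4)}
        s4, retained = merge_step(s3, ctx)
        assert s4 == {(0, 1, 2, 3), (0, 1, 2, 4)}
        assert retained == set()

    def test_spline_failure_blocks_merge(self):
        peaks = [
            Peak(1, 200.0, 300.0, 1.0),
            Peak(2, 200.0 + CH2, 330.0, 1.0),
            Peak(3, 200.0 + 2 * CH2, 345.0, 1.0),
            Peak(4, 200.0 + 3 * CH2, 330.0, 1.0),
        ]
        params = PARAMS.with_(drt_min=-30.0, spline_lambda=1e5, r2_min=0.95)
        ctx = SeriesContext(peaks, params)
        s4, retained = merge_step({(0, 1, 2), (1, 2, 3)}, ctx)
        assert s4 == set()
        assert retained == {(0, 1, 2), (1, 2, 3)}


class TestFilterSubtuples:
    def test_regular_omission_removed(self):
        sets = {5: {(1, 2, 3, 4, 5)}, 3: {(1, 3, 5)}}
        out = filter_subtuples(sets)
        assert out[3] == set()
        assert out[5] == {(1, 2, 3, 4, 5)}

    def test_irregular_subset_kept(self):
        sets = {5: {(1, 2, 3, 4, 5)}, 3: {(1, 2, 4)}}
        assert filter_subtuples(sets)[3] == {(1, 2, 4)}

    def test_offset_progressions_removed(self):
        sets = {7: {(1, 2, 3, 4, 5, 6, 7)}, 3: {(2, 4, 6), (3, 5, 7), (1, 4, 7)}}
        assert filter_subtuples(sets)[3] == set()

    def test_no_supertuple_nothing_removed(self):
        sets = {3: {(1, 3, 5)}}
        assert filter_subtuples(sets)[3] == {(1, 3, 5)}

    def test_four_tuples_do_not_trigger_filtering(self):
        sets = {4: {(1, 2, 3, 4)}, 3: {(1, 3, 5)}}
        assert filter_subtuples(sets)[3] == {(1, 3, 5)}


class TestDetectSeries:
    def test_planted_series_recovered_among_background(self):
        spec = PlantedSeriesSpec(unit="CH2", start_mz=300.0, length=8,
                                 rt_start=300.0, rt_increment=40.0, rt_decay=0.95)
        peaks, truth = generate([spec], n_background=300, seed=3)
        series = detect_series(peaks, PARAMS.with_(n_min=5))
        assert planted_member_ids(truth, 0) in [s.peak_ids for s in series]

    def test_n_min_filters_short_series(self):
        peaks = [Peak(i + 1, 200.0 + i * CH2, 300.0 + 30 * i, 1.0) for i in range(3)]
        assert detect_series(peaks, PARAMS.with_(n_min=5)) == []
        found = detect_series(peaks, PARAMS.with_(n_min=3))
        assert [s.peak_ids for s in found] == [(1, 2, 3)]

    def test_two_series_sharing_a_peak(self):
        # CH2 chain and C2H4O chain crossing in one peak
        shared_mz = 400.0
        a = [shared_mz + k * CH2 for k in range(-2, 3)]
        b = [shared_mz + k * 44.026214747 for k in range(-2, 3)]
        # both chains pass RT 360 at the shared peak
        rts_a = [300.0 + 30 * k for k in range(5)]
        rts_b = [310.0 + 25 * k for k in range(5)]
        mzs = a + [m for m in b if m != shared_mz]
        rts = rts_a + [r for m, r in zip(b, rts_b) if m != shared_mz]
        order = np.argsort(mzs)
        peaks = [Peak(i + 1, float(np.array(mzs)[j]), float(np.array(rts)[j]), 1.0)
                 for i, j in enumerate(order)]
        series = detect_series(peaks, PARAMS.with_(n_min=5, ddrt_max=30.0,
                                                   drt_min=-60.0))
        assert len(series) >= 2
        shared_id = [p.id for p in peaks if p.mz == shared_mz][0]
        containing = [s for s in series if shared_id in s.peak_ids]
        assert len(containing) >= 2

    def test_gap_splits_series_into_flanks(self):
        spec = PlantedSeriesSpec(unit="CH2", start_mz=300.0, length=13,
                                 rt_start=300.0, rt_increment=30.0, gaps=(6,))
        peaks, truth = generate([spec], n_background=0, seed=0)
        series = detect_series(peaks, PARAMS.with_(n_min=5))
        tuples = [s.peak_ids for s in series]
        members = planted_member_ids(truth, 0)
        # the two flanking fragments around the gap ...
        assert members[:6] in tuples
        assert members[6:] in tuples
        # ... plus one double-spacing series bridging it (2*CH2 <= dmz_max)
        others = [s for s in series
                  if s.peak_ids not in (members[:6], members[6:])]
        assert [round(s.mean_dmz, 2) for s in others] == [round(2 * CH2, 2)]

    def test_double_spacing_can_bridge_a_gap(self):
        # 2 * CH2 = 28.03 Th <= dmz_max, so a sparser series may bridge
        spec = PlantedSeriesSpec(unit="CH2", start_mz=300.0, length=13,
                                 rt_start=300.0, rt_increment=30.0, gaps=(6,))
        peaks, _ = generate([spec], n_background=0, seed=0)
        params = PARAMS.with_(n_min=5, ddrt_max=35.0)
        series = detect_series(peaks, params)
        assert any(
            np.isclose(s.mean_dmz, 2 * CH2, atol=0.01) for s in series
        )

    def test_emitted_series_satisfy_definition(self, loose_params):
        rng = np.random.default_rng(23)
        peaks = random_peaks(rng, 150)
        params = loose_params.with_(ddrt_max=150.0)
        ctx = SeriesContext(peaks, params)
        pos = {int(pid): i for i, pid in enumerate(ctx.ids)}
        for s in detect_series(peaks, params):
            idxs = tuple(pos[pid] for pid in s.peak_ids)
            assert ctx.tuple_ok(idxs)

    def test_deterministic_ordering_and_ids(self):
        spec = PlantedSeriesSpec(unit="CH2", start_mz=300.0, length=8,
                                 rt_start=300.0, rt_increment=40.0)
        peaks, _ = generate([spec], n_background=200, seed=5)
        a = detect_series(peaks, PARAMS.with_(n_min=5))
        b = detect_series(peaks, PARAMS.with_(n_min=5))
        assert a == b
        assert [s.series_id for s in a] == list(range(1, len(a) + 1))
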