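import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from conftest import random_accel_tracks
from helpers import (
    naive_detect,
    naive_moving_average,
    naive_quantile,
    naive_window_samples,
)

from gaitassist.assist_detector import (
    DetectorParams,
    detect,
    free_acceleration,
    mark_outliers,
    moving_average,
    resultant_acceleration,
    trim_stationary,
    tukey_threshold,
)
from gaitassist.timeseries_io import SignalTrack


class TestResultantAcceleration:
    def test_3_4_5(self, track_factory):
        n = 10
        out = resultant_acceleration(
            track_factory(np.full(n, 3.0)),
            track_factory(np.full(n, 4.0)),
            track_factory(np.zeros(n)),
        )
        np.testing.assert_allclose(out.samples, 5.0)

    def test_all_zero(self, track_factory):
        z = track_factory(np.zeros(5))
        np.testing.assert_allclose(resultant_acceleration(z, z, z).samples, 0.0)

    def test_mismatch_rejected(self, track_factory):
        with pytest.raises(ValueError):
            resultant_acceleration(
                track_factory(np.zeros(5)),
                track_factory(np.zeros(6)),
                track_factory(np.zeros(5)),
            )

    @pytest.mark.parametrize("seed", range(5))
    def test_rotation_invariance(self, seed, track_factory):
        rng = np.random.default_rng(seed)
        xyz = rng.normal(0, 2, (3, 200))
        rot = Rotation.random(rng=rng).as_matrix()
        rotated = rot @ xyz
        a = resultant_acceleration(*(track_factory(row) for row in xyz))
        b = resultant_acceleration(*(track_factory(row) for row in rotated))
        np.testing.assert_allclose(a.samples, b.samples, atol=1e-10)


class TestFreeAcceleration:
    def test_pure_gravity_vanishes(self, track_factory):
        out = free_acceleration(track_factory(np.full(100, 9.81)))
        np.testing.assert_allclose(out.samples, 0.0, atol=1e-12)

    def test_two_samples(self, track_factory):
        out = free_acceleration(track_factory([1.0, 3.0]))
        np.testing.assert_allclose(out.samples, [-1.0, 1.0])

    def test_zero_mean_unchanged(self, track_factory, rng):
        x = rng.normal(size=500)
        x -= x.mean()
        out = free_acceleration(track_factory(x))
        np.testing.assert_allclose(out.samples, x, atol=1e-12)
        assert abs(out.samples.mean()) < 1e-9


class TestTrimStationary:
    def test_known_change_points(self, track_factory):
        fs = 60.0
        rng = np.random.default_rng(7)
        quiet = lambda n: rng.normal(0, 0.01, n)
        walk = 1.5 * np.sin(2 * np.pi * 2.0 * np.arange(int(20 * fs)) / fs)
        x = np.concatenate([quiet(int(5 * fs)), walk + rng.normal(0, 0.2, walk.size),
                            quiet(int(5 * fs))])
        _, kept = trim_stationary(track_factory(x, fs=fs))
        assert kept[0] == pytest.approx(5.0, abs=1.0)
        assert kept[1] == pytest.approx(25.0, abs=1.0)

    def test_no_tails_identity(self, track_factory):
        fs = 60.0
        x = np.sin(2 * np.pi * 2.0 * np.arange(int(10 * fs)) / fs)
        trimmed, kept = trim_stationary(track_factory(x, fs=fs))
        assert trimmed.n == x.size
        assert kept == (0.0, pytest.approx((x.size - 1) / fs))

    def test_manual_bounds(self, track_factory):
        tr = track_factory(np.arange(100.0), fs=10.0)
        trimmed, kept = trim_stationary(tr, manual=(2.0, 7.0))
        assert kept == (pytest.approx(2.0), pytest.approx(7.0))
        assert trimmed.samples[0] == 20.0
        assert trimmed.samples[-1] == 70.0

    def test_manual_bounds_outside(self, track_factory):
        tr = track_factory(np.arange(100.0), fs=10.0)
        with pytest.raises(ValueError):
            trim_stationary(tr, manual=(2.0, 20.0))


class TestMovingAverage:
    def test_constant_preserved(self, track_factory):
        tr = track_factory(np.full(50, 4.2), fs=10.0)
        np.testing.assert_allclose(moving_average(tr, 1.7).samples, 4.2, atol=1e-12)

    def test_three_sample_window(self, track_factory):
        tr = track_factory([0, 0, 3, 0, 0], fs=1.0)
        out = moving_average(tr, 3.0)
        assert out.samples[2] == pytest.approx(1.0)
        np.testing.assert_allclose(out.samples, [0, 1, 1, 1, 0])

    def test_single_sample_window_identity(self, track_factory, rng):
        x = rng.normal(size=40)
        tr = track_factory(x, fs=1.0)
        np.testing.assert_allclose(moving_average(tr, 1.0).samples, x)

    def test_window_longer_than_record(self, track_factory):
        with pytest.raises(ValueError, match="longer"):
            moving_average(track_factory(np.zeros(10), fs=1.0), 20.0)

    def test_even_window_forced_odd(self, track_factory):
        # round(0.4 * 10) = 4 -> 5 samples
        tr = track_factory([0, 0, 5, 0, 0, 0], fs=10.0)
        out = moving_average(tr, 0.4)
        assert out.samples[2] == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_naive_loops(self, seed, track_factory):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 400))
        fs = float(rng.uniform(10, 120))
        delta = float(rng.uniform(1.5 / fs, (n - 1) / fs))
        x = rng.normal(size=n)
        w = naive_window_samples(delta, fs)
        if w > n:
            return
        out = moving_average(track_factory(x, fs=fs), delta)
        np.testing.assert_allclose(out.samples, naive_moving_average(list(x), w), atol=1e-10)


class TestTukeyThreshold:
    def test_alpha_zero_gives_q3(self, track_factory, rng):
        tr = track_factory(rng.normal(size=501))
        threshold, _, q3, _ = tukey_threshold(tr, 0.0)
        assert threshold == pytest.approx(q3)

    def test_linear_grid(self, track_factory):
        tr = track_factory(np.linspace(0.0, 100.0, 101), fs=1.0)
        threshold, q1, q3, iqr = tukey_threshold(tr, 1.0)
        assert (q1, q3, iqr) == (pytest.approx(25.0), pytest.approx(75.0), pytest.approx(50.0))
        assert threshold == pytest.approx(125.0)

    def test_constant_signal(self, track_factory):
        tr = track_factory(np.full(100, 2.5))
        threshold, _, _, iqr = tukey_threshold(tr, 3.0)
        assert iqr == pytest.approx(0.0)
        assert threshold == pytest.approx(2.5)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_naive_quantiles(self, seed, track_factory):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=int(rng.integers(5, 300)))
        _, q1, q3, _ = tukey_threshold(track_factory(x), 1.0)
        assert q1 == pytest.approx(naive_quantile(list(x), 0.25), rel=1e-12, abs=1e-12)
        assert q3 == pytest.approx(naive_quantile(list(x), 0.75), rel=1e-12, abs=1e-12)

    def test_hinges_method(self, track_factory):
        # n = 7: hinges are medians of {1..4} and {4..7}
        tr = track_factory([1, 2, 3, 4, 5, 6, 7], fs=1.0)
        _, q1, q3, iqr = tukey_threshold(tr, 0.0, quantile_method="hinges")
        assert (q1, q3) == (pytest.approx(2.5), pytest.approx(5.5))


class TestMarkOutliers:
    def test_below_threshold_nothing(self, track_factory):
        assert mark_outliers(track_factory([0, 0, 0.5, 0], fs=1.0), 1.0) == ()

    def test_single_run(self, track_factory):
        out = mark_outliers(track_factory([0, 0, 2, 2, 0], fs=1.0), 1.0)
        assert out == ((2.0, 4.0),)

    def test_two_runs_in_order(self, track_factory):
        out = mark_outliers(track_factory([0, 2, 0, 0, 3, 3, 0], fs=1.0), 1.0)
        assert out == ((1.0, 2.0), (4.0, 6.0))

    def test_strictly_above(self, track_factory):
        assert mark_outliers(track_factory([1.0, 1.0], fs=1.0), 1.0) == ()

    def test_positive_width_even_for_single_sample(self, track_factory):
        (onset, offset), = mark_outliers(track_factory([0, 5, 0], fs=10.0), 1.0)
        assert offset > onset


class TestDetect:
    @pytest.mark.parametrize("seed", range(10))
    def test_matches_naive_pipeline(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(400, 2000))
        fs = float(rng.choice([30.0, 60.0, 100.0]))
        tracks = random_accel_tracks(rng, n, fs)
        alpha = float(rng.uniform(0.0, 3.0))
        delta = float(rng.uniform(0.2, 3.0))
        result = detect(tracks, DetectorParams(alpha, delta))
        spans, threshold, quartiles, _ = naive_detect(
            list(tracks[0].samples), list(tracks[1].samples), list(tracks[2].samples),
            fs, alpha, delta,
        )
        assert result.threshold == pytest.approx(threshold, rel=1e-9, abs=1e-9)
        assert len(result.intervals) == len(spans)
        for got, want in zip(result.intervals, spans):
            assert got[0] == pytest.approx(want[0], abs=1e-9)
            assert got[1] == pytest.approx(want[1], abs=1e-9)

    @pytest.mark.parametrize("seed", range(3))
    def test_marked_time_monotone_in_alpha(self, seed):
        rng = np.random.default_rng(100 + seed)
        tracks = random_accel_tracks(rng, 3000, 60.0)
        marked = []
        for alpha in np.arange(0.0, 3.01, 0.25):
            res = detect(tracks, DetectorParams(float(alpha), 1.5))
            marked.append(sum(b - a for a, b in res.intervals))
        assert all(a >= b - 1e-12 for a, b in zip(marked, marked[1:]))

    def test_constant_record_no_outliers(self, track_factory):
        tr = track_factory(np.full(600, 2.0), fs=60.0)
        res = detect((tr, tr, tr), DetectorParams(0.5, 1.0))
        assert res.intervals == ()

    def test_rotation_invariance(self):
        rng = np.random.default_rng(42)
        tracks = random_accel_tracks(rng, 3000, 60.0)
        xyz = np.vstack([tr.samples for tr in tracks])
        rot = Rotation.random(rng=rng).as_matrix()
        rotated = tuple(SignalTrack(row, 60.0) for row in rot @ xyz)
        a = detect(tracks, DetectorParams(1.0, 2.0))
        b = detect(rotated, DetectorParams(1.0, 2.0))
        assert a.threshold == pytest.approx(b.threshold, rel=1e-9)
        assert len(a.intervals) == len(b.intervals)
        np.testing.assert_allclose(np.asarray(a.intervals), np.asarray(b.intervals), atol=1e-6)

    def test_short_spike_suppressed_long_event_kept(self):
        # a large single-sample spike vanishes into a 2 s average (its
        # averaged contribution, height / window, stays under the fence),
        # while a sustained 2 s elevation of modest height is detected
        fs = 60.0
        rng = np.random.default_rng(3)
        n = int(60 * fs)
        base = rng.normal(0, 0.3, n)
        spike = base.copy()
        spike[int(30 * fs)] += 20.0
        sustained = base.copy()
        sustained[int(30 * fs) : int(32 * fs)] += 5.0
        grav = np.full(n, 9.81)
        zeros = np.zeros(n)
        params = DetectorParams(1.0, 2.0)
        res_spike = detect(
            (SignalTrack(zeros, fs), SignalTrack(zeros, fs), SignalTrack(grav + spike, fs)),
            params,
        )
        res_sustained = detect(
            (SignalTrack(zeros, fs), SignalTrack(zeros, fs), SignalTrack(grav + sustained, fs)),
            params,
        )
        assert res_spike.intervals == ()
        assert len(res_sustained.intervals) == 1
        onset, offset = res_sustained.intervals[0]
        assert 28.0 < onset < 32.0 and 30.0 < offset < 34.0

    def test_result_invariants(self):
        rng = np.random.default_rng(11)
        tracks = random_accel_tracks(rng, 4000, 60.0)
        res = detect(tracks, DetectorParams(1.0, 1.0))
        q1, q3, iqr = res.quartiles
        assert iqr == pytest.approx(q3 - q1)
        assert res.threshold == pytest.approx(q3 + res.params.alpha * iqr)
        flat = [t for iv in res.intervals for t in iv]
        assert flat == sorted(flat)  # disjoint + sorted
        assert all(b > a for a, b in res.intervals)
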