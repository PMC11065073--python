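"""ΔF/F₀ trace analytics: extraction, kinetics, statistics, latency."""

import math

import numpy as np
import pytest
from scipy import stats

from catflux.synth import LN19, gen_dual_channel, gen_sensor_trace
from catflux.traces import (
    NoResponseError,
    bootstrap_ci,
    compare_groups,
    dff,
    extract_roi_traces,
    max_response,
    peak_latency,
    rise_time_5_95,
)


class TestExtract:
    def test_uniform_movie_gives_constant_trace(self):
        frames = np.full((10, 4, 4), 7.0)
        labels = np.zeros((4, 4), int)
        labels[1:3, 1:3] = 1
        roi = extract_roi_traces(frames, labels, frame_interval=0.1)
        assert np.allclose(roi.traces[0], 7.0)

    def test_two_rois_follow_label_values(self):
        labels = np.zeros((6, 6), int)
        labels[:3] = 1
        labels[3:] = 2
        frames = np.repeat(labels[None].astype(float), 5, axis=0)
        roi = extract_roi_traces(frames, labels, frame_interval=0.05)
        assert list(roi.roi_ids) == [1, 2]
        assert np.allclose(roi.traces[0], 1.0)
        assert np.allclose(roi.traces[1], 2.0)

    def test_noise_averages_down_with_roi_size(self, rng):
        n_px, n_frames, sigma = 400, 200, 2.0
        programmed = 50.0 + 10.0 * np.sin(np.linspace(0, 6, n_frames))
        frames = programmed[:, None, None] + rng.normal(
            0, sigma, size=(n_frames, 20, 20)
        )
        labels = np.ones((20, 20), int)
        roi = extract_roi_traces(frames, labels, frame_interval=0.05)
        rms = np.sqrt(np.mean((roi.traces[0] - programmed) ** 2))
        assert rms < 3.0 * sigma / math.sqrt(n_px)

    def test_empty_expected_label_dropped_with_warning(self):
        frames = np.ones((5, 3, 3))
        labels = np.zeros((3, 3), int)
        labels[0, 0] = 2
        with pytest.warns(UserWarning, match="dropped"):
            roi = extract_roi_traces(
                frames, labels, frame_interval=0.1, expected_ids=[1, 2]
            )
        assert list(roi.roi_ids) == [2]


class TestDff:
    def test_constant_fluorescence_is_zero_everywhere(self):
        t = np.arange(20) * 0.1
        d = dff(np.full(20, 5.0), t, baseline_window=(0.0, 0.5))
        assert np.allclose(d.dff, 0.0)
        assert d.fo == 5.0

    def test_signed_percent_arithmetic(self):
        t = np.arange(10) * 1.0
        f = np.array([10.0] * 5 + [5.0, 30.0, 10.0, 10.0, 10.0])
        d = dff(f, t, baseline_window=(0.0, 4.0))
        assert d.dff[5] == pytest.approx(-50.0)
        assert d.dff[6] == pytest.approx(200.0)

    def test_scale_invariance(self):
        t = np.arange(30) * 0.5
        f = 10.0 + np.sin(t)
        a = dff(f, t, baseline_window=(0.0, 3.0))
        b = dff(4.2 * f, t, baseline_window=(0.0, 3.0))
        assert np.allclose(a.dff, b.dff)

    def test_nonpositive_fo_rejected(self):
        t = np.arange(10) * 1.0
        with pytest.raises(ValueError, match="Fo"):
            dff(np.zeros(10), t, baseline_window=(0.0, 5.0))

    def test_short_baseline_window_rejected(self):
        t = np.arange(10) * 1.0
        with pytest.raises(ValueError, match="frames"):
            dff(np.ones(10), t, baseline_window=(0.0, 2.0))


class TestMaxResponse:
    def test_inverse_polarity_takes_minimum(self):
        t = np.arange(9) * 1.0
        f = 10.0 * (1.0 + np.array([0, 0, 0, 0, 0, -10, -60, -55, -50]) / 100.0)
        d = dff(f, t, baseline_window=(0.0, 4.0), polarity="inverse")
        assert max_response(d, smooth_frames=1) == pytest.approx(-60.0)

    def test_direct_polarity_takes_maximum(self):
        t = np.arange(8) * 1.0
        f = 10.0 * (1.0 + np.array([0, 0, 0, 0, 0, 40, 35, 30]) / 100.0)
        d = dff(f, t, baseline_window=(0.0, 4.0))
        assert max_response(d, smooth_frames=1) == pytest.approx(40.0)

    def test_smoothing_suppresses_single_frame_spikes(self):
        t = np.arange(40) * 0.1
        f = np.full(40, 100.0)
        f[25] = 160.0  # lone artifact frame
        d = dff(f, t, baseline_window=(0.0, 1.0))
        assert max_response(d) < 30.0

    def test_programmed_inverse_plateau_recovered(self):
        t, f, truth = gen_sensor_trace(
            plateau_pct=-58.7, rise_time_s=0.96, polarity="inverse",
            noise_sigma_pct=1.0, duration=30.0, seed=5,
        )
        d = dff(f, t, stimulus_time=truth["stimulus_time_s"], polarity="inverse")
        # 5-frame smoothing keeps the extremum's noise bias below 2 dff points
        assert max_response(d, smooth_frames=5) == pytest.approx(-58.7, abs=2.0)


class TestRiseTime:
    def test_linear_ramp_rise_time(self):
        t = np.arange(0.0, 4.0, 0.01)
        f = 100.0 * (1.0 + np.clip(t - 1.0, 0.0, 1.0) * 0.5)
        d = dff(f, t, stimulus_time=1.0)
        res = rise_time_5_95(d, stimulus_time=1.0)
        assert res.rise_time_5_95_s == pytest.approx(0.9, abs=0.02)

    def test_exponential_rise_time_is_tau_ln19(self):
        tau = 0.4
        t = np.arange(0.0, 12.0, 0.005)
        mag = np.where(t >= 1.0, 1.0 - np.exp(-(t - 1.0) / tau), 0.0)
        f = 100.0 * (1.0 + 0.5 * mag)
        d = dff(f, t, stimulus_time=1.0)
        res = rise_time_5_95(d, stimulus_time=1.0)
        assert res.rise_time_5_95_s == pytest.approx(tau * LN19, rel=0.01)

    def test_generator_hits_requested_rise_time(self):
        t, f, truth = gen_sensor_trace(
            plateau_pct=-60.0, rise_time_s=0.96, sample_rate=20.0,
            duration=20.0, seed=0,
        )
        d = dff(f, t, stimulus_time=truth["stimulus_time_s"], polarity="inverse")
        res = rise_time_5_95(d, stimulus_time=truth["stimulus_time_s"])
        assert res.rise_time_5_95_s == pytest.approx(0.96, abs=1.0 / 20.0)

    def test_rise_time_invariant_under_dff_scaling(self):
        t, f, truth = gen_sensor_trace(plateau_pct=40.0, polarity="direct", seed=1)
        d = dff(f, t, stimulus_time=truth["stimulus_time_s"])
        d_scaled = type(d)(
            t=d.t, dff=2.5 * d.dff, fo=d.fo,
            baseline_window=d.baseline_window, polarity=d.polarity,
        )
        a = rise_time_5_95(d, truth["stimulus_time_s"])
        b = rise_time_5_95(d_scaled, truth["stimulus_time_s"])
        assert b.rise_time_5_95_s == pytest.approx(a.rise_time_5_95_s, abs=1e-9)

    def test_no_response_below_noise_floor(self, rng):
        t = np.arange(0.0, 20.0, 0.05)
        f = 100.0 + rng.normal(0, 1.0, size=len(t))
        d = dff(f, t, stimulus_time=5.0)
        with pytest.raises(NoResponseError, match="no response"):
            rise_time_5_95(d, stimulus_time=5.0)


class TestBootstrap:
    def test_degenerate_constant_sample(self):
        ci = bootstrap_ci([3.0] * 10, seed=0)
        assert (ci.lo, ci.estimate, ci.hi) == (3.0, 3.0, 3.0)

    def test_same_seed_reproduces_interval(self, rng):
        x = rng.normal(size=50)
        a = bootstrap_ci(x, seed=42)
        b = bootstrap_ci(x, seed=42)
        assert (a.lo, a.hi) == (b.lo, b.hi)

    def test_interval_brackets_estimate(self, rng):
        x = rng.exponential(size=80)
        ci = bootstrap_ci(x, seed=3)
        assert ci.lo <= ci.estimate <= ci.hi

    def test_width_matches_normal_theory(self, rng):
        x = rng.normal(0.0, 1.0, size=200)
        ci = bootstrap_ci(x, n_boot=10_000, seed=7)
        analytic = 2.0 * 1.96 * x.std(ddof=1) / math.sqrt(len(x))
        assert abs((ci.hi - ci.lo) - analytic) / analytic < 0.15

    def test_width_shrinks_with_sample_size(self, rng):
        pop = rng.normal(0.0, 1.0, size=2000)
        small = bootstrap_ci(pop[:50], seed=1)
        large = bootstrap_ci(pop[:800], seed=1)
        assert (large.hi - large.lo) < (small.hi - small.lo)

    def test_seed_is_mandatory(self):
        with pytest.raises(ValueError, match="seed"):
            bootstrap_ci([1.0, 2.0, 3.0])


class TestLatency:
    def _as_dff(self, t, f, stim, polarity="direct"):
        return dff(f, t, stimulus_time=stim, polarity=polarity)

    def test_identical_channels_have_zero_lag(self):
        t, fa, fb, truth = gen_dual_channel(lag_s=0.0, seed=0)
        a = self._as_dff(t, fa, 2.0)
        b = self._as_dff(t, fa, 2.0)
        assert peak_latency(a, b).lag_s == 0.0

    def test_programmed_lag_recovered_with_sign(self):
        t, fa, fb, truth = gen_dual_channel(lag_s=3.12, seed=1)
        a = self._as_dff(t, fa, 2.0)
        b = self._as_dff(t, fb, 2.0)
        assert peak_latency(a, b).lag_s == pytest.approx(-3.12, abs=0.05)

    def test_swapping_channels_negates_lag(self):
        t, fa, fb, truth = gen_dual_channel(lag_s=2.0, noise_sigma_pct=0.5, seed=2)
        a = self._as_dff(t, fa, 2.0)
        b = self._as_dff(t, fb, 2.0)
        assert peak_latency(a, b).lag_s == pytest.approx(
            -peak_latency(b, a).lag_s
        )

    def test_time_reversal_negates_lag(self):
        t, fa, fb, truth = gen_dual_channel(lag_s=1.5, seed=3)
        a = self._as_dff(t, fa, 2.0)
        b = self._as_dff(t, fb, 2.0)
        ar = type(a)(t=t, dff=a.dff[::-1], fo=a.fo,
                     baseline_window=a.baseline_window, polarity=a.polarity)
        br = type(b)(t=t, dff=b.dff[::-1], fo=b.fo,
                     baseline_window=b.baseline_window, polarity=b.polarity)
        assert peak_latency(ar, br).lag_s == pytest.approx(
            -peak_latency(a, b).lag_s
        )

    def test_mismatched_time_bases_rejected(self):
        t, fa, fb, _ = gen_dual_channel(lag_s=1.0, seed=4)
        a = self._as_dff(t, fa, 2.0)
        b = self._as_dff(t + 0.5, fb, 2.5)
        with pytest.raises(ValueError, match="time base"):
            peak_latency(a, b)


class TestCompareGroups:
    def test_identical_groups(self):
        a = [1.0, 2.0, 3.0, 4.0]
        t_stat, p = compare_groups(a, list(a))
        assert t_stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_swap_antisymmetry(self, rng):
        a = rng.normal(0, 1, 30)
        b = rng.normal(0.5, 2, 40)
        t1, p1 = compare_groups(a, b)
        t2, p2 = compare_groups(b, a)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_matches_scipy_welch(self, rng):
        a = rng.normal(0, 1, 25)
        b = rng.normal(1, 3, 35)
        expected = stats.ttest_ind(a, b, equal_var=False)
        got = compare_groups(a, b)
        assert got == pytest.approx((expected.statistic, expected.pvalue))

    def test_degenerate_zero_variance_unequal_means(self):
        with pytest.warns(UserWarning, match="degenerate"):
            t_stat, p = compare_groups([1.0, 1.0], [2.0, 2.0])
        assert math.isinf(t_stat) and p == 0.0

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([1.0], [1.0, 2.0])
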