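"""Activation mapping, arrival times and wavefront speed."""

import numpy as np
import pytest

from catflux.front import (
    ActivationMovie,
    ActivationParams,
    FrontUnresolvedError,
    activation_fraction,
    arrival_time_map,
    binarize,
    front_speed,
)
from catflux.synth import WaveGroundTruth, gen_wave_movie


def step_movie(step_frame=5, n_frames=12, lo=50.0, hi=100.0):
    frames = np.full((n_frames, 3, 3), hi)
    frames[step_frame:] = lo
    return ActivationMovie(frames=frames, frame_interval=0.05, pixel_size=1.0)


class TestActivation:
    def test_step_pixel_jumps_zero_to_one(self):
        movie = step_movie()
        a = activation_fraction(movie, ActivationParams(baseline_frames=3))
        assert np.allclose(a[:5], 0.0)
        assert np.allclose(a[5:], 1.0)

    def test_normalization_contract(self, rng):
        frames = 100.0 + rng.normal(0, 5.0, size=(20, 8, 8)).cumsum(axis=0)
        movie = ActivationMovie(frames=frames, frame_interval=0.05, pixel_size=1.0)
        a = activation_fraction(movie, ActivationParams(baseline_frames=4))
        assert np.nanmin(a) >= 0.0 and np.nanmax(a) <= 1.0
        assert np.allclose(np.nanmax(a, axis=0), 1.0)

    def test_monotone_decay_gives_monotone_activation(self):
        t = np.arange(30)[:, None, None]
        frames = 100.0 * np.exp(-t / 10.0) * np.ones((30, 4, 4))
        movie = ActivationMovie(frames=frames, frame_interval=0.05, pixel_size=1.0)
        a = activation_fraction(movie, ActivationParams(baseline_frames=1))
        assert np.all(np.diff(a, axis=0) >= -1e-12)

    def test_zero_range_everywhere_is_an_error(self):
        frames = np.full((5, 3, 3), 10.0)
        movie = ActivationMovie(frames=frames, frame_interval=0.05, pixel_size=1.0)
        with pytest.raises(ValueError, match="dynamic range"):
            activation_fraction(movie)

    def test_binarize_is_inclusive_at_threshold(self):
        a = np.array([[[0.49]], [[0.5]], [[0.51]]])
        out = binarize(a, 0.5)
        assert out.ravel().tolist() == [False, True, True]


class TestArrival:
    def test_exact_frame_crossing(self):
        a = np.zeros((10, 1, 1))
        a[4:, 0, 0] = [0.5, 0.8, 1.0, 1.0, 1.0, 1.0]
        arr = arrival_time_map(a, 0.5, frame_interval=0.05)
        assert arr[0, 0] == pytest.approx(4 * 0.05)

    def test_linear_interpolation_between_frames(self):
        a = np.linspace(0.0, 1.0, 11)[:, None, None] * np.ones((11, 2, 2))
        arr = arrival_time_map(a, 0.5, frame_interval=0.1)
        assert np.allclose(arr, 5 * 0.1)

    def test_never_activated_pixel_is_nan(self):
        a = np.zeros((6, 2, 1))
        a[:, 0, 0] = np.linspace(0, 1, 6)
        a[:, 1, 0] = 0.2
        arr = arrival_time_map(a, 0.5, frame_interval=0.1)
        assert np.isfinite(arr[0, 0])
        assert np.isnan(arr[1, 0])


class TestFrontSpeed:
    def test_plane_wave_speed_recovered_noiseless(self):
        gt = WaveGroundTruth(speed_um_s=10.0, seed=0)
        movie, truth = gen_wave_movie(gt, shape=(40, 40), duration=10.0)
        a = activation_fraction(movie, ActivationParams(baseline_frames=10))
        arr = arrival_time_map(a, 0.5, movie.frame_interval)
        est = front_speed(arr, movie.pixel_size)
        assert est.speed_um_s == pytest.approx(10.0, rel=0.02)

    @pytest.mark.parametrize("speed", [5.0, 10.0, 20.0])
    def test_speeds_recovered_under_noise(self, speed):
        gt = WaveGroundTruth(speed_um_s=speed, noise_sigma_pct=3.0, seed=int(speed))
        movie, _ = gen_wave_movie(gt, shape=(40, 40), duration=10.0)
        a = activation_fraction(movie, ActivationParams(baseline_frames=10))
        arr = arrival_time_map(a, 0.5, movie.frame_interval)
        est = front_speed(arr, movie.pixel_size, direction=gt.direction)
        assert est.speed_um_s == pytest.approx(speed, rel=0.05)

    @pytest.mark.parametrize("theta", [0.4, 0.5, 0.6])
    def test_threshold_insensitivity_for_uniform_kinetics(self, theta):
        gt = WaveGroundTruth(speed_um_s=10.0, seed=2)
        movie, _ = gen_wave_movie(gt, shape=(32, 32), duration=10.0)
        a = activation_fraction(movie, ActivationParams(baseline_frames=10))
        arr = arrival_time_map(a, theta, movie.frame_interval)
        est = front_speed(arr, movie.pixel_size, direction=gt.direction)
        assert est.speed_um_s == pytest.approx(10.0, rel=0.05)

    def test_doubling_pixel_size_doubles_speed(self):
        gt = WaveGroundTruth(speed_um_s=10.0, seed=3)
        movie, _ = gen_wave_movie(gt, shape=(30, 30), duration=10.0)
        a = activation_fraction(movie, ActivationParams(baseline_frames=10))
        arr = arrival_time_map(a, 0.5, movie.frame_interval)
        est1 = front_speed(arr, 1.0, direction=gt.direction)
        est2 = front_speed(arr, 2.0, direction=gt.direction)
        assert est2.speed_um_s == pytest.approx(2.0 * est1.speed_um_s)

    def test_reversed_movie_is_flagged_as_retreating(self):
        gt = WaveGroundTruth(speed_um_s=10.0, seed=4)
        movie, _ = gen_wave_movie(gt, shape=(30, 30), duration=10.0)
        a = activation_fraction(movie, ActivationParams(baseline_frames=10))
        arr = arrival_time_map(a, 0.5, movie.frame_interval)
        est = front_speed(arr, movie.pixel_size, direction=(-gt.direction[0],
                                                            -gt.direction[1]))
        assert est.retreating

    def test_simultaneous_arrival_unresolved(self):
        arr = np.zeros((5, 5))
        with pytest.raises(FrontUnresolvedError, match="unresolved|distances"):
            front_speed(arr, 1.0, direction=(0.0, 1.0))

    def test_roi_mode_with_eight_rois(self):
        gt = WaveGroundTruth(speed_um_s=10.0, seed=5)
        movie, _ = gen_wave_movie(gt, shape=(40, 40), duration=10.0)
        a = activation_fraction(movie, ActivationParams(baseline_frames=10))
        arr = arrival_time_map(a, 0.5, movie.frame_interval)
        cents = np.array([[y, 20.0] for y in np.linspace(4, 36, 8)])
        est = front_speed(arr, movie.pixel_size, roi_centroids=cents)
        assert est.mode == "roi"
        assert est.speed_um_s == pytest.approx(10.0, rel=0.05)

    def test_speed_invariant_to_affine_intensity_changes(self):
        gt = WaveGroundTruth(speed_um_s=10.0, seed=6)
        movie, _ = gen_wave_movie(gt, shape=(24, 24), duration=10.0)
        gains = 1.0 + 0.5 * np.random.default_rng(0).uniform(size=(24, 24))
        warped = ActivationMovie(
            frames=movie.frames * gains[None] + 13.0,
            frame_interval=movie.frame_interval,
            pixel_size=movie.pixel_size,
        )
        for m in (movie, warped):
            a = activation_fraction(m, ActivationParams(baseline_frames=10))
            arr = arrival_time_map(a, 0.5, m.frame_interval)
            est = front_speed(arr, m.pixel_size, direction=gt.direction)
            assert est.speed_um_s == pytest.approx(10.0, rel=0.02)


class TestMovieValidation:
    def test_short_movie_rejected(self):
        with pytest.raises(ValueError, match="T >= 3"):
            ActivationMovie(frames=np.ones((2, 4, 4)), frame_interval=0.05,
                            pixel_size=1.0)

    def test_bad_scales_rejected(self):
        with pytest.raises(ValueError):
            ActivationMovie(frames=np.ones((5, 4, 4)), frame_interval=0.0,
                            pixel_size=1.0)

    def test_threshold_bounds(self):
        with pytest.raises(ValueError):
            ActivationParams(threshold=1.0)
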