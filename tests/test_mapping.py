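"""Activation maps, isochrones, conduction velocity, phase movies."""

import math

import numpy as np
import pytest

from opticard import mapping, preprocess, synthetic, transients
from conftest import make_voltage_movie


@pytest.fixture(scope="module")
def planar_result():
    movie, gt = make_voltage_movie(frame_shape=(40, 120))
    pre = preprocess.preprocess(movie)
    res = mapping.activation_map(pre, beat_window=(0.0, 450.0))
    return movie, gt, res


class TestActivationMap:
    def test_planar_activation_affine_in_distance(self, planar_result):
        movie, gt, res = planar_result
        amap = res.activation_map
        cols = np.arange(amap.shape[1])
        col_mean = np.nanmean(amap, axis=0)
        coef = np.polyfit(cols, col_mean, 1)
        resid = col_mean - np.polyval(coef, cols)
        assert np.abs(resid).max() <= movie.frame_interval
        # slope = pitch / cv
        expected = movie.pixel_pitch / 10.0 / gt.cv * 1000.0
        assert coef[0] == pytest.approx(expected, rel=0.02)

    def test_point_source_monotone_in_radius(self):
        gt = synthetic.WaveGroundTruth(cv=10.0, duration80=260.0, geometry="point",
                                       origin=(20.0, 20.0))
        shape = (synthetic.n_frames_for(gt, (41, 41), 10 / 3, 0.05), 41, 41)
        movie, _ = synthetic.gen_voltage_movie(gt, shape)
        res = mapping.activation_map(preprocess.preprocess(movie), (0.0, 450.0))
        rows, cols = np.mgrid[0:41, 0:41]
        r = np.hypot(rows - 20.0, cols - 20.0)
        bins = np.round(r).astype(int)
        radial = [np.nanmean(res.activation_map[bins == k]) for k in range(1, 19)]
        assert np.all(np.diff(radial) > 0)

    def test_noisy_activation_error_below_one_frame(self):
        errs = []
        for seed in (0, 1, 2):
            movie, gt = make_voltage_movie(frame_shape=(24, 60), snr=10.0, seed=seed)
            res = mapping.activation_map(preprocess.preprocess(movie), (0.0, 450.0))
            truth = synthetic.true_activation_map(gt, movie.frame_shape, movie.pixel_pitch)
            diff = res.activation_map - truth
            diff = diff[np.isfinite(diff)]
            diff -= np.median(diff)  # common offset (stimulus delay) is irrelevant
            errs.append(np.median(np.abs(diff)))
        assert np.median(errs) <= movie.frame_interval

    def test_windows_without_upstroke_rejected(self):
        rng = np.random.default_rng(0)
        noise = synthetic.MovieStack if False else None
        from opticard.stack import MovieStack
        m = MovieStack(rng.normal(0, 1, (60, 8, 8)), 10 / 3, 0.05)
        with pytest.raises(ValueError, match="no upstroke"):
            mapping.activation_map(m)


class TestIsochrones:
    def test_level_count_matches_span(self, planar_result):
        _, _, res = planar_result
        iso = mapping.isochrones(res, interval=10.0)
        amap = res.activation_map
        span = np.nanmax(amap) - np.nanmin(amap)
        assert len(iso) == int(span // 10.0)

    def test_planar_10cm_isochrones_are_parallel_lines_1mm_apart(self):
        gt = synthetic.WaveGroundTruth(cv=10.0, duration80=260.0)
        shape = (synthetic.n_frames_for(gt, (30, 100), 10 / 3, 0.05), 30, 100)
        movie, _ = synthetic.gen_voltage_movie(gt, shape)
        res = mapping.activation_map(preprocess.preprocess(movie), (0.0, 500.0))
        iso = mapping.isochrones(res, interval=10.0)
        mean_cols = []
        for level in sorted(iso):
            pts = np.vstack(iso[level])
            assert pts[:, 1].std() < 1.5  # near-vertical line
            mean_cols.append(pts[:, 1].mean())
        # 10 cm/s x 10 ms = 1 mm = 20 px at 0.05 mm pitch
        spacing = np.diff(mean_cols) * 0.05
        assert np.allclose(spacing, 1.0, atol=0.1)

    def test_all_nan_map_rejected(self):
        res = mapping.ActivationResult(np.full((5, 5), np.nan), 5.0, 0.05)
        with pytest.raises(ValueError):
            mapping.isochrones(res)


class TestConductionVelocity:
    def test_noise_free_cv_191_recovered_within_5pct(self, planar_result):
        _, gt, res = planar_result
        res = mapping.conduction_velocity(res)
        assert res.cv_mean == pytest.approx(19.1, rel=0.05)
        assert (res.cv_paths["valid"]).sum() >= 3

    def test_doubling_pixel_pitch_doubles_cv(self, planar_result):
        _, _, res = planar_result
        cv1 = mapping.conduction_velocity(res).cv_mean
        res2 = mapping.ActivationResult(res.activation_map, res.frame_interval,
                                        2 * res.pixel_pitch)
        cv2 = mapping.conduction_velocity(res2).cv_mean
        assert cv2 == pytest.approx(2 * cv1, rel=1e-6)

    def test_seeded_noisy_recovery_within_5pct(self):
        cvs = []
        for seed in range(4):
            movie, _ = make_voltage_movie(duration80=260.0, cv=15.0,
                                          frame_shape=(40, 120), snr=10.0, seed=seed)
            res = mapping.activation_map(preprocess.preprocess(movie), (0.0, 500.0))
            cvs.append(mapping.conduction_velocity(res).cv_mean)
        assert np.mean(cvs) == pytest.approx(15.0, rel=0.05)

    def test_non_monotone_path_flagged_and_excluded(self):
        rows, cols = np.mgrid[0:30, 0:60]
        amap = cols * 0.25
        amap[:, 40:] = (60 - cols[:, 40:]) * 0.25  # wave reverses: non-monotone
        res = mapping.ActivationResult(amap.astype(float), 10 / 3, 0.05)
        res = mapping.conduction_velocity(
            res, paths=[((15.0, 0.0), (15.0, 59.0))])
        assert not res.cv_paths.loc[0, "valid"]
        assert math.isnan(res.cv_mean)

    def test_endpoint_and_regression_methods_agree_on_clean_wave(self, planar_result):
        _, _, res = planar_result
        cv_r = mapping.conduction_velocity(res, method="regression").cv_mean
        cv_e = mapping.conduction_velocity(res, method="endpoints").cv_mean
        assert cv_e == pytest.approx(cv_r, rel=0.02)


class TestHilbertPhase:
    def test_sinusoid_phase_slope_matches_frequency(self):
        from opticard.stack import MovieStack
        fi = 5.0
        f_hz = 1.0
        t = np.arange(1200) * fi / 1000.0
        data = np.tile(np.sin(2 * np.pi * f_hz * t)[:, None, None], (1, 3, 3))
        phase = mapping.hilbert_phase(MovieStack(data, fi, 0.05))
        unwrapped = np.unwrap(phase[:, 1, 1])
        slope = np.polyfit(t[100:-100], unwrapped[100:-100], 1)[0]
        assert slope == pytest.approx(2 * np.pi * f_hz, rel=0.01)

    def test_constant_pixel_is_nan(self):
        from opticard.stack import MovieStack
        data = np.ones((50, 3, 3))
        data[:, 0, 0] = np.sin(np.linspace(0, 20, 50))
        phase = mapping.hilbert_phase(MovieStack(data, 5.0, 0.05))
        assert np.isnan(phase[:, 1, 1]).all()
        assert np.isfinite(phase[:, 0, 0]).all()

    def test_planar_wave_phase_gradient_aligned_with_propagation(self):
        movie, gt = make_voltage_movie(frame_shape=(24, 60))
        pre = preprocess.remove_baseline(movie)
        phase = mapping.hilbert_phase(pre)
        # mid-upstroke frame of the second beat
        frame = phase[int(1100 / movie.frame_interval)]
        gy, gx = np.gradient(np.unwrap(np.unwrap(frame, axis=1), axis=0))
        interior = (slice(4, -4), slice(4, -4))
        aligned = np.abs(gx[interior]) > np.abs(gy[interior])
        assert aligned.mean() >= 0.9
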