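"""Generator contracts: determinism, ground-truth consistency, counts."""

import math

import numpy as np
import pytest

from opticard import synthetic, transients
from conftest import bruteforce_duration80, make_calcium_movie, make_voltage_movie


class TestWaveMovies:
    def test_planar_activation_delay_matches_distance_over_speed(self):
        # 100 columns at 0.05 mm pitch and 10 cm/s -> 50 ms delay
        gt = synthetic.WaveGroundTruth(cv=10.0, duration80=260.0)
        act = synthetic.true_activation_map(gt, (4, 120), 0.05)
        assert act[0, 100] - act[0, 0] == pytest.approx(50.0)

    def test_point_source_activation_monotone_in_radius(self):
        gt = synthetic.WaveGroundTruth(cv=10.0, duration80=260.0,
                                       geometry="point", origin=(10.0, 12.0))
        act = synthetic.true_activation_map(gt, (21, 25), 0.05)
        rows, cols = np.mgrid[0:21, 0:25]
        r = np.hypot(rows - 10.0, cols - 12.0)
        order = np.argsort(r.ravel())
        assert np.all(np.diff(act.ravel()[order]) >= -1e-9)

    @pytest.mark.parametrize("make,frame_interval,d80", [
        (make_voltage_movie, 10.0 / 3.0, 260.0),
        (make_calcium_movie, 5.0, 552.0),
    ])
    def test_noise_free_trace_recovers_duration_within_one_frame(
        self, make, frame_interval, d80
    ):
        movie, gt = make(duration80=d80, frame_shape=(8, 8))
        trace = movie.data[:, 4, 4]
        measured = bruteforce_duration80(trace, frame_interval)
        assert measured == pytest.approx(d80, abs=frame_interval)

    def test_fixed_seed_gives_bit_identical_movies(self):
        a, _ = make_voltage_movie(snr=10.0, seed=42)
        b, _ = make_voltage_movie(snr=10.0, seed=42)
        assert np.array_equal(a.data, b.data)
        c, _ = make_voltage_movie(snr=10.0, seed=43)
        assert not np.array_equal(a.data, c.data)

    def test_expected_number_of_transients_present(self):
        movie, gt = make_calcium_movie(frame_shape=(6, 6))
        tm = transients.analyze_trace(movie.data[:, 3, 3], movie.frame_interval)
        assert len(tm.events) == gt.n_beats

    def test_rejects_recording_too_short_for_traversal(self):
        gt = synthetic.WaveGroundTruth(cv=1.0, duration80=260.0)  # very slow wave
        with pytest.raises(ValueError, match="traverse"):
            synthetic.gen_voltage_movie(gt, (200, 8, 200))

    def test_invariant_violations_rejected(self):
        with pytest.raises(ValueError):
            synthetic.WaveGroundTruth(cv=-1.0, duration80=260.0)
        with pytest.raises(ValueError):
            synthetic.WaveGroundTruth(cv=10.0, duration80=260.0, pacing_period=280.0)
        with pytest.raises(ValueError):
            synthetic.WaveGroundTruth(cv=10.0, duration80=260.0, n_beats=2)

    def test_template_exact_80pct_recovery_by_construction(self):
        # dense evaluation of the template itself: onset->80% span is exact
        t = np.linspace(-10.0, 1200.0, 400001)
        for d80, rise, power in [(260.0, 5.0, 3.0), (552.0, 30.0, 1.5)]:
            y = synthetic.transient_template(t, d80, rise, power)
            dt = t[1] - t[0]
            measured = bruteforce_duration80(y, dt)
            assert measured == pytest.approx(d80, abs=0.02)
            # monotone repolarisation after the peak
            pk = int(np.argmax(y))
            assert np.all(np.diff(y[pk:]) <= 1e-12)


class TestMicrographs:
    def test_counts_and_determinism(self):
        gt = synthetic.MicrographGroundTruth(n_cells=200, dead_fraction=0.113, seed=5)
        out = synthetic.gen_micrographs(gt, "viability", shape=(256, 256))
        assert out["centers"].shape == (200, 2)
        assert len(out["dead_idx"]) == round(0.113 * 200)
        out2 = synthetic.gen_micrographs(gt, "viability", shape=(256, 256))
        assert np.array_equal(out["PI"], out2["PI"])
        assert np.array_equal(out["DAPI"], out2["DAPI"])

    def test_zero_dead_fraction_gives_background_only_pi(self):
        gt = synthetic.MicrographGroundTruth(n_cells=100, dead_fraction=0.0, seed=1)
        out = synthetic.gen_micrographs(gt, "viability", shape=(256, 256))
        # PI channel is pure background + noise: no pixel near nucleus brightness
        assert out["PI"].max() < 10.0 + 6.0 * 2.0

    def test_zero_expression_gives_autofluorescence_floor(self):
        gt = synthetic.MicrographGroundTruth(n_cells=100, expression_per_cell=0.0,
                                             autofluorescence_level=30.0, seed=2)
        out = synthetic.gen_micrographs(gt, "expression", shape=(256, 256))
        assert out["eYFP"].mean() == pytest.approx(30.0, abs=0.5)
        assert out["eYFP"].std() == pytest.approx(2.0, rel=0.2)

    def test_nuclei_respect_minimum_separation(self):
        gt = synthetic.MicrographGroundTruth(n_cells=300, seed=3)
        out = synthetic.gen_micrographs(gt, "viability", shape=(384, 384),
                                        nucleus_radius=5.0)
        c = out["centers"]
        d = np.hypot(*(c[:, None, :] - c[None, :, :]).transpose(2, 0, 1))
        np.fill_diagonal(d, np.inf)
        assert d.min() >= 2 * 5.0 + 2.0 - 1e-9

    def test_overcrowded_request_fails(self):
        gt = synthetic.MicrographGroundTruth(n_cells=500, seed=4)
        with pytest.raises(ValueError, match="non-overlapping"):
            synthetic.gen_micrographs(gt, "viability", shape=(64, 64))


class TestCaptureOracle:
    def test_capture_region_is_lapicque_half_plane(self):
        # brute-force evaluation over an irradiance x duration grid
        p = synthetic.OracleParams(rheobase=0.05, chronaxie=5.0, capture_noise=0.0)
        oracle = synthetic.gen_capture_oracle(p)
        for d in np.geomspace(0.5, 100.0, 12):
            boundary = 0.05 * (1.0 + 5.0 / d)
            for e in np.geomspace(0.01, 2.0, 15):
                expected = 10 if e >= boundary else 0
                assert oracle(e, d, 10) == expected

    def test_chronaxie_definition_boundary_point(self):
        p = synthetic.OracleParams(rheobase=0.05, chronaxie=5.0)
        oracle = synthetic.gen_capture_oracle(p)
        assert oracle(2 * 0.05, 5.0, 10) == 10          # exactly on boundary
        assert oracle(0.99 * 0.05, 1e6, 10) == 0        # below the asymptote

    def test_noise_only_near_boundary_and_deterministic(self):
        p = synthetic.OracleParams(rheobase=0.1, chronaxie=5.0,
                                   capture_noise=0.3, seed=11)
        oracle = synthetic.gen_capture_oracle(p)
        boundary = 0.1 * (1.0 + 5.0 / 10.0)
        far = oracle(10.0 * boundary, 10.0, 10)
        assert far == 10  # noise applies only within +/-5% of the boundary
        near1 = oracle(boundary * 1.01, 10.0, 10)
        near2 = oracle(boundary * 1.01, 10.0, 10)
        assert near1 == near2  # keyed noise stream: query-order independent

    def test_rejects_nonpositive_inputs(self):
        oracle = synthetic.gen_capture_oracle(synthetic.OracleParams(0.05, 5.0))
        with pytest.raises(ValueError):
            oracle(-1.0, 10.0, 10)
        with pytest.raises(ValueError):
            oracle(1.0, 0.0, 10)
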