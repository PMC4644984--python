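"""Threshold search, strength-duration curves and hyperbolic fits."""

import math

import numpy as np
import pytest

from opticard import excitability as ex
from opticard import synthetic


@pytest.fixture()
def clean_oracle():
    return synthetic.gen_capture_oracle(
        synthetic.OracleParams(rheobase=0.05, chronaxie=5.0))


class TestFindThreshold:
    def test_threshold_at_chronaxie_is_twice_rheobase(self, clean_oracle):
        res = ex.find_threshold(clean_oracle, 5.0)
        assert res.e_th == pytest.approx(0.10, rel=0.03)
        lo, hi = res.bracket
        assert lo < 0.10 <= hi * (1 + 1e-12)
        assert hi / lo <= 1.0 + 2 * ex.REL_PRECISION + 1e-9

    def test_nine_of_ten_is_not_accepted(self):
        # a tester that never reaches 10/10 below 0.2, returns 9 in between
        def tester(e, d, n):
            if e >= 0.2:
                return n
            if e >= 0.05:
                return 9
            return 0
        res = ex.find_threshold(tester, 10.0)
        assert res.e_th >= 0.2 * (1 - ex.REL_PRECISION)
        accepted = res.certificate[res.certificate["accepted"]]
        assert (accepted["captured"] >= 10).all()

    def test_threshold_monotone_in_duration(self, clean_oracle):
        e = [ex.find_threshold(clean_oracle, d).e_th for d in (1.0, 2.0, 5.0, 20.0, 90.0)]
        assert all(a >= b * (1 - 2 * ex.REL_PRECISION) for a, b in zip(e, e[1:]))

    def test_inexcitable_at_grid_maximum_flagged(self):
        def never(e, d, n):
            return 0
        res = ex.find_threshold(never, 10.0, ceiling=1.0)
        assert res.inexcitable and math.isinf(res.e_th)

    def test_bracket_certifies_true_boundary_when_noiseless(self, clean_oracle):
        for d in (1.0, 7.0, 30.0):
            res = ex.find_threshold(clean_oracle, d)
            true = 0.05 * (1 + 5.0 / d)
            lo, hi = res.bracket
            assert lo < true <= hi

    def test_rheobase_ratio_recovered_within_10pct(self):
        r = 35.0
        o1 = synthetic.gen_capture_oracle(synthetic.OracleParams(0.05, 5.0))
        o2 = synthetic.gen_capture_oracle(synthetic.OracleParams(0.05 / r, 5.0))
        for d in (2.0, 10.0, 50.0):
            ratio = ex.find_threshold(o1, d).e_th / ex.find_threshold(o2, d).e_th
            assert ratio == pytest.approx(r, rel=0.10)


class TestSDCurve:
    def test_single_replicate_sem_nan(self, clean_oracle):
        curve = ex.build_sd_curve({1.0: [0.3], 10.0: [0.075]})
        assert math.isnan(curve.table["sem"].iloc[0])
        assert curve.table["mean"].tolist() == [0.3, 0.075]

    def test_identical_replicates_sem_zero(self):
        curve = ex.build_sd_curve({1.0: [0.3, 0.3], 10.0: [0.075, 0.075]})
        assert (curve.table["sem"] == 0).all()

    def test_noisy_oracle_means_within_5pct_of_noiseless(self):
        durations = (2.0, 5.0, 20.0)
        noiseless = {d: ex.find_threshold(
            synthetic.gen_capture_oracle(synthetic.OracleParams(0.05, 5.0)), d).e_th
            for d in durations}
        thr = {d: [] for d in durations}
        for seed in range(6):
            oracle = synthetic.gen_capture_oracle(
                synthetic.OracleParams(0.05, 5.0, capture_noise=0.1, seed=seed))
            for d in durations:
                thr[d].append(ex.find_threshold(oracle, d).e_th)
        curve = ex.build_sd_curve(thr)
        for _, row in curve.table.iterrows():
            assert row["mean"] == pytest.approx(noiseless[row["duration_ms"]], rel=0.05)

    def test_inexcitable_points_propagate_as_missing(self):
        curve = ex.build_sd_curve({1.0: [math.inf], 10.0: [0.1], 50.0: [0.06]})
        assert 1.0 not in curve.table["duration_ms"].tolist()

    def test_fewer_than_two_durations_rejected(self):
        with pytest.raises(ValueError):
            ex.build_sd_curve({1.0: [0.3]})


def test_log_log_plot_export(tmp_path):
    curve = ex.build_sd_curve({1.0: [0.3, 0.31], 10.0: [0.075, 0.08],
                               90.0: [0.052, 0.055]}, condition="0 uM")
    fit = ex.fit_rheobase_chronaxie(curve)
    out = tmp_path / "sd.png"
    ex.plot_sd_curves([curve], [fit], path=str(out))
    assert out.exists() and out.stat().st_size > 0


class TestRheobaseChronaxieFit:
    def test_exact_lapicque_recovered_to_4_significant_digits(self):
        d = np.array([1.0, 2.0, 5.0, 10.0, 50.0, 90.0])
        fit = ex.fit_rheobase_chronaxie((d, synthetic.lapicque(d, 0.05, 5.0)))
        assert fit.rheobase == pytest.approx(0.05, rel=1e-4)
        assert fit.chronaxie == pytest.approx(5.0, rel=1e-4)
        # chronaxie definition: fitted E at chronaxie equals twice rheobase
        assert synthetic.lapicque(fit.chronaxie, fit.rheobase, fit.chronaxie) \
            == pytest.approx(2 * fit.rheobase)

    def test_weiss_form_equivalent_on_exact_data(self):
        d = np.array([1.0, 3.0, 10.0, 30.0, 90.0])
        fit = ex.fit_rheobase_chronaxie((d, synthetic.lapicque(d, 0.02, 8.0)),
                                        model="weiss")
        assert fit.rheobase == pytest.approx(0.02, rel=1e-9)
        assert fit.chronaxie == pytest.approx(8.0, rel=1e-9)

    def test_multiplicative_noise_median_error_below_10pct(self):
        d = np.array([1.0, 2.0, 5.0, 10.0, 20.0, 50.0, 90.0])
        clean = synthetic.lapicque(d, 0.05, 5.0)
        errs_r, errs_c = [], []
        rng = np.random.default_rng(2024)
        for _ in range(100):
            noisy = clean * (1.0 + 0.05 * rng.standard_normal(d.size))
            fit = ex.fit_rheobase_chronaxie((d, noisy))
            errs_r.append(abs(fit.rheobase - 0.05) / 0.05)
            errs_c.append(abs(fit.chronaxie - 5.0) / 5.0)
        assert np.median(errs_r) <= 0.10
        assert np.median(errs_c) <= 0.10

    def test_constant_thresholds_flag_chronaxie_boundary(self):
        d = np.array([1.0, 5.0, 20.0, 90.0])
        fit = ex.fit_rheobase_chronaxie((d, np.full(4, 0.1)))
        assert "chronaxie_at_zero_boundary" in fit.flags

    def test_insufficient_span_rejected(self):
        with pytest.raises(ValueError):
            ex.fit_rheobase_chronaxie((np.array([5.0, 8.0, 10.0]),
                                       np.array([0.2, 0.15, 0.1])))


class TestHyperbolicDoseFit:
    def test_exact_hyperbola_recovered(self):
        a = np.array([0.0, 0.1, 0.25, 0.5, 1.0])
        e = 0.3 / (a + 0.2) + 0.01
        fit = ex.fit_eth_vs_atr(a, e)
        assert fit.k == pytest.approx(0.3, rel=1e-4)
        assert fit.a0 == pytest.approx(0.2, rel=1e-4)
        assert fit.e_inf == pytest.approx(0.01, rel=1e-3)
        assert fit.r_squared > 0.9999

    def test_rebound_doses_excluded_and_flagged(self):
        a = np.array([0.0, 0.5, 1.0, 2.0, 4.0])
        e = np.array([1.5, 0.3, 0.05, 0.2, 0.9])  # minimum at 1 uM, then rises
        fit = ex.fit_eth_vs_atr(a, e)
        assert list(fit.excluded_doses) == [2.0, 4.0]
        assert "excluded_rebound_doses" in fit.flags

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            ex.fit_eth_vs_atr(np.array([0.0, 1.0]), np.array([1.0, 0.5]))
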