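import numpy as np
import pytest

from jdpop import (
    BindingIsotherm,
    CalibrationCurve,
    KineticTrace,
    aggregation_times,
    fit_calibration,
    fit_one_site,
    fold_activation,
    initial_rate,
    tm_from_inflection,
)
from jdpop.assays import AssayError, RateResult


class TestCalibration:
    def test_exact_line(self):
        pts = [(c, 2.0 * c + 5.0) for c in (0, 100, 200, 300, 400)]
        cal = fit_calibration(pts)
        assert cal.slope == pytest.approx(2.0)
        assert cal.intercept == pytest.approx(5.0)
        assert cal.residual_sd == pytest.approx(0.0, abs=1e-9)
        assert cal.n_points == 5

    def test_slope_unbiased_under_noise(self):
        # 100 seeded replicates of 5 standards with sigma=5 FU
        conc = np.array([0.0, 100.0, 200.0, 300.0, 400.0])
        slopes = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            fluor = 100.0 + 2.0 * conc + rng.normal(0, 5.0, 5)
            slopes.append(fit_calibration(np.column_stack([conc, fluor])).slope)
        slopes = np.asarray(slopes)
        se_mean = slopes.std(ddof=1) / 10.0
        assert abs(slopes.mean() - 2.0) < 4 * se_mean

    def test_single_concentration_errors(self):
        with pytest.raises(AssayError, match="equal"):
            fit_calibration([(100.0, 200.0), (100.0, 210.0)])


CAL = CalibrationCurve(slope=2.0, intercept=100.0, n_points=5, residual_sd=0.0)


class TestInitialRate:
    def test_linear_trace_recovers_slope(self):
        t = np.arange(0, 20.01, 2 / 3)
        trace = KineticTrace(t, 100.0 + 2.0 * (0.2 * t))
        rr = initial_rate(trace, CAL)
        assert rr.rate == pytest.approx(0.2)

    def test_flat_trace_zero_rate(self):
        t = np.arange(0, 21.0, 1.0)
        assert initial_rate(KineticTrace(t, np.full_like(t, 150.0)), CAL).rate == pytest.approx(0.0)

    def test_saturating_trace_early_window_exceeds_full_slope(self):
        t = np.arange(0, 60.5, 0.5)
        pi = 50.0 * (1 - np.exp(-t / 10.0))  # saturating Pi accumulation
        trace = KineticTrace(t, 100.0 + 2.0 * pi)
        early = initial_rate(trace, CAL, window=(0.0, 5.0)).rate
        full = initial_rate(trace, CAL, window=(0.0, 60.0)).rate
        assert early > full

    def test_window_outside_trace_errors(self):
        t = np.arange(0, 10.0, 1.0)
        with pytest.raises(AssayError, match="window"):
            initial_rate(KineticTrace(t, t), CAL, window=(50.0, 60.0))

    def test_unit_coherence(self):
        """Scaling fluorescence of standards and trace together leaves the
        rate unchanged."""
        t = np.arange(0, 20.01, 2 / 3)
        fluor = 100.0 + 2.0 * (0.37 * t)
        for c in (1.0, 12.5):
            cal = fit_calibration([(x, c * (2.0 * x + 100.0)) for x in (0, 100, 200, 300, 400)])
            rr = initial_rate(KineticTrace(t, c * fluor), cal)
            assert rr.rate == pytest.approx(0.37)


class TestFoldActivation:
    def test_printed_rate_ratio(self):
        # basal Hsp70 0.2 nM Pi/min; isolated J-domain 1.74 -> 8.7-fold
        assert fold_activation(
            RateResult(1.74, (0, 20)), RateResult(0.2, (0, 20))
        ) == pytest.approx(8.7)

    def test_moderate_activation_ratio(self):
        assert fold_activation(
            RateResult(1.24, (0, 20)), RateResult(0.2, (0, 20))
        ) == pytest.approx(6.2)

    def test_identity(self):
        r = RateResult(0.55, (0, 20))
        assert fold_activation(r, r) == 1.0

    def test_nonpositive_basal_errors(self):
        with pytest.raises(AssayError):
            fold_activation(RateResult(1.0, (0, 20)), RateResult(0.0, (0, 20)))


def one_site(L, r_free, r_bound, kd):
    return r_free + (r_bound - r_free) * L / (kd + L)


class TestOneSiteFit:
    @pytest.mark.parametrize("kd", [1.5, 9.0, 47.0, 290.0])
    def test_noiseless_round_trip(self, kd):
        L = np.concatenate([[0.0], np.geomspace(0.1, 1000.0, 12)])
        iso = BindingIsotherm(L, one_site(L, 0.05, 0.25, kd))
        fit = fit_one_site(iso)
        assert fit.kd == pytest.approx(kd, rel=1e-6)
        assert fit.r_free == pytest.approx(0.05, abs=1e-6)
        assert fit.r_bound == pytest.approx(0.25, abs=1e-6)
        assert not fit.kd_is_lower_bound

    def test_flat_isotherm_reported_as_bound(self):
        L = np.concatenate([[0.0], np.geomspace(0.1, 1000.0, 10)])
        iso = BindingIsotherm(L, np.full_like(L, 0.05))
        fit = fit_one_site(iso)
        assert fit.kd_is_lower_bound
        assert fit.kd == pytest.approx(1000.0)

    def test_saturated_regime_flagged_degenerate(self):
        L = np.geomspace(100.0, 1000.0, 8)  # all L >> KD = 0.5
        iso = BindingIsotherm(L, one_site(L, 0.05, 0.25, 0.5))
        fit = fit_one_site(iso)
        assert any("r_free" in n for n in fit.notes)

    def test_noisy_recovery_median_error(self):
        """Seeded noisy titrations recover K_D with bounded relative error."""
        errors = []
        for i, kd in enumerate([1.5, 9.0, 47.0, 290.0] * 25):
            rng = np.random.default_rng(1000 + i)
            L = np.concatenate([[0.0], np.geomspace(0.1, 1000.0, 12)])
            r = one_site(L, 0.05, 0.25, kd) + rng.normal(0, 0.02 * 0.2, L.size)
            fit = fit_one_site(BindingIsotherm(L, r))
            errors.append(abs(fit.kd - kd) / kd)
        assert np.median(errors) < 0.15

    def test_too_few_concentrations(self):
        with pytest.raises(AssayError, match=">= 4"):
            fit_one_site(BindingIsotherm([0, 1, 2], [0.05, 0.1, 0.15]))


class TestAggregationTimes:
    def test_piecewise_linear_ramp_interpolated(self):
        # flat 0 until t=10, linear to 100 at t=20, flat after -> t_half = 15
        t = np.arange(0.0, 30.5, 0.5)
        y = np.interp(t, [0, 10, 20, 30], [0, 0, 100, 100])
        summ = aggregation_times(KineticTrace(t, y), baseline_window=(0, 8), plateau_window=(22, 30))
        assert summ.t_half == pytest.approx(15.0)
        assert summ.baseline == pytest.approx(0.0)
        assert summ.plateau == pytest.approx(100.0)
        # maximal slope spans the whole ramp: tangent meets baseline at t=10
        assert summ.lag_time == pytest.approx(10.0, abs=0.5)

    def test_logistic_midpoint(self):
        t = np.arange(0.0, 300.0, 2.0)
        y = 100 + 1000 / (1 + np.exp(-(t - 150.0) / 10.0))
        summ = aggregation_times(KineticTrace(t, y))
        assert summ.t_half == pytest.approx(150.0, abs=2.0)
        assert summ.lag_time <= summ.t_half
        assert summ.baseline <= summ.plateau

    def test_affine_signal_invariance(self):
        t = np.arange(0.0, 300.0, 2.0)
        y = 1 / (1 + np.exp(-(t - 140.0) / 12.0))
        a = aggregation_times(KineticTrace(t, y))
        b = aggregation_times(KineticTrace(t, 50.0 + 700.0 * y))
        assert b.t_half == pytest.approx(a.t_half, abs=1e-9)
        assert b.lag_time == pytest.approx(a.lag_time, abs=1e-6)

    def test_monotone_decreasing_errors(self):
        t = np.arange(0.0, 100.0, 1.0)
        with pytest.raises(AssayError, match="no transition"):
            aggregation_times(KineticTrace(t, 1000.0 - 5.0 * t))


class TestMeltingPoint:
    def test_sigmoid_inflection(self):
        t = np.arange(20.0, 90.0, 0.5)
        y = 0.8 + 0.4 / (1 + np.exp(-(t - 55.0) / 2.0))
        assert tm_from_inflection(KineticTrace(t, y, time_unit="degC")) == pytest.approx(
            55.0, abs=0.5
        )

    def test_two_transition_fixture_warns_and_returns_global(self):
        t = np.arange(20.0, 90.0, 0.5)
        y = 0.6 / (1 + np.exp(-(t - 45.0) / 1.5)) + 1.0 / (1 + np.exp(-(t - 70.0) / 1.5))
        with pytest.warns(UserWarning, match="secondary"):
            tm = tm_from_inflection(KineticTrace(t, y, time_unit="degC"))
        assert tm == pytest.approx(70.0, abs=1.0)

    def test_linear_ramp_errors(self):
        t = np.arange(20.0, 90.0, 0.5)
        with pytest.raises(AssayError, match="no melting transition"):
            tm_from_inflection(KineticTrace(t, 0.01 * t, time_unit="degC"))
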