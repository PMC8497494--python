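"""Unit and property tests of the closed-form models and their fits."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.optimize import brentq

from ratiovm.models import (
    BoltzmannParams,
    CalibrationRangeError,
    DomainError,
    KineticsParams,
    NernstConditions,
    SigmoidParams,
    boltzmann_ratio,
    boltzmann_slope,
    calibration_from_dict,
    calibration_to_dict,
    double_exp_response,
    estimate_population_vm,
    fit_boltzmann,
    fit_double_exp,
    fit_sigmoid,
    invert_boltzmann,
    nernst_potential,
    sigmoid_metrics,
    sigmoid_time_course,
)

RASAP_KINETICS = KineticsParams(0.702, 0.298, 7.2, 73.0, 30.0)
INDUCTION = SigmoidParams(1.0, 1.051, 42.5, 19.36)


class TestBoltzmann:
    def test_midpoint_value(self, rasap):
        # sigmoid term is exactly 1/2 at the midpoint voltage
        expected = rasap.r_max * (1 - rasap.delta_r / 200.0)
        assert boltzmann_ratio(rasap.v_half, rasap) == pytest.approx(expected)

    def test_flat_curve_when_delta_r_zero(self):
        p = BoltzmannParams(0.8, 0.0, -20.0, 30.0)
        v = np.linspace(-150, 80, 7)
        assert np.allclose(boltzmann_ratio(v, p), 0.8)

    def test_rasap_endpoints_and_dynamic_range(self, rasap):
        r_hyp = boltzmann_ratio(-100.0, rasap)
        r_dep = boltzmann_ratio(60.0, rasap)
        assert r_hyp == pytest.approx(1.3975, abs=2e-4)
        assert r_dep == pytest.approx(0.7702, abs=2e-4)
        assert 100 * (r_hyp - r_dep) / r_hyp == pytest.approx(44.89, abs=0.05)

    def test_ratio_decreases_with_depolarization(self, rasap, rarc):
        for p in (rasap, rarc):
            v = np.linspace(-150, 80, 100)
            assert np.all(np.diff(boltzmann_ratio(v, p)) < 0)

    def test_nonfinite_voltage_rejected(self, rasap):
        with pytest.raises(DomainError):
            boltzmann_ratio(float("nan"), rasap)

    def test_invalid_params_rejected(self):
        with pytest.raises(DomainError):
            BoltzmannParams(-1.0, 10.0, 0.0, 30.0)
        with pytest.raises(DomainError):
            BoltzmannParams(1.0, 10.0, 0.0, 0.0)

    def test_negating_ks_mirrors_about_midpoint(self, rasap):
        mirrored = BoltzmannParams(rasap.r_max, rasap.delta_r, rasap.v_half,
                                   -rasap.k_s)
        x = np.linspace(-80, 80, 41)
        left = boltzmann_ratio(rasap.v_half + x, rasap)
        right = boltzmann_ratio(rasap.v_half - x, mirrored)
        assert np.allclose(left, right, atol=1e-12)

    def test_canonical_representation_same_curve(self, rasap):
        v = np.linspace(-150, 80, 23)
        assert np.allclose(boltzmann_ratio(v, rasap),
                           boltzmann_ratio(v, rasap.canonical()), rtol=1e-12)
        assert rasap.canonical().delta_r > 0

    def test_slope_matches_finite_difference(self, rasap):
        v = np.linspace(-120, 40, 9)
        h = 1e-5
        fd = (boltzmann_ratio(v + h, rasap) - boltzmann_ratio(v - h, rasap)) / (2 * h)
        assert np.allclose(boltzmann_slope(v, rasap), fd, rtol=1e-6)


class TestInversion:
    @given(vm=st.floats(-150, 80))
    def test_round_trip_identity(self, vm):
        p = BoltzmannParams(0.56, -178.6, -11.5, -54.0)
        assert invert_boltzmann(boltzmann_ratio(vm, p), p) == pytest.approx(
            vm, abs=1e-9
        )

    def test_matches_bisection_oracle(self, rasap):
        # ratios attainable inside the bisection bracket [-200, 100] mV
        for ratio in boltzmann_ratio(np.linspace(-180, 90, 9), rasap):
            oracle = brentq(
                lambda v: boltzmann_ratio(v, rasap) - ratio, -200.0, 100.0,
                xtol=1e-12,
            )
            assert invert_boltzmann(ratio, rasap) == pytest.approx(oracle, abs=1e-8)

    def test_out_of_range_reports_interval(self, rasap):
        lo, hi = rasap.ratio_limits()
        with pytest.raises(CalibrationRangeError) as err:
            invert_boltzmann(hi + 0.1, rasap)
        assert err.value.interval == (lo, hi)

    def test_flat_calibration_not_invertible(self):
        p = BoltzmannParams(1.0, 0.0, 0.0, 30.0)
        with pytest.raises(CalibrationRangeError):
            invert_boltzmann(1.0, p)

    def test_gramicidin_anchored_resting_vm(self, rasap):
        # untreated/gramicidin median ratio 1/0.835 referenced to 0 mV
        ratio = boltzmann_ratio(0.0, rasap) / 0.835
        assert invert_boltzmann(ratio, rasap) == pytest.approx(-44.0, abs=0.1)

    def test_kir_overexpression_vm(self, rasap):
        ratio = boltzmann_ratio(-40.0, rasap) * 1.159
        assert invert_boltzmann(ratio, rasap) == pytest.approx(-92.7, abs=0.1)


class TestPopulationVm:
    def test_equal_medians_return_reference(self, rasap):
        assert estimate_population_vm(1.23, 1.23, rasap, -40.0) == pytest.approx(
            -40.0, abs=1e-9
        )

    def test_gramicidin_and_kir_workflows(self, rasap):
        assert estimate_population_vm(1 / 0.835, 1.0, rasap, 0.0) == pytest.approx(
            -44.0, abs=0.1
        )
        assert estimate_population_vm(1.159, 1.0, rasap, -40.0) == pytest.approx(
            -92.7, abs=0.1
        )

    def test_nonpositive_median_rejected(self, rasap):
        with pytest.raises(DomainError):
            estimate_population_vm(0.0, 1.0, rasap)


class TestFitBoltzmann:
    def test_noiseless_recovery(self, rasap):
        v = np.linspace(-140, 60, 11)
        res = fit_boltzmann(v, boltzmann_ratio(v, rasap))
        got, want = res.params.canonical(), rasap.canonical()
        for name in ("r_max", "delta_r", "v_half", "k_s"):
            assert getattr(got, name) == pytest.approx(
                getattr(want, name), rel=1e-3
            )

    def test_noisy_vhalf_recovery(self, rasap, rng):
        """Median v_half error consistent with the asymptotic (CRLB) bound."""
        v = np.linspace(-140, 60, 11)
        clean = boltzmann_ratio(v, rasap)
        # information bound at this design and noise level (absolute sigma)
        res0 = fit_boltzmann(v, clean)
        from scipy.optimize import curve_fit
        from scipy.special import expit

        def model(vv, r_max, d, vh, ks):
            return r_max * (1 - (d / 100.0) * expit((vv - vh) / ks))

        _, pcov = curve_fit(
            model, v, clean,
            p0=(rasap.r_max, rasap.delta_r, rasap.v_half, rasap.k_s),
            sigma=0.02 * clean, absolute_sigma=True,
        )
        sigma_vh = np.sqrt(pcov[2, 2])
        errors = []
        for _ in range(100):
            r = clean * (1 + 0.02 * rng.standard_normal(v.size))
            res = fit_boltzmann(v, r)
            errors.append(res.params.canonical().v_half - rasap.v_half)
        errors = np.asarray(errors)
        # median |error| of a half-normal is 0.674*sigma; allow 1.5x slack
        assert np.median(np.abs(errors)) < 1.5 * 0.674 * sigma_vh
        # unbiased within Monte-Carlo error (robust center, outlier fits occur)
        assert abs(np.median(errors)) < 3 * sigma_vh / np.sqrt(100)

    def test_constant_input_flagged(self):
        v = np.linspace(-100, 50, 7)
        res = fit_boltzmann(v, np.full(7, 0.9))
        assert res.params.delta_r == 0.0
        assert "unidentifiable" in res.flags

    def test_too_few_voltages_rejected(self):
        with pytest.raises(DomainError):
            fit_boltzmann([0, 1, 2, 3], [1, 2, 3, 4])


class TestDoubleExp:
    def test_boundary_values(self):
        assert double_exp_response(0.0, RASAP_KINETICS) == pytest.approx(1.0)
        assert double_exp_response(1e6, RASAP_KINETICS) == pytest.approx(
            1 - RASAP_KINETICS.delta_r / 100.0
        )

    def test_value_at_fast_time_constant(self):
        assert double_exp_response(7.2, RASAP_KINETICS) == pytest.approx(
            0.8585, abs=2e-4
        )

    def test_negative_time_rejected(self):
        with pytest.raises(DomainError):
            double_exp_response(-1.0, RASAP_KINETICS)

    def test_monotone_when_amplitudes_share_sign(self):
        t = np.linspace(0, 400, 500)
        f = double_exp_response(t, RASAP_KINETICS)
        assert np.all(np.diff(f) < 0)

    def test_invariants_enforced(self):
        with pytest.raises(DomainError):
            KineticsParams(0.6, 0.3, 7.0, 70.0, 30.0)
        with pytest.raises(DomainError):
            KineticsParams(0.7, 0.3, 70.0, 7.0, 30.0)


class TestFitDoubleExp:
    def test_noiseless_recovery(self):
        t = np.arange(0, 500, 0.05)
        res = fit_double_exp(t, double_exp_response(t, RASAP_KINETICS))
        for name in ("a_fast", "tau_fast", "tau_slow", "delta_r"):
            assert getattr(res.params, name) == pytest.approx(
                getattr(RASAP_KINETICS, name), rel=1e-3
            )

    def test_single_exponential_input_flagged(self):
        t = np.arange(0, 500, 0.05)
        f = 1 - 0.3 * (1 - np.exp(-t / 20.0))
        res = fit_double_exp(t, f)
        assert "single_exponential" in res.flags
        assert res.params.a_slow == pytest.approx(0.0, abs=0.02) or \
            res.params.a_fast == pytest.approx(1.0, abs=0.02)

    def test_short_trace_rejected(self):
        with pytest.raises(DomainError):
            fit_double_exp(np.arange(10), np.ones(10))


class TestNernst:
    def test_zero_at_equal_concentrations(self):
        assert nernst_potential(NernstConditions(10, 10, 300)) == 0.0

    def test_patch_solution_values(self):
        assert nernst_potential(NernstConditions(4, 130, 295.15)) == pytest.approx(
            -88.5, abs=0.1
        )
        # default physiological temperature 310.15 K
        ek = nernst_potential(NernstConditions(4, 130))
        assert ek == pytest.approx(-93.0, abs=0.1)
        assert -100.0 < ek < -90.0

    @given(
        a=st.floats(0.5, 500), b=st.floats(0.5, 500),
        temp=st.floats(273, 320),
    )
    def test_antisymmetric_under_swap(self, a, b, temp):
        fwd = nernst_potential(NernstConditions(a, b, temp))
        rev = nernst_potential(NernstConditions(b, a, temp))
        assert fwd == pytest.approx(-rev, abs=1e-9)

    def test_nonpositive_concentration_rejected(self):
        with pytest.raises(DomainError):
            NernstConditions(0.0, 100.0)


class TestSigmoid:
    def test_flat_before_delay(self):
        t = np.array([-10.0, 0.0, 42.5])
        assert np.allclose(sigmoid_time_course(t, INDUCTION), INDUCTION.y0)

    def test_saturates_at_ymax(self):
        assert sigmoid_time_course(1e5, INDUCTION) == pytest.approx(INDUCTION.y_max)

    def test_half_rise_coefficient(self):
        m = sigmoid_metrics(INDUCTION)
        coeff = math.log(1.0 / (1.0 - 0.5 ** (1 / 3)))
        assert coeff == pytest.approx(1.5784, abs=1e-4)
        assert m["t_half"] == pytest.approx(42.5 + 19.36 * coeff, abs=1e-9)
        assert m["t_half"] == pytest.approx(73.0, abs=0.1)
        assert m["rise_20_80"] == pytest.approx(34.0, abs=0.1)

    @given(
        tau=st.floats(1.0, 100.0),
        t_del=st.floats(0.0, 100.0),
    )
    def test_metrics_match_root_finding(self, tau, t_del):
        p = SigmoidParams(0.0, 1.0, t_del, tau)
        m = sigmoid_metrics(p)
        for q, key in ((0.2, "t_20"), (0.5, "t_half"), (0.8, "t_80")):
            root = brentq(
                lambda t: sigmoid_time_course(t, p) - q,
                t_del, t_del + 100 * tau, xtol=1e-12,
            )
            assert m[key] == pytest.approx(root, abs=1e-9)

    def test_metrics_linear_in_tau_and_shift_in_delay(self):
        m1 = sigmoid_metrics(INDUCTION)
        m2 = sigmoid_metrics(SigmoidParams(1.0, 1.051, 42.5, 2 * 19.36))
        assert m2["rise_20_80"] == pytest.approx(2 * m1["rise_20_80"], rel=1e-12)
        m3 = sigmoid_metrics(SigmoidParams(1.0, 1.051, 52.5, 19.36))
        assert m3["t_half"] == pytest.approx(m1["t_half"] + 10.0, abs=1e-12)

    def test_degenerate_amplitude_rejected(self):
        with pytest.raises(DomainError):
            sigmoid_metrics(SigmoidParams(1.0, 1.0, 10.0, 5.0))


class TestFitSigmoid:
    def _series(self, params=INDUCTION, noise=0.0, rng=None):
        t = np.arange(-30.0, 245.0, 10.0)
        y = sigmoid_time_course(t, params)
        if noise and rng is not None:
            y = y + rng.normal(0, noise, t.shape)
        return t, y

    def test_noiseless_recovery_and_metrics(self):
        t, y = self._series()
        res = fit_sigmoid(t, y)
        m = res.extra["metrics"]
        assert m["t_half"] == pytest.approx(73.0, abs=0.5)
        assert m["rise_20_80"] == pytest.approx(34.0, abs=0.5)
        assert 40.0 <= res.params.t_del <= 50.0

    def test_refit_is_fixed_point(self):
        t, y = self._series()
        first = fit_sigmoid(t, y)
        refit = fit_sigmoid(t, sigmoid_time_course(t, first.params))
        for name in ("y0", "y_max", "t_del", "tau"):
            assert getattr(refit.params, name) == pytest.approx(
                getattr(first.params, name), rel=1e-4, abs=1e-6
            )

    def test_noisy_t_half_recovery(self, rng):
        errs = []
        for _ in range(100):
            t, y = self._series(noise=0.003, rng=rng)
            res = fit_sigmoid(t, y)
            errs.append(abs(res.extra["metrics"]["t_half"] - 73.06))
        assert np.median(errs) < 5.0

    def test_flat_input_flagged(self):
        t = np.arange(-30.0, 245.0, 10.0)
        res = fit_sigmoid(t, np.ones(t.size))
        assert "no_amplitude" in res.flags

    def test_too_few_points_rejected(self):
        with pytest.raises(DomainError):
            fit_sigmoid(np.arange(5), np.arange(5.0))


def test_calibration_serialization_round_trip(rasap):
    d = calibration_to_dict("rASAP", rasap, source="patch-clamp")
    assert d["orientation_corrected"] is True
    name, back = calibration_from_dict(d)
    assert name == "rASAP"
    for attr in ("r_max", "delta_r", "v_half", "k_s"):
        assert getattr(back, attr) == getattr(rasap, attr)
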