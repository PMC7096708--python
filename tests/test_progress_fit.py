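"""Relaxation fitting, residual diagnostics, model growth, preprocessing."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import chitkin as ck
from chitkin.progress_fit import runs_test_pvalue

from _oracles import grid_fit_single_exponential, runs_pvalue_enumeration
from conftest import single_exp_curve


class TestFitRelaxation:
    def test_noiseless_exact_recovery(self):
        curve = single_exp_curve(A=100.0, k1=0.01, B=5.0)
        fit = ck.fit_relaxation(curve)
        (a, k), = fit.components
        assert a == pytest.approx(100.0, rel=1e-6)
        assert k == pytest.approx(0.01, rel=1e-6)
        assert fit.B == pytest.approx(5.0, rel=1e-6)
        assert fit.ok

    def test_v0_identity(self):
        curve = single_exp_curve(A=80.0, k1=0.002, B=1.0, noise_sd=0.5, seed=2)
        fit = ck.fit_relaxation(curve)
        expected = sum(a * k for a, k in fit.components) + fit.linear_slope
        assert fit.v0_signal == expected

    def test_constant_curve_flagged_rate_indeterminate(self):
        t = np.arange(0, 600, 60.0)
        curve = ck.ProgressCurve(times=t, signals=np.full_like(t, 7.0))
        fit = ck.fit_relaxation(curve)
        assert "rate_indeterminate" in fit.flags
        assert abs(fit.components[0][0]) < 1e-6

    def test_negative_amplitude_loss_curve(self):
        curve = single_exp_curve(A=-50.0, k1=0.005, B=60.0)
        fit = ck.fit_relaxation(curve)
        (a, k), = fit.components
        assert a == pytest.approx(-50.0, rel=1e-6)
        assert k == pytest.approx(0.005, rel=1e-6)

    def test_noisy_fit_within_3_se_and_matches_grid_oracle(self):
        truth = dict(A=100.0, k1=0.0015, B=10.0)
        curve = single_exp_curve(noise_sd=1.0, seed=5, duration=3600,
                                 interval=20.0, **truth)
        fit = ck.fit_relaxation(curve)
        (a, k), = fit.components
        names = fit.param_names
        se = np.sqrt(np.diag(fit.covariance))
        assert abs(a - truth["A"]) < 3 * se[names.index("A0")]
        assert abs(k - truth["k1"]) < 3 * se[names.index("k0")]
        a_o, k_o, b_o, _ = grid_fit_single_exponential(curve.times,
                                                       curve.signals)
        assert abs(k - k_o) / k_o < 5e-4  # 4 significant figures
        assert abs(a - a_o) / abs(a_o) < 5e-4

    def test_too_few_points_rejected(self):
        t = np.arange(0, 4, 1.0)
        with pytest.raises(ValueError):
            ck.fit_relaxation(ck.ProgressCurve(times=t, signals=t))
        with pytest.raises(ValueError):
            ck.fit_relaxation(single_exp_curve(), n_components=0,
                              include_linear=False)

    def test_asymptote_identity(self):
        curve = single_exp_curve(A=40.0, k1=0.003, B=2.0)
        fit = ck.fit_relaxation(curve)
        assert fit.asymptote == pytest.approx(42.0, rel=1e-5)
        assert fit.predict(np.array([1e7]))[0] == pytest.approx(42.0, rel=1e-5)

    def test_time_shift_invariance_of_A_and_k(self):
        # re-zeroing on the first point changes B, never A or k1
        curve = single_exp_curve(A=70.0, k1=0.004, B=25.0)
        fit0 = ck.fit_relaxation(curve)
        fit1 = ck.fit_relaxation(ck.subtract_initial(curve))
        assert fit1.components[0][0] == pytest.approx(fit0.components[0][0],
                                                      rel=1e-6)
        assert fit1.components[0][1] == pytest.approx(fit0.components[0][1],
                                                      rel=1e-6)
        assert fit1.B == pytest.approx(fit0.B - 25.0, abs=1e-4)


class TestRunsTest:
    @pytest.mark.parametrize("signs", [
        [1, -1, 1, -1, 1, -1, 1, -1, 1, -1],
        [1, 1, 1, 1, -1, -1, -1, -1, 1, 1, 1, 1],
        [1, 1, -1, 1, -1, -1, 1, -1, 1, 1],
        [-1] * 6 + [1] * 6,
    ])
    def test_exact_p_matches_enumeration(self, signs):
        _, p, _, _ = runs_test_pvalue(np.array(signs, dtype=float))
        assert p == pytest.approx(runs_pvalue_enumeration(signs), abs=1e-12)

    def test_alternating_residuals_not_structured(self):
        fit = ck.fit_relaxation(single_exp_curve())
        fit.residuals = np.array([1.0, -1, 1, -1, 1, -1, 1, -1, 1, -1, 1, -1])
        diag = ck.assess_residual_structure(fit)
        assert not diag.structured
        assert diag.p_value == pytest.approx(1.0)

    def test_blocked_residuals_exact_p(self):
        # ++++−−−−++++: R=3 with n1=8, n2=4; exact lower-tail p = 12/495
        fit = ck.fit_relaxation(single_exp_curve())
        fit.residuals = np.array([1.0] * 4 + [-1.0] * 4 + [1.0] * 4)
        diag = ck.assess_residual_structure(fit, threshold=0.05)
        assert diag.statistic == 3
        assert diag.p_value == pytest.approx(12 / 495)
        assert diag.structured  # at the 0.05 level

    def test_noiseless_matched_model_unstructured(self):
        fit = ck.fit_relaxation(single_exp_curve(A=30.0, k1=0.002, B=3.0))
        diag = ck.assess_residual_structure(fit)
        assert not diag.structured

    def test_few_residuals_inconclusive(self):
        fit = ck.fit_relaxation(single_exp_curve())
        fit.residuals = np.array([1.0, -1, 1, -1, 1])
        diag = ck.assess_residual_structure(fit)
        assert diag.inconclusive and not diag.structured

    def test_normal_approximation_regime(self):
        rng = np.random.default_rng(0)
        signs = np.sign(rng.normal(size=500))
        _, p, _, _ = runs_test_pvalue(signs)
        assert 0.01 < p < 1.0  # random signs should not look structured

    def test_delta_aicc_reported(self):
        fit = ck.fit_relaxation(single_exp_curve(noise_sd=0.5, seed=1))
        diag = ck.assess_residual_structure(fit, next_aicc=fit.aicc - 3.0)
        assert diag.delta_aicc == pytest.approx(-3.0)


class TestAutoFit:
    def test_pure_single_exponential_stays_one_component(self):
        fit = ck.auto_fit(single_exp_curve(A=100.0, k1=0.01, B=5.0,
                                           noise_sd=0.3, seed=8))
        assert len(fit.components) == 1
        assert "m" not in fit.param_names

    def test_exponential_plus_drift_recovers_slope(self):
        t = np.arange(0, 7200, 30.0)
        truth_m = 0.004
        s = 60.0 * (-np.expm1(-0.003 * t)) + truth_m * t + 5.0
        s += np.random.default_rng(3).normal(0, 0.3, t.shape)
        fit = ck.auto_fit(ck.ProgressCurve(times=t, signals=s))
        assert "m" in fit.param_names
        m_se = np.sqrt(fit.covariance[fit.param_names.index("m"),
                                      fit.param_names.index("m")])
        assert abs(fit.linear_slope - truth_m) < 3 * m_se

    def test_two_exponentials_with_20x_rate_ratio(self):
        t = np.arange(0, 6000, 10.0)
        s = (50.0 * (-np.expm1(-0.02 * t)) + 50.0 * (-np.expm1(-0.001 * t))
             + 2.0)
        s += np.random.default_rng(4).normal(0, 0.2, t.shape)
        fit = ck.auto_fit(ck.ProgressCurve(times=t, signals=s))
        assert len(fit.components) == 2
        rates = sorted(k for _, k in fit.components)
        assert rates[0] == pytest.approx(0.001, rel=0.10)
        assert rates[1] == pytest.approx(0.02, rel=0.10)


class TestPreprocessing:
    def test_subtract_self_gives_zero(self):
        c = single_exp_curve(noise_sd=1.0, seed=6)
        diff = ck.subtract_control(c, c)
        assert np.all(diff.signals == 0.0)

    def test_drift_cancellation_preserves_kinetics(self):
        t = np.arange(0, 7200, 60.0)
        rng = np.random.default_rng(12)
        drift = 0.01 * t
        pure = 80.0 * (-np.expm1(-0.002 * t)) + 5.0
        sample = ck.ProgressCurve(times=t, signals=pure + drift
                                  + rng.normal(0, 0.4, t.shape))
        control = ck.ProgressCurve(times=t, signals=5.0 + drift
                                   + rng.normal(0, 0.4, t.shape))
        fit = ck.fit_relaxation(ck.subtract_control(sample, control))
        (a, k), = fit.components
        k_se = np.sqrt(fit.covariance[fit.param_names.index("k0"),
                                      fit.param_names.index("k0")])
        assert abs(k - 0.002) < 3 * k_se

    def test_offset_control_shifts_baseline_only(self):
        c = single_exp_curve(A=40.0, k1=0.005, B=10.0)
        ctrl = ck.ProgressCurve(times=c.times,
                                signals=np.full_like(c.times, 3.0))
        fit = ck.fit_relaxation(ck.subtract_control(c, ctrl))
        assert fit.B == pytest.approx(7.0, abs=1e-5)
        assert fit.components[0][0] == pytest.approx(40.0, rel=1e-6)

    def test_control_grid_mismatch_rejected(self):
        c = single_exp_curve(interval=60.0)
        ctrl = ck.ProgressCurve(times=c.times + 45.0, signals=c.signals)
        with pytest.raises(ValueError, match="half an interval"):
            ck.subtract_control(c, ctrl)

    def test_control_interpolated_within_half_interval(self):
        c = single_exp_curve(A=40.0, k1=0.005, B=10.0, interval=60.0)
        ctrl_t = np.arange(-20.0, 3700.0, 25.0)
        ctrl = ck.ProgressCurve(times=ctrl_t, signals=np.full_like(ctrl_t, 2.0))
        diff = ck.subtract_control(c, ctrl)
        assert np.allclose(diff.signals, c.signals - 2.0)

    def test_subtract_initial_idempotent_and_zero_first(self):
        c = single_exp_curve(B=33.0, noise_sd=0.5, seed=7)
        once = ck.subtract_initial(c)
        assert once.signals[0] == 0.0
        twice = ck.subtract_initial(once)
        assert np.array_equal(once.signals, twice.signals)

    def test_loss_curve_amplitude_recovered_after_rezeroing(self):
        # descending OD-style clearance curve, fast enough to clear nearly
        # all substrate: the fitted asymptotic drop recovers the scattering
        # loss (gain × S0)
        spec = ck.SimulationSpec(kcat=10.0, Km=0.09, enzyme_conc=1000.0,
                                 substrate_concs=(0.4,), gain=1.0,
                                 background=0.05, duration=2e4, interval=50.0,
                                 assay_mode="loss_scatter",
                                 substrate_per_product=ck.PCT_WV_PER_UM_MONOMER)
        curve = ck.subtract_initial(ck.integrated_mm_curve(spec, 0.4))
        assert curve.signals[0] == 0.0 and curve.signals[-1] < 0
        fit = ck.fit_relaxation(curve)
        (a, _k), = fit.components
        assert a < 0
        assert abs(fit.asymptote) == pytest.approx(0.4, rel=0.05)


class TestEndpointRate:
    def test_arithmetic(self):
        t = np.arange(0, 14400, 60.0)
        s = 1.0 - 0.6 * (1 - np.exp(-5 * t / t[-1]))
        curve = ck.ProgressCurve(times=t, signals=s)
        r = ck.endpoint_rate(curve, incubation_time=18 * 3600.0)
        expected = (s.max() - s.min()) / 64800.0
        assert r == pytest.approx(expected)
        assert r == pytest.approx(9.26e-6 * (s.max() - s.min()) / 0.6,
                                  rel=1e-3)

    def test_flat_curve_zero(self):
        t = np.arange(0, 600, 60.0)
        assert ck.endpoint_rate(ck.ProgressCurve(times=t,
                                                 signals=np.ones_like(t)),
                                3600.0) == 0.0

    def test_invalid_inputs(self):
        c = single_exp_curve()
        with pytest.raises(ValueError):
            ck.endpoint_rate(c, 0.0)
        with pytest.raises(ValueError):
            ck.endpoint_rate(ck.ProgressCurve(times=np.array([0.0]),
                                              signals=np.array([1.0])), 60.0)


class TestV0Consistency:
    @pytest.mark.parametrize("s0_frac", [0.02, 0.05, 0.10])
    def test_v0_matches_analytic_initial_velocity(self, s0_frac):
        # noiseless integrated-MM curves at S0 ≤ Km/10: fitted ΣA·k1 within
        # 5% of Vmax·S0/(Km+S0), after conversion through the gain
        spec = ck.SimulationSpec(kcat=1.5, Km=33.0, enzyme_conc=10.0,
                                 substrate_concs=(33.0 * s0_frac,),
                                 gain=2.0, background=4.0,
                                 duration=3600.0, interval=30.0)
        s0 = 33.0 * s0_frac
        curve = ck.integrated_mm_curve(spec, s0)
        fit = ck.fit_relaxation(curve)
        v0_conc = fit.v0_signal / spec.gain
        analytic = spec.vmax_substrate * s0 / (spec.Km + s0)
        assert v0_conc == pytest.approx(analytic, rel=0.05)


@settings(derandomize=True, max_examples=20, deadline=None)
@given(a=st.floats(-200, 200), b=st.floats(-50, 50),
       k=st.floats(1e-4, 0.05))
def test_progress_curve_validation_and_fit_consistency(a, b, k):
    t = np.arange(0, 3600, 60.0)
    s = a * (-np.expm1(-k * t)) + b
    curve = ck.ProgressCurve(times=t, signals=s)
    assert len(curve) == len(t)
    if abs(a) > 1e-3:
        fit = ck.fit_relaxation(curve)
        assert fit.v0_signal == pytest.approx(a * k, rel=1e-3, abs=1e-9)
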