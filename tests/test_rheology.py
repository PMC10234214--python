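"""Constitutive models, fitting, and derived rheological quantities."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aggrheo import (
    FJMParams,
    FitFailureError,
    FlowCurve,
    HBThixoParams,
    NoYieldError,
    OscillatorySweep,
    RecoveryTrace,
    RheoSimSpec,
    check_hysteresis,
    critical_strain,
    fit_fjm,
    fit_hb_thixo,
    fit_recovery,
    fjm_complex_modulus,
    fjm_moduli,
    generate_flow_curve,
    generate_oscillatory_sweep,
    hb_thixo_nonmonotonic,
    hb_thixo_stress,
    hb_thixo_viscosity,
    parallel_plate_correct,
)


def random_fjm(rng):
    a = rng.uniform(0.05, 1.0)
    return FJMParams(
        V=10 ** rng.uniform(-2, 3),
        G=10 ** rng.uniform(-2, 3),
        alpha=a,
        beta=rng.uniform(0.0, a),
        eta0=10 ** rng.uniform(-3, 2),
    )


class TestHBThixoForward:
    def test_hand_value(self):
        p = HBThixoParams(30.0, 1.0, 10.0, 0.5)
        assert hb_thixo_stress(1.0, p) == pytest.approx(25.0)

    def test_lam_zero_is_classic_herschel_bulkley(self):
        p = HBThixoParams(30.0, 0.0, 10.0, 0.5)
        rates = np.logspace(-2, 1, 20)
        np.testing.assert_allclose(
            hb_thixo_stress(rates, p), 30.0 + 10.0 * rates**0.5, rtol=1e-14
        )

    def test_small_rate_limit_is_yield_stress(self):
        p = HBThixoParams(30.0, 1.0, 10.0, 0.5)
        assert hb_thixo_stress(1e-8, p) == pytest.approx(30.0, rel=1e-4)

    def test_viscosity_is_stress_over_rate(self):
        p = HBThixoParams(30.0, 1.0, 10.0, 0.5)
        assert hb_thixo_viscosity(2.0, p) == pytest.approx(
            hb_thixo_stress(2.0, p) / 2.0
        )

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(ValueError):
            hb_thixo_stress(0.0, HBThixoParams(1, 0, 1, 1))


class TestNonMonotonicity:
    def test_lam_zero_is_monotone(self):
        flag, rate = hb_thixo_nonmonotonic(
            HBThixoParams(30.0, 0.0, 10.0, 0.5), (1e-3, 10.0)
        )
        assert flag is False and rate is None

    def test_example_minimizer_matches_grid_scan(self):
        p = HBThixoParams(30.0, 10.0, 1.0, 0.5)
        flag, rate = hb_thixo_nonmonotonic(p, (1e-3, 10.0))
        assert flag is True
        grid = np.logspace(-3, 1, 100_000)
        grid_min = grid[np.argmin(hb_thixo_stress(grid, p))]
        assert rate == pytest.approx(grid_min, rel=0.01)

    def test_minimizer_is_stationary(self):
        p = HBThixoParams(30.0, 10.0, 1.0, 0.5)
        _, rate = hb_thixo_nonmonotonic(p, (1e-3, 10.0))
        eps = rate * 1e-7
        deriv = (
            hb_thixo_stress(rate + eps, p) - hb_thixo_stress(rate - eps, p)
        ) / (2 * eps)
        assert abs(deriv) < 1e-6 * p.sigma0

    @given(
        st.floats(1.0, 100.0),
        st.floats(0.0, 20.0),
        st.floats(0.1, 20.0),
        st.floats(0.2, 1.5),
    )
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_dichotomy_matches_grid_scan(self, sigma0, lam, K, n):
        p = HBThixoParams(sigma0, lam, K, n)
        window = (1e-3, 10.0)
        flag, _ = hb_thixo_nonmonotonic(p, window)
        grid = np.logspace(-3, 1, 20_000)
        d = np.diff(hb_thixo_stress(grid, p))
        grid_nonmono = bool(np.any(d < 0) and np.any(d > 0))
        assert flag == grid_nonmono


class TestFitHBThixo:
    def test_noiseless_round_trip_within_one_percent(self):
        truth = HBThixoParams(29.9, 0.5, 8.0, 0.6)
        rates = tuple(np.logspace(np.log10(0.01), np.log10(5.0), 20))
        curve = generate_flow_curve(RheoSimSpec("hb_thixo", truth, rates))
        fitted, diag = fit_hb_thixo(curve)
        for name in ("sigma0", "lam", "K", "n"):
            assert getattr(fitted, name) == pytest.approx(
                getattr(truth, name), rel=0.01
            )
        assert diag.residual_norm < 1e-8

    def test_lam_zero_curve_recovers_nested_model(self):
        truth = HBThixoParams(25.0, 0.0, 5.0, 0.7)
        rates = tuple(np.logspace(-2, np.log10(5.0), 20))
        curve = generate_flow_curve(RheoSimSpec("hb_thixo", truth, rates))
        fitted, _ = fit_hb_thixo(curve)
        assert fitted.lam < 1e-3

    def test_constant_stress_is_degenerate(self):
        curve = FlowCurve(
            shear_rates=np.logspace(-2, 1, 10), stresses=np.full(10, 5.0)
        )
        with pytest.raises(FitFailureError):
            fit_hb_thixo(curve)

    def test_too_few_points_rejected(self):
        curve = FlowCurve(
            shear_rates=np.logspace(-2, 1, 5), stresses=np.linspace(1, 5, 5)
        )
        with pytest.raises(FitFailureError):
            fit_hb_thixo(curve)


class TestFJMForward:
    def test_matches_complex_modulus_oracle(self, rng):
        for _ in range(300):
            p = random_fjm(rng)
            w = 10 ** rng.uniform(-2, 2)
            gp, gpp = fjm_moduli(w, p)
            gs = fjm_complex_modulus(w, p)
            assert gp == pytest.approx(gs.real, rel=1e-10)
            assert gpp == pytest.approx(gs.imag, rel=1e-10)

    def test_maxwell_limit_closed_form(self):
        p = FJMParams(V=5.0, G=2.0, alpha=1.0, beta=0.0, eta0=0.0)
        w = np.logspace(-1, 1, 9)
        tau = p.V / p.G
        gp, gpp = fjm_moduli(w, p)
        np.testing.assert_allclose(
            gp, p.G * (w * tau) ** 2 / (1 + (w * tau) ** 2), rtol=1e-12
        )
        np.testing.assert_allclose(
            gpp, p.G * (w * tau) / (1 + (w * tau) ** 2), rtol=1e-12
        )

    def test_eta0_adds_exactly_to_loss_modulus(self, rng):
        base = random_fjm(rng)
        p0 = FJMParams(base.V, base.G, base.alpha, base.beta, 0.0)
        p1 = FJMParams(base.V, base.G, base.alpha, base.beta, 7.5)
        w = np.logspace(-1, 1, 7)
        gp0, gpp0 = fjm_moduli(w, p0)
        gp1, gpp1 = fjm_moduli(w, p1)
        np.testing.assert_array_equal(gp0, gp1)
        np.testing.assert_allclose(gpp1 - gpp0, 7.5 * w, rtol=1e-12)

    def test_moduli_nonnegative(self, rng):
        for _ in range(100):
            p = random_fjm(rng)
            gp, gpp = fjm_moduli(10 ** rng.uniform(-2, 2), p)
            assert gp >= 0 and gpp >= 0

    def test_order_invariant_enforced(self):
        with pytest.raises(ValueError):
            FJMParams(V=1.0, G=1.0, alpha=0.3, beta=0.6, eta0=0.0)


class TestFitFJM:
    OMEGAS = tuple(np.logspace(-1, 1, 12))

    def test_noiseless_round_trip_within_two_percent(self):
        truth = FJMParams(V=200.0, G=800.0, alpha=0.6, beta=0.15, eta0=5.0)
        sweep = generate_oscillatory_sweep(
            RheoSimSpec("fjm", truth, self.OMEGAS)
        )
        fitted, diag = fit_fjm(sweep)
        for name in ("V", "G", "alpha", "beta", "eta0"):
            assert getattr(fitted, name) == pytest.approx(
                getattr(truth, name), rel=0.02
            )

    def test_elastic_dominated_sweep_gives_tan_delta_below_one(self):
        truth = FJMParams(V=500.0, G=1000.0, alpha=0.3, beta=0.05, eta0=0.0)
        sweep = generate_oscillatory_sweep(
            RheoSimSpec("fjm", truth, self.OMEGAS)
        )
        assert np.all(sweep.g_prime > sweep.g_double_prime)
        _, diag = fit_fjm(sweep)
        assert np.all(diag.tan_delta < 1.0)

    def test_equal_orders_give_constant_tan_delta(self):
        a = 0.4
        truth = FJMParams(V=300.0, G=700.0, alpha=a, beta=a, eta0=0.0)
        sweep = generate_oscillatory_sweep(
            RheoSimSpec("fjm", truth, self.OMEGAS)
        )
        _, diag = fit_fjm(sweep)
        td = diag.tan_delta
        assert np.ptp(td) / np.median(td) < 0.01
        assert np.median(td) == pytest.approx(np.tan(np.pi * a / 2), rel=0.01)

    def test_amplitude_sweep_rejected(self):
        sweep = OscillatorySweep(
            abscissa=np.logspace(-4, -1, 10),
            g_prime=np.full(10, 100.0),
            g_double_prime=np.full(10, 10.0),
            mode="amplitude",
        )
        with pytest.raises(ValueError):
            fit_fjm(sweep)


class TestCriticalStrain:
    @staticmethod
    def piecewise_sweep(scale=1.0, yield_strain=0.03):
        strain = np.logspace(-4, np.log10(0.5), 60)
        gp = np.where(
            strain <= yield_strain,
            1000.0,
            1000.0 * (strain / yield_strain) ** -2.0,
        )
        return OscillatorySweep(
            abscissa=strain,
            g_prime=gp * scale,
            g_double_prime=np.full_like(strain, 100.0) * scale,
            mode="amplitude",
        )

    def test_piecewise_plateau_yields_near_construction(self):
        strain_c = critical_strain(self.piecewise_sweep())
        assert strain_c == pytest.approx(0.03, rel=0.10)

    def test_constant_modulus_reports_no_yield(self):
        sweep = OscillatorySweep(
            abscissa=np.logspace(-4, -1, 20),
            g_prime=np.full(20, 500.0),
            g_double_prime=np.full(20, 50.0),
            mode="amplitude",
        )
        with pytest.raises(NoYieldError):
            critical_strain(sweep)

    def test_scale_invariance(self):
        assert critical_strain(self.piecewise_sweep(1.0)) == pytest.approx(
            critical_strain(self.piecewise_sweep(137.0))
        )


class TestRecovery:
    def test_round_trip_within_one_percent(self):
        t = np.linspace(0, 60, 40)
        g = 500.0 - (500.0 - 100.0) * np.exp(-t / 10.0)
        fit = fit_recovery(RecoveryTrace(time=t, g_prime=g))
        assert fit.g_inf == pytest.approx(500.0, rel=0.01)
        assert fit.g0 == pytest.approx(100.0, rel=0.01)
        assert fit.tau_r == pytest.approx(10.0, rel=0.01)
        assert fit.tau_identifiable

    def test_constant_trace_flagged_unidentifiable(self):
        t = np.linspace(0, 10, 8)
        fit = fit_recovery(RecoveryTrace(time=t, g_prime=np.full(8, 250.0)))
        assert fit.g_inf == fit.g0 == 250.0
        assert not fit.tau_identifiable

    def test_fitted_curve_at_time_zero_equals_g0(self):
        t = np.linspace(0, 30, 25)
        g = 400.0 - 300.0 * np.exp(-t / 5.0)
        fit = fit_recovery(RecoveryTrace(time=t, g_prime=g))
        value_at_zero = fit.g_inf - (fit.g_inf - fit.g0)
        assert value_at_zero == pytest.approx(g[0], rel=1e-6)


class TestParallelPlate:
    def test_newtonian_unchanged(self):
        rates = np.logspace(-2, 1, 10)
        curve = FlowCurve(shear_rates=rates, stresses=3.0 * rates)
        out = parallel_plate_correct(curve)
        np.testing.assert_allclose(out.stresses, curve.stresses, rtol=1e-12)
        assert out.corrected

    @pytest.mark.parametrize("n", [0.3, 0.5, 0.8])
    def test_power_law_uniform_factor(self, n):
        rates = np.logspace(-2, 1, 12)
        curve = FlowCurve(shear_rates=rates, stresses=7.0 * rates**n)
        out = parallel_plate_correct(curve)
        np.testing.assert_allclose(
            out.stresses / curve.stresses, (3.0 + n) / 4.0, rtol=0.005
        )

    def test_double_correction_rejected(self):
        rates = np.logspace(-2, 1, 6)
        out = parallel_plate_correct(
            FlowCurve(shear_rates=rates, stresses=2.0 * rates)
        )
        with pytest.raises(ValueError):
            parallel_plate_correct(out)


class TestHysteresis:
    def test_identical_branches_not_flagged(self):
        rates = np.logspace(-2, np.log10(5), 10)
        p = HBThixoParams(30.0, 0.5, 8.0, 0.6)
        down = FlowCurve(shear_rates=rates[::-1],
                         stresses=hb_thixo_stress(rates[::-1], p))
        up = FlowCurve(shear_rates=rates, stresses=hb_thixo_stress(rates, p))
        flagged, med = check_hysteresis(down, up)
        assert not flagged and med == pytest.approx(0.0)

    def test_shifted_branch_flagged(self):
        rates = np.logspace(-2, np.log10(5), 10)
        p = HBThixoParams(30.0, 0.5, 8.0, 0.6)
        down = FlowCurve(shear_rates=rates, stresses=hb_thixo_stress(rates, p))
        up = FlowCurve(shear_rates=rates,
                       stresses=1.3 * hb_thixo_stress(rates, p))
        flagged, med = check_hysteresis(down, up)
        assert flagged and med > 0.1
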