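"""Integration, time-averaged fluxes, output metrics and steady states."""

import numpy as np
import pytest

import cysredox as cx
from cysredox.exceptions import MappingError, ValidationError


def reference_rk4(y0, params, t_end, n_steps):
    """Independent fixed-step RK4 written from scratch for cross-checking."""
    h = t_end / n_steps
    y = np.asarray(y0, dtype=float).copy()
    out = [y.copy()]
    for _ in range(n_steps):
        k1 = cx.rhs(np.maximum(y, 0), params)
        k2 = cx.rhs(np.maximum(y + 0.5 * h * k1, 0), params)
        k3 = cx.rhs(np.maximum(y + 0.5 * h * k2, 0), params)
        k4 = cx.rhs(np.maximum(y + h * k3, 0), params)
        y = y + (h / 6) * (k1 + 2 * k2 + 2 * k3 + k4)
        out.append(y.copy())
    return np.array(out)


class TestIntegrate:
    def test_atp_decays_in_closed_form_with_sources_off(self, params):
        p = params.replace(Cext=0.0, kROS=0.0)
        A0 = 2.0
        traj = cx.integrate(cx.State(0, 0, 0, 0, A0), p, 24.0)
        expected = A0 * np.exp(-p.kAd * traj.t)
        np.testing.assert_allclose(traj.y[:, 4], expected, rtol=1e-6, atol=1e-10)
        np.testing.assert_allclose(traj.y[:, :4], 0.0, atol=1e-10)

    def test_h2s_decays_in_closed_form_without_cysteine(self, params):
        p = params.replace(Cext=0.0, kROS=0.0)
        S0 = 0.8
        traj = cx.integrate(cx.State(0, 0, 0, S0, 0), p, 24.0)
        np.testing.assert_allclose(traj.y[:, 3], S0 * np.exp(-p.kS * traj.t), rtol=1e-6)

    def test_adaptive_solution_matches_independent_rk4(self, params, y0, nominal_traj):
        ref = reference_rk4(y0.as_array(), params, 24.0, 4800)
        ts = np.linspace(0, 24, 4801)
        got = nominal_traj.state_at(ts)
        scale = np.max(np.abs(ref), axis=0)
        assert np.max(np.abs(got - ref) / scale) <= 1e-4

    def test_fast_path_matches_adaptive(self, params, y0, nominal_traj):
        fast = cx.integrate(y0, params, 24.0, method="rk4", dt=0.02)
        assert np.max(np.abs(nominal_traj.state_at(fast.t) - fast.y)) < 1e-6

    def test_first_state_is_initial_condition(self, params, y0, nominal_traj):
        np.testing.assert_array_equal(nominal_traj.y[0], y0.as_array())

    def test_trajectory_nonnegative_within_solver_tolerance(self, nominal_traj):
        assert nominal_traj.y.min() >= -1e-8

    def test_deterministic(self, params, y0):
        a = cx.integrate(y0, params, 24.0)
        b = cx.integrate(y0, params, 24.0)
        np.testing.assert_array_equal(a.y, b.y)

    def test_output_grid_refinement_consistency(self, params, y0):
        coarse = cx.integrate(y0, params, 24.0, n_out=49)
        fine = cx.integrate(y0, params, 24.0, n_out=971)
        ts = np.linspace(0, 24, 100)
        assert np.max(np.abs(coarse.state_at(ts) - fine.state_at(ts))) < 1e-7

    def test_invalid_arguments(self, params, y0):
        with pytest.raises(ValidationError):
            cx.integrate(y0, params, -1.0)
        with pytest.raises(ValidationError):
            cx.integrate(y0, params, 24.0, rtol=0.0)


class TestMeanModelFlux:
    def test_constant_uptake_is_exact(self, params, nominal_traj):
        v = cx.mean_model_flux(nominal_traj, params, "uptake", (0, 24))
        assert v == params.kin * params.Cext

    def test_atp_decay_against_analytic_integral(self, params):
        p = params.replace(Cext=0.0, kROS=0.0)
        A0 = 2.0
        traj = cx.integrate(cx.State(0, 0, 0, 0, A0), p, 24.0)
        got = cx.mean_model_flux(traj, p, "atp_decay", (0, 24))
        expected = p.kAd * A0 * (1 - np.exp(-p.kAd * 24)) / (p.kAd * 24)
        assert got == pytest.approx(expected, rel=1e-7)

    @pytest.mark.parametrize("term", ["gsh_synthesis", "ros_detox", "atp_sulfide"])
    def test_agrees_with_dense_trapezoid_oracle(self, params, nominal_traj, term):
        from cysredox.model import flux_terms_arrays

        ts = np.linspace(0, 24, 10_001)
        vals = flux_terms_arrays(nominal_traj.state_at(ts), params)[term]
        oracle = np.trapezoid(vals, ts) / 24.0
        assert cx.mean_model_flux(nominal_traj, params, term, (0, 24)) == pytest.approx(
            oracle, rel=1e-5
        )

    def test_quadrature_refinement_stable(self, params, nominal_traj):
        a = cx.mean_model_flux(nominal_traj, params, "ros_detox", (0, 24), n_quad=1001)
        b = cx.mean_model_flux(nominal_traj, params, "ros_detox", (0, 24), n_quad=4001)
        assert abs(a - b) <= 1e-6 * abs(b)

    def test_unknown_term_raises_lookup_error(self, params, nominal_traj):
        with pytest.raises(MappingError, match="unknown flux term"):
            cx.mean_model_flux(nominal_traj, params, "glycolysis")


class TestOutputMetrics:
    @staticmethod
    def _flat_traj(A=1.0, R=1.0):
        ts = np.linspace(0, 24, 25)
        ys = np.zeros((25, 5))
        ys[:, 4] = A
        ys[:, 2] = R
        return cx.Trajectory(ts, ys)

    def test_constant_trajectory(self):
        m = cx.output_metrics(self._flat_traj(1.0, 1.0))
        assert m.A24 == pytest.approx(1.0)
        assert m.ATPint == pytest.approx(24.0)
        assert m.ROSint == pytest.approx(24.0)
        assert m.fitness_ratio == pytest.approx(1.0)

    def test_proportional_signals_give_ratio(self):
        m = cx.output_metrics(self._flat_traj(2.0, 1.0))
        assert m.fitness_ratio == pytest.approx(2.0)

    def test_zero_ros_reports_undefined_flag(self):
        m = cx.output_metrics(self._flat_traj(1.0, 0.0))
        assert not m.fitness_defined
        assert np.isnan(m.fitness_ratio)

    def test_nominal_metrics_match_dense_oracle(self, nominal_traj):
        m = cx.output_metrics(nominal_traj)
        ts = np.linspace(0, 24, 10_001)
        states = nominal_traj.state_at(ts)
        assert m.ATPint == pytest.approx(np.trapezoid(states[:, 4], ts), rel=1e-5)
        assert m.ROSint == pytest.approx(np.trapezoid(states[:, 2], ts), rel=1e-5)

    def test_solver_tolerance_self_consistency(self, params, y0):
        loose = cx.output_metrics(cx.integrate(y0, params, 24.0, rtol=1e-6, atol=1e-8))
        tight = cx.output_metrics(cx.integrate(y0, params, 24.0, rtol=1e-7, atol=1e-9))
        for attr in ("A24", "ATPint", "ROSint"):
            a, b = getattr(loose, attr), getattr(tight, attr)
            assert abs(a - b) <= 1e-6 * max(1.0, abs(b))


class TestSteadyState:
    def test_converges_to_origin_with_sources_off(self, params):
        p = params.replace(Cext=0.0, kROS=0.0)
        res = cx.find_steady_state(p, cx.State(0, 0, 0, 0, 1.0), tolerance=1e-10)
        assert res.converged
        assert res.residual_norm <= 1e-10
        assert np.max(res.state.as_array()) < 1e-6

    def test_balanced_parameters_reach_redox_balance(self, params, y0):
        # repo defaults are constructed to satisfy the equilibrium identity
        res = cx.find_steady_state(params, y0, tolerance=1e-10)
        assert res.converged
        lhs = params.kRG * res.state.G * res.state.R
        rhs = (1 + params.beta * params.H) * params.kROS
        assert abs(lhs - rhs) <= 10 * 1e-10

    def test_unbalanced_parameters_report_nonconvergence_in_redox(self, params, y0):
        p = params.replace(kROS=3 * params.kROS)  # breaks the balance
        res = cx.find_steady_state(p, y0, tolerance=1e-10, t_max=500.0)
        assert not res.converged
        deriv = np.abs(cx.rhs(np.maximum(res.state.as_array(), 0), p))
        # residual concentrated in the G/R components
        assert max(deriv[1], deriv[2]) == pytest.approx(res.residual_norm, rel=1e-6)
        assert max(deriv[0], deriv[3], deriv[4]) < res.residual_norm / 10

    def test_polish_reduces_residual(self, params, y0):
        rough = cx.find_steady_state(params, y0, tolerance=1e-8, polish=False)
        polished = cx.find_steady_state(params, y0, tolerance=1e-8, polish=True)
        assert polished.residual_norm <= rough.residual_norm

    def test_structural_zero_eigenvalue_at_steady_state(self, params, y0):
        res = cx.find_steady_state(params, y0)
        assert np.min(np.abs(res.eigenvalues)) <= 1e-12
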