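"""Bootstrap ensembles, identifiability summaries, Hessian conditioning and
the steady-state identity for the hypoxia ROS-amplification factor."""

import numpy as np
import pytest

import cysredox as cx
from cysredox.calibrate import CalibrationProblem
from cysredox.exceptions import NotIdentifiableError, ValidationError
from cysredox.fluxes import FluxDataset, FluxObservation, ObservableMapping
from cysredox.uncertainty import (
    BootstrapEnsemble,
    beta_from_steady_state,
    bootstrap,
    finite_difference_hessian,
    hessian_condition,
    summarize,
)


@pytest.fixture(scope="module")
def kin_problem(params):
    dataset = FluxDataset([FluxObservation("cysteine", "cond", 1.0, 0.0081)])
    return CalibrationProblem(
        dataset=dataset,
        mapping=ObservableMapping({"cysteine": [("uptake", 1)]}),
        fixed=params,
        calibrated_names=("kin",),
        bounds={"kin": (1e-3, 1.0)},
    )


class TestBootstrap:
    def test_zero_noise_collapses_to_point_estimate(self, kin_problem):
        ens = bootstrap(kin_problem, B=5, noise_scale=0.0, seed=1, n_starts=1)
        # replicates see identical data; spread is optimizer rounding only
        assert np.ptp(ens.thetas) <= 1e-12 * np.abs(ens.thetas).max()

    def test_same_seed_gives_identical_ensembles(self, kin_problem):
        a = bootstrap(kin_problem, B=10, noise_scale=0.05, seed=3, n_starts=1)
        b = bootstrap(kin_problem, B=10, noise_scale=0.05, seed=3, n_starts=1)
        np.testing.assert_array_equal(a.thetas, b.thetas)

    def test_cv_tracks_noise_scale_analytically(self, kin_problem, params):
        # kin_hat^(b) = v*(1+eps_b)/Cext, so the ensemble CV estimates the
        # noise scale directly (sampling error ~ sigma/sqrt(2B))
        ens = bootstrap(kin_problem, B=500, noise_scale=0.05, seed=11, n_starts=1)
        summary = summarize(ens)
        cv = summary.table.loc["kin", "cv_percent"]
        assert cv == pytest.approx(5.0, abs=0.6)
        expected = 0.0081 * (1 + 0.0) / params.Cext
        assert summary.table.loc["kin", "mean"] == pytest.approx(expected, rel=0.01)

    def test_cv_nondecreasing_in_noise_scale(self, kin_problem):
        cvs = []
        for sigma in (0.01, 0.02, 0.05):
            ens = bootstrap(kin_problem, B=100, noise_scale=sigma, seed=13, n_starts=1)
            cvs.append(summarize(ens).table.loc["kin", "cv_percent"])
        assert cvs[0] < cvs[1] < cvs[2]

    def test_requires_at_least_two_replicates(self, kin_problem):
        with pytest.raises(ValidationError):
            bootstrap(kin_problem, B=1, noise_scale=0.05, seed=1)


class TestSummarize:
    @staticmethod
    def _ensemble(columns: dict) -> BootstrapEnsemble:
        names = tuple(columns)
        thetas = np.column_stack([np.asarray(v, float) for v in columns.values()])
        return BootstrapEnsemble(names, thetas, thetas.shape[0], 0, 0.05, None)

    def test_repeated_vector_collapses(self):
        summary = summarize(self._ensemble({"kin": [0.3] * 10}))
        row = summary.table.loc["kin"]
        assert row["std"] == pytest.approx(0.0, abs=1e-15)
        assert row["cv_percent"] == pytest.approx(0.0, abs=1e-12)
        assert row["ci_low"] == row["ci_high"] == 0.3

    def test_hand_computed_five_point_ensemble(self):
        # {1..5}: mean 3, sample std sqrt(2.5); linear-interpolation quantiles
        # q(0.025) = 1 + 0.1*4*0.025... = 1.1, q(0.975) = 4.9
        summary = summarize(self._ensemble({"x": [1, 2, 3, 4, 5]}))
        row = summary.table.loc["x"]
        assert row["mean"] == pytest.approx(3.0)
        assert row["std"] == pytest.approx(np.sqrt(2.5))
        assert row["ci_low"] == pytest.approx(1.1)
        assert row["ci_high"] == pytest.approx(4.9)
        assert not summary.ci_reliable  # B < 40

    def test_perfect_anticorrelation_flagged(self):
        x = np.linspace(1, 2, 50)
        summary = summarize(self._ensemble({"a": x, "b": 3 - x}))
        assert summary.correlation.loc["a", "b"] == pytest.approx(-1.0)
        assert summary.high_correlation_pairs[0][:2] == ("a", "b")

    def test_zero_variance_column_gives_nan_correlation(self):
        summary = summarize(self._ensemble({"a": [1, 2, 3, 4], "b": [2, 2, 2, 2]}))
        assert np.isnan(summary.correlation.loc["a", "b"])
        assert summary.high_correlation_pairs == ()


class TestHessianCondition:
    def test_prescribed_quadratic_eigenvalues(self):
        Q = np.diag([1.0, 100.0])
        H = finite_difference_hessian(lambda x: 0.5 * x @ Q @ x, np.array([0.3, 0.4]))
        kappa = np.abs(np.linalg.eigvalsh(H)).max() / np.abs(np.linalg.eigvalsh(H)).min()
        assert kappa == pytest.approx(100.0, rel=1e-4)

    def test_isotropic_quadratic_is_perfectly_conditioned(self):
        H = finite_difference_hessian(lambda x: float(x @ x), np.array([0.5, -0.2, 1.0]))
        eig = np.linalg.eigvalsh(H)
        assert eig.max() / eig.min() == pytest.approx(1.0, rel=1e-6)

    def test_objective_scaling_leaves_kappa_unchanged(self, kin_problem):
        res = hessian_condition(kin_problem, np.array([0.03]))
        assert res.condition_number == pytest.approx(1.0)  # single parameter
        # scaling invariance on a synthetic 2-parameter quadratic
        f = lambda x: 2.0 * x[0] ** 2 + 50.0 * x[1] ** 2
        for scale in (1.0, 1e3):
            H = finite_difference_hessian(lambda x: scale * f(x), np.array([0.1, 0.1]))
            eig = np.abs(np.linalg.eigvalsh(H))
            assert eig.max() / eig.min() == pytest.approx(25.0, rel=1e-4)

    def test_theta_on_bound_rejected(self, kin_problem):
        with pytest.raises(ValidationError):
            hessian_condition(kin_problem, np.array([1e-3]))


class TestBetaIdentity:
    def test_algebraic_inversion_recovers_known_beta(self, params):
        beta_true, H = 0.5, 1.0
        # construct a balanced redox state: G*R = (1+beta*H)*kROS/kRG
        GR = (1 + beta_true * H) * params.kROS / params.kRG
        G = 0.8
        got = beta_from_steady_state(G, GR / G, params.kRG, params.kROS, H)
        assert got == pytest.approx(beta_true, rel=1e-12)

    def test_normoxic_balance_gives_zero(self, params):
        GR = params.kROS / params.kRG
        for H in (0.3, 0.7, 1.0):
            assert beta_from_steady_state(1.0, GR, params.kRG, params.kROS, H) == pytest.approx(
                0.0, abs=1e-12
            )

    @pytest.mark.parametrize("beta_true", [0.0, 0.5, 1.0, 2.0])
    @pytest.mark.parametrize("H", [0.25, 0.5, 1.0])
    def test_round_trip_identity_over_grid(self, params, beta_true, H):
        GR = (1 + beta_true * H) * params.kROS / params.kRG
        got = beta_from_steady_state(2.0, GR / 2.0, params.kRG, params.kROS, H)
        assert got == pytest.approx(beta_true, rel=1e-10, abs=1e-10)

    def test_normoxia_is_not_identifiable(self, params):
        with pytest.raises(NotIdentifiableError):
            beta_from_steady_state(1.0, 0.01, params.kRG, params.kROS, 0.0)

    def test_identity_holds_at_simulated_steady_state(self, params, y0):
        # find_steady_state at repo defaults, then invert for beta
        res = cx.find_steady_state(params, y0)
        assert res.converged
        got = beta_from_steady_state(
            res.state.G, res.state.R, params.kRG, params.kROS, params.H
        )
        assert got == pytest.approx(params.beta, abs=1e-6)
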