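"""Flux-based model calibration.

The objective is a sum of squared *relative* errors between time-averaged
model fluxes and apparent experimental fluxes, over all mapped metabolites
and experimental conditions:

    J(theta) = sum_i sum_k ((vbar_model_ik(theta) - v_exp_ik) / v_exp_ik)^2

Relative errors keep metabolites with very different absolute scales
comparable.  Minimisation uses bounded trust-region least squares restarted
from multiple uniform draws within the bounds (the landscape can be
multimodal when several saturable branches compete for the same substrate).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

from .exceptions import CalibrationError, IntegrationError, ValidationError
from .fluxes import FluxDataset, ObservableMapping
from .model import CALIBRATED_NAMES, ModelParameters, State, flux_terms_arrays
from .model import STATE_INDEPENDENT_TERMS
from .simulate import integrate, mean_model_flux

__all__ = [
    "CalibrationProblem",
    "CalibrationResult",
    "IdentifiabilityWarning",
    "objective",
    "residuals",
    "calibrate",
]


class IdentifiabilityWarning(UserWarning):
    """Fewer informative observables than calibrated parameters."""


@dataclass
class CalibrationProblem:
    """Everything needed to evaluate and minimise the flux objective.

    ``condition_params`` optionally overrides parameters per condition
    (typically ``Cext`` for supplemented media); ``H`` always comes from the
    dataset rows.  ``solver_options`` are forwarded to
    :func:`cysredox.simulate.integrate`; the default fixed-step compiled
    solver keeps multi-start/bootstrap loops affordable while remaining well
    inside quadrature accuracy for 24 h windows.
    """

    dataset: FluxDataset
    mapping: ObservableMapping
    fixed: ModelParameters
    calibrated_names: Sequence[str] = CALIBRATED_NAMES
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    initial_state: State = field(
        default_factory=lambda: State(C=0.05, G=1.0, R=0.01, S=0.05, A=1.0)
    )
    window: tuple[float, float] = (0.0, 24.0)
    condition_params: dict[str, dict[str, float]] = field(default_factory=dict)
    solver_options: dict = field(default_factory=lambda: {"method": "rk4", "dt": 0.02})

    def __post_init__(self):
        self.calibrated_names = tuple(self.calibrated_names)
        if not self.calibrated_names:
            raise ValidationError("calibrated_names must be non-empty")
        unknown = set(self.calibrated_names) - set(CALIBRATED_NAMES)
        if unknown:
            raise ValidationError(
                f"calibrated_names must be a subset of {CALIBRATED_NAMES}, "
                f"got extras {sorted(unknown)}"
            )
        for name in self.calibrated_names:
            if name not in self.bounds:
                raise ValidationError(f"missing bounds for calibrated parameter {name!r}")
            lo, hi = self.bounds[name]
            if not lo < hi:
                raise ValidationError(f"bounds for {name!r} must satisfy lo < hi")
            if name != "beta" and lo <= 0:
                raise ValidationError(f"lower bound for rate/flux {name!r} must be positive")
            if name == "beta" and lo < 0:
                raise ValidationError("lower bound for 'beta' must be nonnegative")
        used = self.used_observations()
        if not used:
            raise ValidationError("no dataset metabolite is covered by the mapping")
        for obs in used:
            if obs.v_exp == 0:
                raise ValidationError(
                    f"v_exp = 0 for {obs.metabolite!r}/{obs.condition!r}: "
                    "relative error undefined"
                )
        if len(used) < len(self.calibrated_names):
            warnings.warn(
                f"{len(used)} mapped flux observations constrain "
                f"{len(self.calibrated_names)} parameters; expect practical "
                "non-identifiability",
                IdentifiabilityWarning,
                stacklevel=2,
            )

    def used_observations(self):
        return [o for o in self.dataset if o.metabolite in self.mapping]

    def bounds_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.array([self.bounds[n][0] for n in self.calibrated_names])
        hi = np.array([self.bounds[n][1] for n in self.calibrated_names])
        return lo, hi

    def params_for(self, theta: np.ndarray, condition: str, H: float) -> ModelParameters:
        changes = dict(zip(self.calibrated_names, (float(t) for t in theta)))
        changes.update(self.condition_params.get(condition, {}))
        changes["H"] = H
        return self.fixed.replace(**changes)


def _state_independent_value(term: str, params: ModelParameters) -> float:
    return float(flux_terms_arrays(np.zeros((1, 5)), params)[term][0])


def residuals(theta, problem: CalibrationProblem) -> np.ndarray:
    """Vector of relative flux errors, one per mapped observation."""
    theta = np.asarray(theta, dtype=float)
    out = []
    with_noise = problem.used_observations()
    for condition, H in problem.dataset.conditions.items():
        cond_obs = [o for o in with_noise if o.condition == condition]
        if not cond_obs:
            continue
        params = problem.params_for(theta, condition, H)
        needed = {
            term
            for o in cond_obs
            for term, _ in problem.mapping.terms_for(o.metabolite)
        }
        traj = None
        if not needed <= STATE_INDEPENDENT_TERMS:
            try:
                traj = integrate(
                    problem.initial_state,
                    params,
                    t_end=problem.window[1],
                    **problem.solver_options,
                )
            except IntegrationError as exc:
                raise IntegrationError(
                    f"condition {condition!r}: {exc}", t_fail=exc.t_fail
                ) from exc
        for o in cond_obs:
            v_model = 0.0
            for term, sign in problem.mapping.terms_for(o.metabolite):
                if term in STATE_INDEPENDENT_TERMS:
                    v_model += sign * _state_independent_value(term, params)
                else:
                    v_model += sign * mean_model_flux(traj, params, term, problem.window)
            out.append((v_model - o.v_exp) / o.v_exp)
    return np.array(out)


def objective(theta, problem: CalibrationProblem) -> float:
    """Sum of squared relative flux errors (dimensionless, >= 0)."""
    r = residuals(theta, problem)
    return float(np.dot(r, r))


@dataclass(frozen=True)
class StartRecord:
    start: np.ndarray
    solution: Optional[np.ndarray]
    objective: float
    success: bool
    message: str


@dataclass(frozen=True)
class CalibrationResult:
    names: tuple[str, ...]
    theta_hat: dict[str, float]
    J_min: float
    per_start: tuple[StartRecord, ...]
    n_starts: int
    seed: Optional[int]

    @property
    def theta_array(self) -> np.ndarray:
        return np.array([self.theta_hat[n] for n in self.names])


def calibrate(
    problem: CalibrationProblem,
    n_starts: int = 25,
    seed: Optional[int] = None,
    *,
    xtol: float = 1e-12,
    ftol: float = 1e-12,
    gtol: float = 1e-12,
) -> CalibrationResult:
    """Multi-start bounded least squares over the calibrated subset.

    Starts are drawn uniformly within the bounds from a generator seeded by
    ``seed``; results are deterministic given (seed, n_starts, tolerances).
    """
    if n_starts < 1:
        raise ValidationError("n_starts must be >= 1")
    lo, hi = problem.bounds_arrays()
    rng = np.random.default_rng(seed)
    starts = rng.uniform(lo, hi, size=(int(n_starts), lo.size))

    records: list[StartRecord] = []
    for x0 in starts:
        try:
            res = least_squares(
                residuals,
                x0,
                args=(problem,),
                bounds=(lo, hi),
                method="trf",
                xtol=xtol,
                ftol=ftol,
                gtol=gtol,
            )
            records.append(
                StartRecord(x0.copy(), res.x.copy(), float(2.0 * res.cost), True, res.message)
            )
        except (IntegrationError, np.linalg.LinAlgError) as exc:
            records.append(StartRecord(x0.copy(), None, np.inf, False, str(exc)))

    ok = [r for r in records if r.success]
    if not ok:
        raise CalibrationError(
            "all optimisation starts failed", diagnostics=[r.message for r in records]
        )
    best = min(ok, key=lambda r: r.objective)
    theta_hat = dict(zip(problem.calibrated_names, (float(v) for v in best.solution)))
    return CalibrationResult(
        names=tuple(problem.calibrated_names),
        theta_hat=theta_hat,
        J_min=best.objective,
        per_start=tuple(records),
        n_starts=int(n_starts),
        seed=seed,
    )
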