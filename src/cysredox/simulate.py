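"""Numerical integration, time-averaged flux observables, output metrics and
steady states.

The default solver is stiff-capable adaptive LSODA with tight tolerances
(rtol 1e-8, atol 1e-10): the bilinear GSH-ROS term can become stiff when ROS
grows.  A compiled fixed-step RK4 path (``method="rk4"``) serves
evaluation-heavy workloads.

Steady states are computed operationally by integrating to convergence and
checking the residual ``max |dX/dt|``, not by root finding: the Jacobian is
structurally singular (neutral (G, R) direction), so plain Newton iteration
is ill-posed.  A pseudo-inverse Newton polish is available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.integrate import simpson, solve_ivp

from .exceptions import IntegrationError, MappingError, ValidationError
from .model import (
    FLUX_TERM_NAMES,
    STATE_INDEPENDENT_TERMS,
    ModelParameters,
    State,
    _coerce_state,
    flux_terms_arrays,
    jacobian,
    rhs_array,
)

__all__ = [
    "Trajectory",
    "OutputMetrics",
    "SteadyStateResult",
    "integrate",
    "mean_model_flux",
    "output_metrics",
    "find_steady_state",
]

_ADAPTIVE_METHODS = {"lsoda": "LSODA", "bdf": "BDF", "rk45": "RK45"}


@dataclass
class Trajectory:
    """Solution of the model on [0, t_end].

    ``t`` is a strictly increasing grid (h) and ``y`` the matching (n, 5)
    state array.  ``state_at`` evaluates at arbitrary times: through the
    solver's dense interpolant when available, otherwise by linear
    interpolation on the stored grid (the fixed-step path stores a grid fine
    enough for the two to agree within solver tolerance).
    """

    t: np.ndarray
    y: np.ndarray
    dense: Optional[Callable] = field(default=None, repr=False)

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.t.ndim != 1 or self.y.shape != (self.t.size, 5):
            raise ValidationError("trajectory arrays have inconsistent shapes")
        if np.any(np.diff(self.t) <= 0):
            raise ValidationError("trajectory times must be strictly increasing")
        if not np.all(np.isfinite(self.y)):
            raise ValidationError("trajectory contains non-finite states")

    @property
    def t_span(self) -> tuple[float, float]:
        return float(self.t[0]), float(self.t[-1])

    def state_at(self, times) -> np.ndarray:
        """State at time(s) ``times``; shape (5,) for a scalar, else (m, 5)."""
        scalar = np.isscalar(times)
        ts = np.atleast_1d(np.asarray(times, dtype=float))
        if ts.min() < self.t[0] - 1e-12 or ts.max() > self.t[-1] + 1e-12:
            raise ValidationError("requested time outside the trajectory span")
        if self.dense is not None:
            out = np.asarray(self.dense(ts)).T
        else:
            out = np.column_stack([np.interp(ts, self.t, self.y[:, i]) for i in range(5)])
        return out[0] if scalar else out


def integrate(
    initial,
    params: ModelParameters,
    t_end: float = 24.0,
    *,
    method: str = "lsoda",
    rtol: float = 1e-8,
    atol: float = 1e-10,
    dt: float = 0.02,
    n_out: int = 481,
) -> Trajectory:
    """Integrate the model from ``initial`` over [0, t_end] hours.

    ``method`` is one of ``"lsoda"`` (default), ``"bdf"``, ``"rk45"``
    (adaptive, via scipy, with dense output) or ``"rk4"`` (compiled fixed
    step ``dt``).  Deterministic for identical inputs and options.
    """
    if t_end <= 0:
        raise ValidationError(f"t_end must be positive, got {t_end}")
    if rtol <= 0 or atol <= 0:
        raise ValidationError("solver tolerances must be positive")
    y0 = _coerce_state(initial)

    if method == "rk4":
        from ._fast import rk4_integrate

        ts, ys = rk4_integrate(params.as_array(), y0, float(t_end), float(dt))
        if not np.all(np.isfinite(ys)):
            bad = int(np.argmax(~np.all(np.isfinite(ys), axis=1)))
            raise IntegrationError(
                f"fixed-step integration diverged near t={ts[bad]:.3g} h", t_fail=float(ts[bad])
            )
        return Trajectory(ts, ys)

    if method not in _ADAPTIVE_METHODS:
        raise ValidationError(f"unknown method {method!r}")
    sol = solve_ivp(
        lambda t, y: rhs_array(y, params),
        (0.0, float(t_end)),
        y0,
        method=_ADAPTIVE_METHODS[method],
        rtol=rtol,
        atol=atol,
        dense_output=True,
        t_eval=np.linspace(0.0, float(t_end), int(n_out)),
    )
    if not sol.success:
        t_fail = float(sol.t[-1]) if sol.t.size else 0.0
        raise IntegrationError(f"solver failed near t={t_fail:.6g} h: {sol.message}", t_fail=t_fail)
    return Trajectory(sol.t, sol.y.T, dense=sol.sol)


def _resolve_window(traj: Trajectory, window) -> tuple[float, float]:
    t0, t1 = traj.t_span if window is None else (float(window[0]), float(window[1]))
    lo, hi = traj.t_span
    if not (lo - 1e-12 <= t0 < t1 <= hi + 1e-12):
        raise ValidationError(f"window ({t0}, {t1}) outside trajectory span ({lo}, {hi})")
    return t0, t1


def mean_model_flux(
    traj: Trajectory,
    params: ModelParameters,
    term: str,
    window=None,
    *,
    n_quad: int = 2001,
) -> float:
    """Time average of a named flux term over ``window`` (default: full span).

    Computed as ``(1/(t1-t0)) * int term(t) dt`` by composite Simpson
    quadrature on a dense resampling of the trajectory.  Terms that do not
    depend on the state (``uptake``, ``ros_production``) are returned exactly.
    """
    if term not in FLUX_TERM_NAMES:
        raise MappingError(f"unknown flux term {term!r}; available: {list(FLUX_TERM_NAMES)}")
    t0, t1 = _resolve_window(traj, window)
    if term in STATE_INDEPENDENT_TERMS:
        vals = flux_terms_arrays(np.zeros((1, 5)), params)[term]
        return float(vals[0])
    ts = np.linspace(t0, t1, int(n_quad))
    states = traj.state_at(ts)
    vals = flux_terms_arrays(states, params)[term]
    return float(simpson(vals, x=ts) / (t1 - t0))


@dataclass(frozen=True)
class OutputMetrics:
    """Energetic/redox summary of a 24 h trajectory.

    ``A24`` is ATP at 24 h (mM); ``ATPint`` and ``ROSint`` are the time
    integrals of ATP and ROS over [0, 24] (mM h); ``fitness_ratio`` is
    ATPint/ROSint, defined only when ROSint > 0 (``fitness_defined``).
    """

    A24: float
    ATPint: float
    ROSint: float
    fitness_ratio: float
    fitness_defined: bool


def output_metrics(traj: Trajectory, *, t_end: float = 24.0, n_quad: int = 2001) -> OutputMetrics:
    """Compute the four outputs from a trajectory spanning [0, t_end]."""
    lo, hi = traj.t_span
    if lo > 1e-12 or hi < t_end - 1e-9:
        raise ValidationError(f"trajectory span ({lo}, {hi}) does not cover [0, {t_end}]")
    ts = np.linspace(0.0, t_end, int(n_quad))
    states = traj.state_at(ts)
    A24 = float(traj.state_at(t_end)[4])
    ATPint = float(simpson(states[:, 4], x=ts))
    ROSint = float(simpson(states[:, 2], x=ts))
    defined = ROSint > 0.0
    ratio = ATPint / ROSint if defined else float("nan")
    return OutputMetrics(A24, ATPint, ROSint, ratio, defined)


@dataclass(frozen=True)
class SteadyStateResult:
    """Outcome of integrate-to-convergence steady-state search."""

    state: State
    residual_norm: float  # max |dX/dt|, mM h^-1
    converged: bool
    elapsed_model_time: float  # h
    eigenvalues: np.ndarray  # 5 complex eigenvalues of the Jacobian at state


def _clip_tiny_negatives(y: np.ndarray, floor: float = -1e-8) -> np.ndarray:
    out = y.copy()
    mask = (out < 0) & (out > floor)
    out[mask] = 0.0
    return out


def find_steady_state(
    params: ModelParameters,
    initial,
    *,
    tolerance: float = 1e-10,
    t_max: float = 1e5,
    polish: bool = False,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> SteadyStateResult:
    """Integrate until ``max |dX/dt| <= tolerance`` or model time hits t_max.

    Non-convergence is reported, never raised: away from the redox-balanced
    parameter manifold the neutral (G, R) direction drifts and no strict
    equilibrium exists.  ``polish=True`` runs a few pseudo-inverse Newton
    steps after convergence-by-integration (useful to push the residual to
    rounding level despite the singular Jacobian).
    """
    if tolerance <= 0:
        raise ValidationError("tolerance must be positive")
    y = _coerce_state(initial).copy()
    elapsed = 0.0
    chunk = 10.0
    residual = float(np.max(np.abs(rhs_array(y, params))))
    while residual > tolerance and elapsed < t_max:
        span = min(chunk, t_max - elapsed)
        sol = solve_ivp(
            lambda t, yy: rhs_array(yy, params),
            (0.0, span),
            y,
            method="LSODA",
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            raise IntegrationError(
                f"solver failed near t={elapsed + sol.t[-1]:.6g} h: {sol.message}",
                t_fail=elapsed + float(sol.t[-1]),
            )
        y = _clip_tiny_negatives(sol.y[:, -1])
        elapsed += span
        chunk *= 10.0
        residual = float(np.max(np.abs(rhs_array(y, params))))
    converged = residual <= tolerance

    if polish and converged:
        for _ in range(10):
            F = rhs_array(y, params)
            if np.max(np.abs(F)) <= max(1e-15, np.finfo(float).eps * 10):
                break
            J = jacobian(y, params)
            step, *_ = np.linalg.lstsq(J, F, rcond=1e-10)
            y_new = _clip_tiny_negatives(y - step)
            if np.max(np.abs(rhs_array(y_new, params))) >= np.max(np.abs(F)):
                break
            y = y_new
        residual = float(np.max(np.abs(rhs_array(y, params))))

    state = State.from_array(_clip_tiny_negatives(y))
    eig = np.linalg.eigvals(jacobian(state.as_array(), params))
    return SteadyStateResult(state, residual, converged, elapsed, eig)
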