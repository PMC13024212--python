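"""Bootstrap practical-identifiability analysis.

Experimental apparent fluxes carry measurement noise; to propagate it into
parameter uncertainty, each bootstrap replicate perturbs every flux
independently and multiplicatively, ``v -> v * (1 + eps)`` with
``eps ~ Normal(0, noise_scale^2)``, and re-runs the full multi-start
calibration.  Percentile confidence intervals, coefficients of variation and
pairwise Pearson correlations summarise the replicate ensemble; a
finite-difference Hessian of the objective at the optimum quantifies local
curvature conditioning.

The hypoxia ROS-amplification factor also satisfies an algebraic
steady-state identity (the redox balance ``kRG*G*R = (1+beta*H)*kROS``),
which makes it recoverable in closed form from a converged steady state —
provided at least one strictly hypoxic condition is available.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
import pandas as pd

from .calibrate import CalibrationProblem, CalibrationResult, calibrate, objective
from .exceptions import CalibrationError, NotIdentifiableError, ValidationError
from .fluxes import FluxDataset, FluxObservation

__all__ = [
    "BootstrapEnsemble",
    "IdentifiabilitySummary",
    "bootstrap",
    "summarize",
    "finite_difference_hessian",
    "hessian_condition",
    "HessianConditioning",
    "beta_from_steady_state",
]


@dataclass(frozen=True)
class BootstrapEnsemble:
    """Calibrated parameter vectors across bootstrap replicates.

    ``thetas`` has one row per successful replicate; failed replicates are
    excluded and counted in ``n_failed`` so the effective B is transparent.
    """

    names: tuple[str, ...]
    thetas: np.ndarray  # (B_effective, p)
    B_requested: int
    n_failed: int
    noise_scale: float
    seed: Optional[int]

    @property
    def B_effective(self) -> int:
        return self.thetas.shape[0]


def _perturb_dataset(dataset: FluxDataset, eps: np.ndarray) -> FluxDataset:
    rows = []
    for obs, e in zip(dataset, eps):
        rows.append(
            FluxObservation(
                metabolite=obs.metabolite,
                condition=obs.condition,
                H=obs.H,
                v_exp=obs.v_exp * (1.0 + float(e)),
                delta_t=obs.delta_t,
                sd=obs.sd,
            )
        )
    return FluxDataset(rows)


def bootstrap(
    problem: CalibrationProblem,
    B: int = 500,
    noise_scale: float = 0.05,
    seed: Optional[int] = None,
    *,
    n_starts: int = 5,
) -> BootstrapEnsemble:
    """Multiplicative-noise bootstrap of the calibration.

    All randomness flows from ``seed``: the noise matrix (B x n_obs) and the
    per-replicate calibration seeds are drawn up front from one generator,
    so the ensemble is reproducible and independent of execution order.
    """
    if B < 2:
        raise ValidationError("B must be >= 2")
    if noise_scale < 0:
        raise ValidationError("noise_scale must be >= 0")
    rng = np.random.default_rng(seed)
    n_obs = len(problem.dataset)
    eps = rng.normal(0.0, noise_scale, size=(int(B), n_obs)) if noise_scale > 0 else np.zeros((int(B), n_obs))
    calib_seeds = rng.integers(0, 2**31 - 1, size=int(B))

    rows, n_failed = [], 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # per-replicate identifiability warnings repeat
        for b in range(int(B)):
            replica = dataclasses.replace(
                problem, dataset=_perturb_dataset(problem.dataset, eps[b])
            )
            try:
                result = calibrate(replica, n_starts=n_starts, seed=int(calib_seeds[b]))
                rows.append(result.theta_array)
            except (CalibrationError, ValidationError):
                n_failed += 1
    if len(rows) < 2:
        raise CalibrationError(f"bootstrap produced {len(rows)} usable replicates (of {B})")
    return BootstrapEnsemble(
        names=tuple(problem.calibrated_names),
        thetas=np.vstack(rows),
        B_requested=int(B),
        n_failed=n_failed,
        noise_scale=float(noise_scale),
        seed=seed,
    )


@dataclass(frozen=True)
class IdentifiabilitySummary:
    """Per-parameter dispersion statistics and the correlation structure."""

    table: pd.DataFrame  # index: parameter; columns: mean, std, ci_low, ci_high, cv_percent
    correlation: pd.DataFrame  # p x p Pearson correlations (NaN where undefined)
    high_correlation_pairs: tuple[tuple[str, str, float], ...]  # |rho| > threshold
    ci_reliable: bool  # percentile CIs need a reasonably large ensemble
    correlation_threshold: float


def summarize(
    ensemble: BootstrapEnsemble, *, correlation_threshold: float = 0.9
) -> IdentifiabilitySummary:
    """Percentile 95% CIs (linear-interpolation quantiles), CVs, correlations.

    CIs are the empirical 2.5/97.5 percentiles of the replicate ensemble.
    ``cv_percent`` is 100*std/mean, reported only for positive-mean
    parameters.  Pairs with |Pearson rho| above the threshold are flagged as
    near-singular dependencies; zero-variance columns yield NaN correlations.
    """
    thetas = ensemble.thetas
    mean = thetas.mean(axis=0)
    std = thetas.std(axis=0, ddof=1)
    lo = np.quantile(thetas, 0.025, axis=0, method="linear")
    hi = np.quantile(thetas, 0.975, axis=0, method="linear")
    cv = np.where(mean > 0, 100.0 * std / np.where(mean > 0, mean, 1.0), np.nan)
    table = pd.DataFrame(
        {"mean": mean, "std": std, "ci_low": lo, "ci_high": hi, "cv_percent": cv},
        index=list(ensemble.names),
    )

    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(thetas, rowvar=False)
    corr = np.atleast_2d(corr)
    correlation = pd.DataFrame(corr, index=list(ensemble.names), columns=list(ensemble.names))

    flagged = []
    p = len(ensemble.names)
    for i in range(p):
        for j in range(i + 1, p):
            rho = corr[i, j]
            if np.isfinite(rho) and abs(rho) > correlation_threshold:
                flagged.append((ensemble.names[i], ensemble.names[j], float(rho)))

    return IdentifiabilitySummary(
        table=table,
        correlation=correlation,
        high_correlation_pairs=tuple(flagged),
        ci_reliable=ensemble.B_effective >= 40,
        correlation_threshold=correlation_threshold,
    )


def finite_difference_hessian(
    fun: Callable[[np.ndarray], float], x: np.ndarray, rel_step: float = 1e-4
) -> np.ndarray:
    """Central-difference Hessian, symmetrised."""
    x = np.asarray(x, dtype=float)
    n = x.size
    h = rel_step * np.maximum(np.abs(x), 1e-8)
    H = np.empty((n, n))
    f0 = fun(x)
    for i in range(n):
        ei = np.zeros(n)
        ei[i] = h[i]
        H[i, i] = (fun(x + ei) - 2.0 * f0 + fun(x - ei)) / h[i] ** 2
        for j in range(i + 1, n):
            ej = np.zeros(n)
            ej[j] = h[j]
            H[i, j] = H[j, i] = (
                fun(x + ei + ej) - fun(x + ei - ej) - fun(x - ei + ej) + fun(x - ei - ej)
            ) / (4.0 * h[i] * h[j])
    return 0.5 * (H + H.T)


@dataclass(frozen=True)
class HessianConditioning:
    condition_number: float  # max|eig| / min|eig|
    eigenvalues: np.ndarray
    positive_definite: bool


def hessian_condition(
    problem: CalibrationProblem, theta_hat, rel_step: float = 1e-4
) -> HessianConditioning:
    """Condition number of the objective's Hessian at ``theta_hat``.

    A non-positive-definite numerical Hessian is not an error here (finite
    differences near a flat direction can produce tiny negative curvature);
    the ratio of absolute eigenvalues is returned with the flag cleared.
    """
    theta = np.asarray(theta_hat, dtype=float)
    lo, hi = problem.bounds_arrays()
    if np.any(theta <= lo) or np.any(theta >= hi):
        raise ValidationError("theta_hat must lie strictly inside the bounds")
    H = finite_difference_hessian(lambda th: objective(th, problem), theta, rel_step)
    eig = np.linalg.eigvalsh(H)
    mags = np.abs(eig)
    kappa = float(np.inf) if mags.min() == 0 else float(mags.max() / mags.min())
    pd_flag = bool(np.all(eig > 0))
    if not pd_flag:
        warnings.warn(
            "numerical Hessian is not positive definite; condition number uses "
            "absolute eigenvalues",
            stacklevel=2,
        )
    return HessianConditioning(kappa, eig, pd_flag)


def beta_from_steady_state(
    G_star: float, R_star: float, kRG: float, kROS: float, H: float
) -> float:
    """Invert the steady-state redox balance for the ROS amplification factor.

    From ``kRG*G**R* = (1 + beta*H) * kROS``:
    ``beta = (kRG*G**R*) / (H*kROS) - 1/H``.  Requires a strictly hypoxic
    condition: at H = 0 the balance is independent of beta.
    """
    if kROS <= 0:
        raise ValidationError(f"kROS must be positive, got {kROS}")
    if kRG <= 0:
        raise ValidationError(f"kRG must be positive, got {kRG}")
    if H == 0:
        raise NotIdentifiableError(
            "beta is not identifiable from a normoxic (H = 0) steady state; "
            "at least one strictly hypoxic condition is required"
        )
    return (kRG * G_star * R_star) / (H * kROS) - 1.0 / H
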