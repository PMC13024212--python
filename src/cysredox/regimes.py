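"""Hypoxia continuation: steady states, regime classification, stability.

The hypoxia level H is swept over [0, 1]; at each grid point the model is
integrated to its steady state (warm-started from the previous point by
default) and the Jacobian spectrum is recorded.  Region labels
(plateau / decline / collapse) are an explicitly heuristic thresholding of
the numerical slope of steady-state ATP with respect to H — steep but
continuous shifts, not bifurcations, and no formal bifurcation detection is
claimed or implemented.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import ClassificationError, ValidationError
from .model import ModelParameters, State
from .simulate import SteadyStateResult, find_steady_state

__all__ = [
    "RegimeScan",
    "hypoxia_scan",
    "Region",
    "RegionClassification",
    "classify_regions",
    "StabilityReport",
    "stability_report",
]


@dataclass
class RegimeScan:
    """Steady-state observables and spectra along an H grid."""

    H: np.ndarray
    states: np.ndarray  # (n, 5)
    ATP: np.ndarray
    ROS: np.ndarray
    converged: np.ndarray  # bool
    residuals: np.ndarray
    eigenvalues: np.ndarray  # (n, 5) complex
    max_real_part: np.ndarray
    min_abs_eigenvalue: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "H": self.H,
                "C": self.states[:, 0],
                "G": self.states[:, 1],
                "R": self.states[:, 2],
                "S": self.states[:, 3],
                "A": self.states[:, 4],
                "converged": self.converged,
                "residual": self.residuals,
                "max_real_eig": self.max_real_part,
                "min_abs_eig": self.min_abs_eigenvalue,
            }
        )


def hypoxia_scan(
    params: ModelParameters,
    H_grid: Sequence[float],
    *,
    initial=None,
    warm_start: bool = True,
    steady_state_options: Optional[dict] = None,
) -> RegimeScan:
    """Continuation of the steady state over the H grid.

    Warm-starting reuses the previous converged state as the next initial
    condition; a cold-start mode re-integrates from ``initial`` at every H
    (useful to check for path dependence — none is expected for this model).
    Non-convergence at a grid point is recorded, never raised.
    """
    H_grid = np.asarray(H_grid, dtype=float)
    if np.any(np.diff(H_grid) <= 0):
        raise ValidationError("H_grid must be strictly increasing")
    if H_grid[0] < 0 or H_grid[-1] > 1:
        raise ValidationError("H_grid must lie within [0, 1]")
    if initial is None:
        initial = State(C=0.05, G=1.0, R=0.01, S=0.05, A=1.0)
    opts = dict(steady_state_options or {})
    opts.setdefault("polish", True)

    n = H_grid.size
    states = np.empty((n, 5))
    eigs = np.empty((n, 5), dtype=complex)
    converged = np.zeros(n, dtype=bool)
    residuals = np.empty(n)
    current = initial
    for i, h in enumerate(H_grid):
        result: SteadyStateResult = find_steady_state(params.replace(H=float(h)), current, **opts)
        states[i] = result.state.as_array()
        eigs[i] = result.eigenvalues
        converged[i] = result.converged
        residuals[i] = result.residual_norm
        if warm_start and result.converged:
            current = result.state
    return RegimeScan(
        H=H_grid,
        states=states,
        ATP=states[:, 4],
        ROS=states[:, 2],
        converged=converged,
        residuals=residuals,
        eigenvalues=eigs,
        max_real_part=eigs.real.max(axis=1),
        min_abs_eigenvalue=np.abs(eigs).min(axis=1),
    )


@dataclass(frozen=True)
class Region:
    label: str  # "plateau" | "decline" | "collapse"
    H_start: float
    H_end: float


@dataclass(frozen=True)
class RegionClassification:
    regions: tuple[Region, ...]
    boundaries: tuple[float, ...]  # H values where the label changes
    boundary_uncertainty: float  # one grid step
    note: str = (
        "heuristic slope-threshold classification; boundaries are operational, "
        "not bifurcation points"
    )


def classify_regions(
    scan: RegimeScan,
    *,
    plateau_threshold: float = 0.05,
    collapse_threshold: float = 0.5,
) -> RegionClassification:
    """Label contiguous H ranges by the normalised steady-state ATP slope.

    The slope |dATP*/dH| is normalised by the ATP range over the scan, so
    thresholds are fractions of that range per unit H: below
    ``plateau_threshold`` is a plateau, above ``collapse_threshold`` a
    collapse, in between a monotone decline.  Boundaries are placed at the
    first grid point where each threshold is exceeded, giving at most three
    contiguous regions; their uncertainty is the grid resolution.
    """
    mask = scan.converged
    if mask.sum() < 5:
        raise ClassificationError(
            f"need at least 5 converged scan points, have {int(mask.sum())}"
        )
    H = scan.H[mask]
    ATP = scan.ATP[mask]
    atp_range = float(ATP.max() - ATP.min())
    step = float(np.max(np.diff(H)))
    if atp_range == 0.0:
        return RegionClassification(
            regions=(Region("plateau", float(H[0]), float(H[-1])),),
            boundaries=(),
            boundary_uncertainty=step,
        )
    norm_slope = np.abs(np.gradient(ATP, H)) / atp_range

    above_plateau = np.nonzero(norm_slope >= plateau_threshold)[0]
    above_collapse = np.nonzero(norm_slope >= collapse_threshold)[0]
    h1 = float(H[above_plateau[0]]) if above_plateau.size else None
    h2 = float(H[above_collapse[0]]) if above_collapse.size else None

    edges: list[tuple[str, float, float]] = []
    start = float(H[0])
    if h1 is not None and h1 > start:
        edges.append(("plateau", start, h1))
        start = h1
    elif h1 is None:
        edges.append(("plateau", start, float(H[-1])))
        start = None
    if start is not None:
        if h2 is not None and h2 > start:
            edges.append(("decline", start, h2))
            start = h2
        if h2 is not None:
            edges.append(("collapse", start, float(H[-1])))
        elif start < float(H[-1]) or not edges:
            edges.append(("decline", start, float(H[-1])))

    boundaries = tuple(e[1] for e in edges[1:])
    return RegionClassification(
        regions=tuple(Region(*e) for e in edges),
        boundaries=boundaries,
        boundary_uncertainty=step,
    )


@dataclass(frozen=True)
class StabilityReport:
    """Spectral summary of a scan: neutral direction plus transverse decay."""

    max_real_part: float  # max over converged grid points of max Re(lambda)
    structural_zero_everywhere: bool  # |lambda|_min <= tol at every converged point
    transversally_stable: bool  # all eigenvalues with |lambda| > tol have Re < 0
    n_converged: int
    n_points: int
    zero_tolerance: float


def stability_report(scan: RegimeScan, zero_tolerance: float = 1e-9) -> StabilityReport:
    """Reduce a scan's spectra to the three stability claims of interest.

    The bilinear detoxification coupling forces a zero eigenvalue at every
    steady state (neutral (G, R) direction); a *normally attractive* steady
    state has all remaining eigenvalues strictly in the left half plane.
    """
    mask = scan.converged
    if mask.sum() == 0:
        return StabilityReport(np.nan, False, False, 0, scan.H.size, zero_tolerance)
    eigs = scan.eigenvalues[mask]
    max_real = float(eigs.real.max())
    structural = bool(np.all(np.abs(eigs).min(axis=1) <= zero_tolerance))
    transverse = True
    for row in eigs:
        big = row[np.abs(row) > zero_tolerance]
        if big.size and big.real.max() >= 0:
            transverse = False
            break
    return StabilityReport(
        max_real_part=max_real,
        structural_zero_everywhere=structural,
        transversally_stable=transverse,
        n_converged=int(mask.sum()),
        n_points=int(scan.H.size),
        zero_tolerance=float(zero_tolerance),
    )
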