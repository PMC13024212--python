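"""Variance-based global sensitivity analysis (Sobol indices).

First-order indices S1 quantify the fraction of output variance explained by
one parameter alone; total-order indices ST include all interactions.
Sampling uses scrambled Sobol low-discrepancy sequences over a box around a
center parameter vector (default +/-20-30% of the center, with a wide-scan
option), evaluated through Saltelli's pick-freeze design (A, B and AB_i
matrices, N*(p+2) model runs).  Estimators: Saltelli-2010 for S1 and Jansen
for ST — both standard, documented and swappable at the function level.

Small negative estimates are a known finite-sample artefact; values with
magnitude below a clip threshold are reported as zero and flagged, with the
raw estimates retained for inspection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import qmc

from .exceptions import CysredoxError, IntegrationError, ValidationError
from .model import ModelParameters, State
from .simulate import integrate, output_metrics

__all__ = [
    "SensitivityDesign",
    "design_around",
    "DesignMatrices",
    "sobol_design",
    "SobolResult",
    "sobol_indices",
    "SensitivityReport",
    "sensitivity_pipeline",
    "effect_direction",
]

OUTPUT_NAMES = ("A24", "ATPint", "ROSint", "fitness_ratio")


@dataclass(frozen=True)
class SensitivityDesign:
    """Parameter box and sampling plan for a Sobol analysis."""

    names: tuple[str, ...]
    lower: np.ndarray
    upper: np.ndarray
    N: int
    scheme: str = "sobol"  # "sobol" (scrambled low-discrepancy) or "random"
    seed: Optional[int] = None

    def __post_init__(self):
        object.__setattr__(self, "names", tuple(self.names))
        object.__setattr__(self, "lower", np.asarray(self.lower, dtype=float))
        object.__setattr__(self, "upper", np.asarray(self.upper, dtype=float))
        p = len(self.names)
        if self.lower.shape != (p,) or self.upper.shape != (p,):
            raise ValidationError("bounds arrays must match the number of parameters")
        if np.any(self.lower > self.upper):
            raise ValidationError("lower bounds must not exceed upper bounds")
        if self.scheme not in ("sobol", "random"):
            raise ValidationError(f"unknown sampling scheme {self.scheme!r}")
        if self.N < 2:
            raise ValidationError("N must be >= 2")
        if self.scheme == "sobol" and (self.N & (self.N - 1)) != 0:
            raise ValidationError("N must be a power of 2 for the Sobol scheme")

    @property
    def p(self) -> int:
        return len(self.names)


def design_around(
    center: ModelParameters,
    names: Sequence[str],
    fraction: float = 0.25,
    N: int = 1024,
    *,
    scheme: str = "sobol",
    seed: Optional[int] = None,
    floor: float = 1e-12,
    frozen: Sequence[str] = (),
) -> SensitivityDesign:
    """Box of center*(1 +/- fraction) per parameter, floored at positivity.

    ``fraction=1.0`` gives the wide scan (+/-100% preserving positivity).
    Parameters listed in ``frozen`` get degenerate bounds (no variance
    contribution), which is the cleanest way to exclude them from a shared
    design.
    """
    names = tuple(names)
    c = np.array([getattr(center, n) for n in names], dtype=float)
    lo = np.maximum(c * (1.0 - fraction), floor)
    hi = c * (1.0 + fraction)
    for i, n in enumerate(names):
        if n in frozen:
            lo[i] = hi[i] = c[i]
    return SensitivityDesign(names, lo, hi, int(N), scheme, seed)


@dataclass(frozen=True)
class DesignMatrices:
    """Saltelli pick-freeze evaluation matrices: N*(p+2) rows in total."""

    A: np.ndarray  # (N, p)
    B: np.ndarray  # (N, p)
    AB: np.ndarray  # (p, N, p); AB[i] equals A with column i taken from B

    @property
    def n_evaluations(self) -> int:
        N, p = self.A.shape
        return N * (p + 2)


def sobol_design(design: SensitivityDesign) -> DesignMatrices:
    """Draw the A/B/AB_i matrices over the design box, deterministically."""
    N, p = design.N, design.p
    if design.scheme == "sobol":
        sampler = qmc.Sobol(d=2 * p, scramble=True, seed=design.seed)
        u = sampler.random(N)
    else:
        u = np.random.default_rng(design.seed).random((N, 2 * p))
    span = design.upper - design.lower
    A = design.lower + u[:, :p] * span
    B = design.lower + u[:, p:] * span
    AB = np.empty((p, N, p))
    for i in range(p):
        AB[i] = A
        AB[i, :, i] = B[:, i]
    return DesignMatrices(A, B, AB)


@dataclass(frozen=True)
class SobolResult:
    """First- and total-order indices for one scalar output."""

    names: tuple[str, ...]
    S1: np.ndarray
    ST: np.ndarray
    S1_err: np.ndarray  # bootstrap standard errors
    ST_err: np.ndarray
    S1_raw: np.ndarray  # pre-clipping estimates
    ST_raw: np.ndarray
    S1_clipped: np.ndarray  # bool: small negative reported as zero
    ST_clipped: np.ndarray
    n_evaluations: int
    zero_variance: bool = False

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "S1": self.S1,
                "S1_err": self.S1_err,
                "ST": self.ST,
                "ST_err": self.ST_err,
                "S1_clipped": self.S1_clipped,
                "ST_clipped": self.ST_clipped,
            },
            index=list(self.names),
        )


def _estimate(fA: np.ndarray, fB: np.ndarray, fAB: np.ndarray):
    """Saltelli-2010 S1 and Jansen ST estimators on one sample set."""
    V = np.var(np.concatenate([fA, fB]), ddof=0)
    S1 = np.mean(fB[:, None] * (fAB - fA[:, None]), axis=0) / V
    ST = 0.5 * np.mean((fA[:, None] - fAB) ** 2, axis=0) / V
    return S1, ST


def sobol_indices(
    fA: np.ndarray,
    fB: np.ndarray,
    fAB: np.ndarray,
    names: Sequence[str],
    *,
    clip_threshold: float = 1e-3,
    n_boot: int = 100,
    boot_seed: int = 0,
) -> SobolResult:
    """Indices from pick-freeze evaluations.

    ``fA``/``fB`` are length-N output vectors for the A and B matrices;
    ``fAB`` is (N, p) for the AB_i matrices.  Error bars come from
    resampling the N sample rows with replacement.  A zero-variance output
    yields all-zero indices with the ``zero_variance`` flag set rather than
    NaNs.
    """
    fA = np.asarray(fA, dtype=float)
    fB = np.asarray(fB, dtype=float)
    fAB = np.asarray(fAB, dtype=float)
    if not (np.all(np.isfinite(fA)) and np.all(np.isfinite(fB)) and np.all(np.isfinite(fAB))):
        raise ValidationError("evaluations must be complete and finite")
    names = tuple(names)
    N, p = fAB.shape
    V = np.var(np.concatenate([fA, fB]), ddof=0)
    scale = 1.0 + float(np.mean(np.concatenate([fA, fB])) ** 2)
    if V <= 1e-14 * scale:
        z = np.zeros(p)
        return SobolResult(
            names, z, z.copy(), z.copy(), z.copy(), z.copy(), z.copy(),
            np.zeros(p, bool), np.zeros(p, bool), N * (p + 2), zero_variance=True,
        )

    S1_raw, ST_raw = _estimate(fA, fB, fAB)

    rng = np.random.default_rng(boot_seed)
    S1_bs = np.empty((n_boot, p))
    ST_bs = np.empty((n_boot, p))
    for b in range(n_boot):
        idx = rng.integers(0, N, N)
        S1_bs[b], ST_bs[b] = _estimate(fA[idx], fB[idx], fAB[idx])
    S1_err = S1_bs.std(axis=0, ddof=1)
    ST_err = ST_bs.std(axis=0, ddof=1)

    def clip(raw):
        clipped = (raw < 0) & (raw > -clip_threshold)
        out = raw.copy()
        out[clipped] = 0.0
        return out, clipped

    S1, S1_clipped = clip(S1_raw)
    ST, ST_clipped = clip(ST_raw)
    return SobolResult(
        names, S1, ST, S1_err, ST_err, S1_raw, ST_raw, S1_clipped, ST_clipped, N * (p + 2)
    )


@dataclass
class SensitivityReport:
    """Sobol indices per output plus run metadata."""

    results: dict[str, SobolResult]
    design: SensitivityDesign
    H: float
    n_failed_rows: int
    metadata: dict = field(default_factory=dict)


def sensitivity_pipeline(
    center: ModelParameters,
    design: SensitivityDesign,
    outputs: Sequence[str] = OUTPUT_NAMES,
    H: float = 1.0,
    *,
    initial=None,
    solver_options: Optional[dict] = None,
    t_end: float = 24.0,
    clip_threshold: float = 1e-3,
    max_failure_fraction: float = 0.01,
) -> SensitivityReport:
    """One 24 h simulation per design row; indices per requested output.

    Failed rows (solver breakdown or undefined fitness ratio) drop the whole
    pick-freeze sample they belong to, preserving estimator pairing; more
    than ``max_failure_fraction`` failures aborts the analysis.
    """
    outputs = tuple(outputs)
    unknown = set(outputs) - set(OUTPUT_NAMES)
    if unknown:
        raise ValidationError(f"unknown output(s) {sorted(unknown)}; choose from {OUTPUT_NAMES}")
    if initial is None:
        initial = State(C=0.05, G=1.0, R=0.01, S=0.05, A=1.0)
    solver_options = dict(solver_options or {"method": "rk4", "dt": 0.02})

    mats = sobol_design(design)
    N, p = mats.A.shape
    blocks = np.concatenate([mats.A[None], mats.B[None], mats.AB], axis=0)  # (p+2, N, p)

    values = {out: np.full((p + 2, N), np.nan) for out in outputs}
    n_failed = 0
    for bi in range(p + 2):
        for si in range(N):
            row = blocks[bi, si]
            changes = dict(zip(design.names, (float(v) for v in row)))
            changes["H"] = H
            try:
                params = center.replace(**changes)
                traj = integrate(initial, params, t_end=t_end, **solver_options)
                m = output_metrics(traj, t_end=t_end)
            except (IntegrationError, ValidationError):
                n_failed += 1
                continue
            for out in outputs:
                v = getattr(m, out)
                if out == "fitness_ratio" and not m.fitness_defined:
                    v = np.nan
                values[out][bi, si] = v

    total = (p + 2) * N
    if n_failed > max_failure_fraction * total:
        raise CysredoxError(
            f"{n_failed}/{total} model evaluations failed "
            f"(> {100 * max_failure_fraction:.0f}%); aborting sensitivity analysis"
        )

    results = {}
    for out in outputs:
        grid = values[out]
        ok = np.all(np.isfinite(grid), axis=0)  # keep only fully paired samples
        fA, fB, fAB = grid[0, ok], grid[1, ok], grid[2:, ok].T
        results[out] = sobol_indices(
            fA, fB, fAB, design.names, clip_threshold=clip_threshold,
            boot_seed=design.seed if design.seed is not None else 0,
        )

    return SensitivityReport(
        results=results,
        design=design,
        H=float(H),
        n_failed_rows=n_failed,
        metadata={
            "N": design.N,
            "scheme": design.scheme,
            "seed": design.seed,
            "bounds": {n: [float(l), float(u)] for n, l, u in zip(design.names, design.lower, design.upper)},
            "solver_options": solver_options,
            "outputs": list(outputs),
        },
    )


def effect_direction(
    center: ModelParameters,
    names: Sequence[str],
    output: str = "A24",
    H: float = 1.0,
    *,
    rel_step: float = 0.05,
    initial=None,
    solver_options: Optional[dict] = None,
) -> dict[str, float]:
    """Sign of each parameter's local effect on an output (+1, -1 or 0).

    Variance-based indices are nonnegative by construction and carry no
    direction; this centered-difference diagnostic reports whether nudging a
    parameter up increases or decreases the output at the center point.
    """
    if initial is None:
        initial = State(C=0.05, G=1.0, R=0.01, S=0.05, A=1.0)
    solver_options = dict(solver_options or {"method": "rk4", "dt": 0.02})

    def evaluate(params):
        traj = integrate(initial, params, t_end=24.0, **solver_options)
        return getattr(output_metrics(traj), output)

    out = {}
    for name in names:
        c = getattr(center, name)
        h = rel_step * abs(c) if c != 0 else rel_step
        up = evaluate(center.replace(**{name: c + h, "H": H}))
        dn = evaluate(center.replace(**{name: max(c - h, 1e-12), "H": H}))
        diff = up - dn
        out[name] = 0.0 if diff == 0 else float(np.sign(diff))
    return out
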