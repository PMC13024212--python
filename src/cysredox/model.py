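"""Reduced kinetic model of intracellular cysteine allocation under hypoxia.

Five state variables, all in mM:

    C  intracellular cysteine
    G  reduced glutathione (GSH)
    R  reactive oxygen species (ROS, lumped)
    S  hydrogen sulfide (H2S)
    A  ATP (proxy for energetic state)

Cysteine is taken up from the medium at rate ``kin * Cext`` and partitioned
between two saturable branches — GSH synthesis (``VG``, ``KG``) and H2S
production (``VS``, ``KS``) — plus a first-order basal drain (``kC``).  GSH
removes ROS by mass action (``kRG * G * R``); ROS is generated at a basal
rate ``kROS`` amplified by hypoxia (``1 + beta * H``).  Hypoxia also amplifies
GSH synthesis demand (``1 + alpha * H``) and suppresses oxygen-dependent ATP
production (``kAO * G * (1 - H)``), while H2S supports ATP independently of
oxygen (``kAS * S``).  The hypoxia level ``H`` in [0, 1] is a fixed external
condition, not a dynamic variable.

The bilinear detoxification term makes the Jacobian structurally rank
deficient: the G and R equations share the ``kRG * G * R`` sink, leaving a
neutral direction in the (G, R) plane (see :func:`jacobian`).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping

import numpy as np
import yaml

from .exceptions import ValidationError

__all__ = [
    "PARAM_NAMES",
    "CALIBRATED_NAMES",
    "STATE_NAMES",
    "FLUX_TERM_NAMES",
    "STATE_INDEPENDENT_TERMS",
    "State",
    "ModelParameters",
    "FluxTerms",
    "flux_terms",
    "flux_terms_arrays",
    "rhs",
    "rhs_array",
    "jacobian",
    "default_parameters",
    "steady_cysteine",
    "balanced_kros",
]

STATE_NAMES = ("C", "G", "R", "S", "A")

#: Canonical parameter ordering used for array round-trips and the fast
#: compiled integrator.
PARAM_NAMES = (
    "kin", "Cext", "VG", "KG", "VS", "KS", "kC", "alpha",
    "kRG", "kROS", "beta", "kS", "kAO", "kAS", "kAd", "H",
)

#: Subset of parameters estimated from extracellular flux data; the rest are
#: fixed to literature-informed repository defaults.
CALIBRATED_NAMES = ("kin", "VG", "VS", "kROS", "beta")

FLUX_TERM_NAMES = (
    "uptake",
    "gsh_synthesis",
    "gsh_synthesis_hypoxic",
    "h2s_synthesis",
    "basal_cys",
    "ros_production",
    "ros_detox",
    "h2s_clearance",
    "atp_oxidative",
    "atp_sulfide",
    "atp_decay",
)

#: Flux terms that do not depend on the state vector.  Their time average
#: equals their pointwise value, so observables built only from these terms
#: never require an ODE solve.
STATE_INDEPENDENT_TERMS = frozenset({"uptake", "ros_production"})

# parameters that must be strictly positive (denominators / rates); the two
# source terms (Cext, kROS) may be zero, which shuts the corresponding influx
_STRICTLY_POSITIVE = (
    "kin", "VG", "KG", "VS", "KS", "kC", "kRG", "kS", "kAO", "kAS", "kAd",
)
_NONNEGATIVE = ("Cext", "kROS", "alpha", "beta")


@dataclass(frozen=True)
class State:
    """One point in state space; all concentrations in mM."""

    C: float
    G: float
    R: float
    S: float
    A: float

    def __post_init__(self):
        for name in STATE_NAMES:
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValidationError(f"state component {name!r} is not finite: {v!r}")
            if v < 0:
                raise ValidationError(f"state component {name!r} is negative: {v!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.C, self.G, self.R, self.S, self.A], dtype=float)

    @classmethod
    def from_array(cls, arr: Iterable[float]) -> "State":
        return cls(*(float(x) for x in arr))


def _coerce_state(state) -> np.ndarray:
    if isinstance(state, State):
        return state.as_array()
    arr = np.asarray(state, dtype=float)
    if arr.shape != (5,):
        raise ValidationError(f"state must have 5 components, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValidationError("state contains non-finite components")
    if np.any(arr < 0):
        bad = STATE_NAMES[int(np.argmax(arr < 0))]
        raise ValidationError(f"state component {bad!r} is negative")
    return arr


@dataclass(frozen=True)
class ModelParameters:
    """Full kinetic parameter set, including the external condition.

    Units: ``kin``, ``kC``, ``kS``, ``kAO``, ``kAS``, ``kAd`` are first-order
    rates (h^-1); ``VG``, ``VS``, ``kROS`` are fluxes (mM h^-1); ``KG``, ``KS``
    and ``Cext`` are concentrations (mM); ``kRG`` is a bimolecular constant
    (mM^-1 h^-1); ``alpha``, ``beta`` and ``H`` are dimensionless.
    """

    kin: float
    Cext: float
    VG: float
    KG: float
    VS: float
    KS: float
    kC: float
    alpha: float
    kRG: float
    kROS: float
    beta: float
    kS: float
    kAO: float
    kAS: float
    kAd: float
    H: float

    def __post_init__(self):
        for name in PARAM_NAMES:
            v = getattr(self, name)
            if not isinstance(v, (int, float)) or not math.isfinite(v):
                raise ValidationError(f"parameter {name!r} is not a finite number: {v!r}")
            object.__setattr__(self, name, float(v))
        for name in _STRICTLY_POSITIVE:
            if getattr(self, name) <= 0:
                raise ValidationError(
                    f"parameter {name!r} must be strictly positive, got {getattr(self, name)}"
                )
        for name in _NONNEGATIVE:
            if getattr(self, name) < 0:
                raise ValidationError(
                    f"parameter {name!r} must be nonnegative, got {getattr(self, name)}"
                )
        if not 0.0 <= self.H <= 1.0:
            raise ValidationError(f"parameter 'H' must lie in [0, 1], got {self.H}")

    def replace(self, **changes) -> "ModelParameters":
        unknown = set(changes) - set(PARAM_NAMES)
        if unknown:
            raise ValidationError(f"unknown parameter name(s): {sorted(unknown)}")
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return {name: getattr(self, name) for name in PARAM_NAMES}

    @classmethod
    def from_dict(cls, d: Mapping[str, float]) -> "ModelParameters":
        unknown = set(d) - set(PARAM_NAMES)
        if unknown:
            raise ValidationError(f"unknown parameter name(s): {sorted(unknown)}")
        missing = set(PARAM_NAMES) - set(d)
        if missing:
            raise ValidationError(f"missing parameter name(s): {sorted(missing)}")
        return cls(**{k: float(v) for k, v in d.items()})

    def as_array(self) -> np.ndarray:
        """Values in :data:`PARAM_NAMES` order (used by the fast integrator)."""
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    # -- flat key/value config I/O -------------------------------------------------
    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ModelParameters":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ValidationError(f"parameter file {path} does not contain a mapping")
        return cls.from_dict(data)


@dataclass(frozen=True)
class FluxTerms:
    """The eleven named flux terms, each in mM h^-1, all nonnegative."""

    uptake: float
    gsh_synthesis: float
    gsh_synthesis_hypoxic: float
    h2s_synthesis: float
    basal_cys: float
    ros_production: float
    ros_detox: float
    h2s_clearance: float
    atp_oxidative: float
    atp_sulfide: float
    atp_decay: float

    def as_dict(self) -> dict:
        return {name: getattr(self, name) for name in FLUX_TERM_NAMES}


def flux_terms_arrays(states: np.ndarray, params: ModelParameters) -> dict:
    """Evaluate every flux term on an (n, 5) array of states.

    Returns a dict mapping term name to an array of length n.  Scalars are
    broadcast for the two state-independent terms.
    """
    states = np.atleast_2d(np.asarray(states, dtype=float))
    C, G, R, S, A = (states[:, i] for i in range(5))
    p = params
    n = states.shape[0]
    mmG = p.VG * C / (p.KG + C)
    mmS = p.VS * C / (p.KS + C)
    return {
        "uptake": np.full(n, p.kin * p.Cext),
        "gsh_synthesis": mmG,
        "gsh_synthesis_hypoxic": (1.0 + p.alpha * p.H) * mmG,
        "h2s_synthesis": mmS,
        "basal_cys": p.kC * C,
        "ros_production": np.full(n, (1.0 + p.beta * p.H) * p.kROS),
        "ros_detox": p.kRG * G * R,
        "h2s_clearance": p.kS * S,
        "atp_oxidative": p.kAO * G * (1.0 - p.H),
        "atp_sulfide": p.kAS * S,
        "atp_decay": p.kAd * A,
    }


def flux_terms(state, params: ModelParameters) -> FluxTerms:
    """Evaluate the eleven flux terms at a single state."""
    arr = _coerce_state(state)
    d = flux_terms_arrays(arr[None, :], params)
    return FluxTerms(**{k: float(v[0]) for k, v in d.items()})


def rhs(state, params: ModelParameters) -> np.ndarray:
    """Time derivative (dC, dG, dR, dS, dA)/dt in mM h^-1.

    dC/dt = uptake - gsh_synthesis - h2s_synthesis - basal_cys
    dG/dt = gsh_synthesis_hypoxic - ros_detox
    dR/dt = ros_production - ros_detox
    dS/dt = h2s_synthesis - h2s_clearance
    dA/dt = atp_oxidative + atp_sulfide - atp_decay

    Note the stoichiometric asymmetry kept as modelled: the cysteine drain
    toward GSH does not carry the hypoxia amplification factor, while GSH
    production does.
    """
    arr = _coerce_state(state)
    return rhs_array(arr, params)


def rhs_array(y: np.ndarray, params: ModelParameters) -> np.ndarray:
    """:func:`rhs` on a bare length-5 array, without state validation."""
    C, G, R, S, A = y
    p = params
    mmG = p.VG * C / (p.KG + C)
    mmS = p.VS * C / (p.KS + C)
    detox = p.kRG * G * R
    return np.array([
        p.kin * p.Cext - mmG - mmS - p.kC * C,
        (1.0 + p.alpha * p.H) * mmG - detox,
        (1.0 + p.beta * p.H) * p.kROS - detox,
        mmS - p.kS * S,
        p.kAO * G * (1.0 - p.H) + p.kAS * S - p.kAd * A,
    ])


def jacobian(state, params: ModelParameters) -> np.ndarray:
    """Analytic 5x5 Jacobian of :func:`rhs` (entries in h^-1).

    Structurally singular for every valid state: the vector
    ``(0, G, -R, 0, kAO (1 - H) G / kAd)`` is a right null vector (the G and R
    equations share the bilinear sink), so rank(J) <= 4 and one eigenvalue is
    exactly zero in exact arithmetic.
    """
    arr = _coerce_state(state)
    C, G, R, S, A = arr
    p = params
    dmmG = p.VG * p.KG / (p.KG + C) ** 2
    dmmS = p.VS * p.KS / (p.KS + C) ** 2
    J = np.zeros((5, 5))
    J[0, 0] = -dmmG - dmmS - p.kC
    J[1, 0] = (1.0 + p.alpha * p.H) * dmmG
    J[1, 1] = -p.kRG * R
    J[1, 2] = -p.kRG * G
    J[2, 1] = -p.kRG * R
    J[2, 2] = -p.kRG * G
    J[3, 0] = dmmS
    J[3, 3] = -p.kS
    J[4, 1] = p.kAO * (1.0 - p.H)
    J[4, 3] = p.kAS
    J[4, 4] = -p.kAd
    return J


def default_parameters(**overrides) -> ModelParameters:
    """Repository default parameter set.

    Loaded from the packaged ``data/default_parameters.yaml``.  These are
    documented repository defaults chosen for biological plausibility and a
    well-posed steady-state continuation; they are not published estimates.
    """
    ref = resources.files("cysredox.data").joinpath("default_parameters.yaml")
    data = yaml.safe_load(ref.read_text())
    params = ModelParameters.from_dict(data)
    return params.replace(**overrides) if overrides else params


def steady_cysteine(params: ModelParameters) -> float:
    """Steady-state intracellular cysteine C* (mM).

    Solves the scalar balance
    ``kin*Cext = VG*C/(KG+C) + VS*C/(KS+C) + kC*C``
    by bisection; the left side is constant and the right side is strictly
    increasing from 0, so the root is unique.
    """
    from scipy.optimize import brentq

    p = params
    target = p.kin * p.Cext

    def f(C):
        return p.VG * C / (p.KG + C) + p.VS * C / (p.KS + C) + p.kC * C - target

    hi = max(1.0, target / p.kC)  # kC*hi >= target guarantees f(hi) >= 0
    return float(brentq(f, 0.0, hi, xtol=1e-15, rtol=1e-14))


def balanced_kros(params: ModelParameters) -> float:
    """ROS production rate that closes the redox balance at steady state.

    At equilibrium the GSH and ROS equations require
    ``(1+alpha*H) * VG*C*/(KG+C*) = (1+beta*H) * kROS``.  With
    ``alpha == beta`` this reduces to ``kROS = VG*C*/(KG+C*)`` for every H,
    so a single kROS value yields a steady state across the whole hypoxia
    scan.  The repository defaults are constructed this way.
    """
    p = params
    Cstar = steady_cysteine(p)
    return float(p.VG * Cstar / (p.KG + Cstar))
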