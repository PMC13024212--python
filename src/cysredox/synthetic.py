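"""Self-contained synthetic flux datasets with known ground truth.

The generator mirrors the experimental design the model targets: a handful
of culture conditions (normoxia/hypoxia crossed with control/supplemented
extracellular cysteine), each observed once through time-averaged apparent
fluxes over a 24 h window, perturbed by independent multiplicative Gaussian
noise.  Because truth is recorded alongside the data, calibration, bootstrap
and sensitivity machinery can be validated end to end without any external
measurements.

The default mapping exposes observables that inform each calibrated flux
parameter: cysteine uptake (kin), a secretion-signed GSH-synthesis proxy
(VG, glutamate-like) and an H2S-production observable (VS).  An optional
``ros_probe`` observable exposes the ROS generation term; it is hypothetical
(no extracellular measurement maps onto ROS production) and exists so that
kROS/beta recovery can be studied mechanically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .exceptions import GenerationError, IntegrationError, ValidationError
from .fluxes import FluxDataset, FluxObservation, ObservableMapping, apparent_flux
from .model import STATE_INDEPENDENT_TERMS, ModelParameters, State, flux_terms_arrays
from .simulate import integrate, mean_model_flux

__all__ = [
    "Condition",
    "SyntheticSpec",
    "default_spec",
    "generate_flux_dataset",
    "generate_concentration_table",
]


@dataclass(frozen=True)
class Condition:
    id: str
    H: float
    Cext: float
    supplemented: bool = False


@dataclass
class SyntheticSpec:
    """Ground truth plus experimental design for synthetic data."""

    true_params: ModelParameters
    conditions: Sequence[Condition]
    mapping: ObservableMapping
    noise_scale: float = 0.05
    delta_t: float = 24.0
    seed: Optional[int] = None
    initial_state: State = field(
        default_factory=lambda: State(C=0.05, G=1.0, R=0.01, S=0.05, A=1.0)
    )
    M_initial: dict[str, float] = field(default_factory=dict)
    solver_options: dict = field(default_factory=lambda: {"method": "rk4", "dt": 0.02})

    def __post_init__(self):
        self.conditions = tuple(self.conditions)
        if not self.conditions:
            raise ValidationError("conditions must be non-empty")
        if self.noise_scale < 0:
            raise ValidationError("noise_scale must be >= 0")
        if self.delta_t <= 0:
            raise ValidationError("delta_t must be positive")

    def condition_params(self) -> dict[str, dict[str, float]]:
        """Per-condition parameter overrides for a CalibrationProblem."""
        return {c.id: {"Cext": c.Cext} for c in self.conditions}


def default_spec(
    true_params: ModelParameters,
    *,
    noise_scale: float = 0.05,
    seed: Optional[int] = None,
    expose_ros: bool = False,
) -> SyntheticSpec:
    """2x2 design: {normoxia, hypoxia} x {control, cysteine-supplemented}."""
    mapping = {
        "cysteine": [("uptake", 1)],
        "glutamate": [("gsh_synthesis_hypoxic", -1)],
        "h2s": [("h2s_synthesis", 1)],
    }
    if expose_ros:
        mapping["ros_probe"] = [("ros_production", 1)]  # hypothetical observable
    conditions = (
        Condition("normoxia_ctrl", H=0.0, Cext=0.2, supplemented=False),
        Condition("normoxia_cys", H=0.0, Cext=0.6, supplemented=True),
        Condition("hypoxia_ctrl", H=1.0, Cext=0.2, supplemented=False),
        Condition("hypoxia_cys", H=1.0, Cext=0.6, supplemented=True),
    )
    return SyntheticSpec(
        true_params=true_params,
        conditions=conditions,
        mapping=ObservableMapping(mapping),
        noise_scale=noise_scale,
        seed=seed,
    )


def _true_fluxes(spec: SyntheticSpec) -> dict[str, dict[str, float]]:
    """Noise-free time-averaged mapped fluxes per condition."""
    out: dict[str, dict[str, float]] = {}
    for cond in spec.conditions:
        params = spec.true_params.replace(H=cond.H, Cext=cond.Cext)
        needed = {
            term for m in spec.mapping.metabolites for term, _ in spec.mapping.terms_for(m)
        }
        traj = None
        if not needed <= STATE_INDEPENDENT_TERMS:
            try:
                traj = integrate(
                    spec.initial_state, params, t_end=spec.delta_t, **spec.solver_options
                )
            except IntegrationError as exc:
                raise GenerationError(f"simulation failed for condition {cond.id!r}: {exc}")
        fluxes = {}
        for metabolite in spec.mapping.metabolites:
            v = 0.0
            for term, sign in spec.mapping.terms_for(metabolite):
                if term in STATE_INDEPENDENT_TERMS:
                    v += sign * float(flux_terms_arrays(np.zeros((1, 5)), params)[term][0])
                else:
                    v += sign * mean_model_flux(traj, params, term, (0.0, spec.delta_t))
            fluxes[metabolite] = v
        out[cond.id] = fluxes
    return out


def _truth_record(spec: SyntheticSpec, fluxes: dict) -> dict:
    from .model import CALIBRATED_NAMES

    return {
        "theta_true": {n: getattr(spec.true_params, n) for n in CALIBRATED_NAMES},
        "params": spec.true_params.to_dict(),
        "conditions": [
            {"id": c.id, "H": c.H, "Cext": c.Cext, "supplemented": c.supplemented}
            for c in spec.conditions
        ],
        "mapping": spec.mapping.to_dict(),
        "noise_scale": spec.noise_scale,
        "delta_t": spec.delta_t,
        "seed": spec.seed,
        "fluxes_noise_free": fluxes,
    }


def generate_flux_dataset(spec: SyntheticSpec) -> tuple[FluxDataset, dict]:
    """Noisy flux table plus a sidecar recording truth and seed.

    Noise is multiplicative Gaussian, one independent draw per
    condition x metabolite, consumed in deterministic order from the single
    spec seed: identical specs give byte-identical outputs.
    """
    fluxes = _true_fluxes(spec)
    rng = np.random.default_rng(spec.seed)
    rows = []
    for cond in spec.conditions:
        for metabolite in spec.mapping.metabolites:
            eps = rng.normal(0.0, spec.noise_scale) if spec.noise_scale > 0 else 0.0
            rows.append(
                FluxObservation(
                    metabolite=metabolite,
                    condition=cond.id,
                    H=cond.H,
                    v_exp=fluxes[cond.id][metabolite] * (1.0 + eps),
                    delta_t=spec.delta_t,
                )
            )
    return FluxDataset(rows), _truth_record(spec, fluxes)


def generate_concentration_table(
    spec: SyntheticSpec, *, max_retries: int = 100
) -> tuple[FluxDataset, dict]:
    """Concentration-pair table whose recomputed fluxes match by construction.

    For each observation an initial medium concentration is chosen (from
    ``spec.M_initial`` or a heuristic that comfortably covers the expected
    depletion) and the final concentration is back-computed as
    ``M_final = M_initial - v * delta_t``.  Draws leading to a negative
    final concentration are rejected and the noise resampled (bounded
    retries).  The stored flux is recomputed from the emitted pair via
    :func:`apparent_flux`, so the round trip is bit-exact.
    """
    fluxes = _true_fluxes(spec)
    rng = np.random.default_rng(spec.seed)
    rows = []
    for cond in spec.conditions:
        for metabolite in spec.mapping.metabolites:
            v_true = fluxes[cond.id][metabolite]
            Mi = spec.M_initial.get(
                metabolite, max(1.0, 2.0 * abs(v_true) * spec.delta_t)
            )
            for attempt in range(max_retries + 1):
                eps = rng.normal(0.0, spec.noise_scale) if spec.noise_scale > 0 else 0.0
                v = v_true * (1.0 + eps)
                Mf = Mi - v * spec.delta_t
                if Mf >= 0:
                    break
            else:
                raise GenerationError(
                    f"could not keep M_final nonnegative for {metabolite!r} in "
                    f"condition {cond.id!r} within {max_retries} retries"
                )
            rows.append(
                FluxObservation(
                    metabolite=metabolite,
                    condition=cond.id,
                    H=cond.H,
                    v_exp=apparent_flux(Mi, Mf, spec.delta_t),
                    delta_t=spec.delta_t,
                    M_initial=Mi,
                    M_final=Mf,
                )
            )
    return FluxDataset(rows), _truth_record(spec, fluxes)
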