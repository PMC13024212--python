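"""Apparent extracellular fluxes, observable mappings and flux-table I/O.

An *apparent flux* is the net uptake (positive) or secretion (negative) rate
inferred from the extracellular concentration change of a metabolite between
two time points: ``v = (M_initial - M_final) / delta_t`` (mM h^-1).

An :class:`ObservableMapping` declares how a measured metabolite relates to
the model: a signed combination of named flux terms whose time average is
the model's prediction for that metabolite's extracellular flux.  Only
cysteine has an unambiguous default mapping (the uptake term); any other
metabolite must be mapped explicitly by the user, since the reduced model
contains no glucose/glutamine/methionine species and guessing a mapping
silently would fabricate structure.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import MappingError, ParseError, ValidationError
from .model import FLUX_TERM_NAMES, ModelParameters
from .simulate import Trajectory, mean_model_flux

__all__ = [
    "apparent_flux",
    "relative_deviation",
    "round_half_up",
    "FluxObservation",
    "FluxDataset",
    "ObservableMapping",
    "default_mapping",
    "model_flux_for_metabolite",
    "read_flux_table",
    "write_flux_table",
    "load_es2_table2",
]

TABLE_COLUMNS = (
    "metabolite",
    "condition",
    "H",
    "M_initial_mM",
    "M_final_mM",
    "delta_t_h",
    "v_exp_mM_per_h",
    "sd",
)

#: Absolute slack (mM h^-1) allowed between a stored flux and the one
#: recomputed from its concentration pair before a consistency warning is
#: raised.  Printed tables carry rounded values; this catches gross
#: inconsistencies (sign flips, wrong delta_t) without flagging rounding.
CONSISTENCY_TOL = 1e-3


def apparent_flux(M_initial: float, M_final: float, delta_t: float) -> float:
    """(M_initial - M_final) / delta_t; positive = net uptake."""
    if delta_t <= 0:
        raise ValidationError(f"delta_t must be positive, got {delta_t}")
    return (M_initial - M_final) / delta_t


def relative_deviation(v_exp: float, v_model: float) -> float:
    """100 * |v_model - v_exp| / |v_exp| (percent)."""
    if v_exp == 0:
        raise ValidationError("relative deviation undefined for v_exp = 0")
    return 100.0 * abs(v_model - v_exp) / abs(v_exp)


def round_half_up(x: float, ndigits: int) -> float:
    """Round with ties away from zero, as printed tables typically do."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class FluxObservation:
    """One measured metabolite in one condition."""

    metabolite: str
    condition: str
    H: float
    v_exp: float  # mM h^-1
    delta_t: float = 24.0  # h
    M_initial: Optional[float] = None  # mM
    M_final: Optional[float] = None  # mM
    sd: Optional[float] = None  # mM h^-1

    def __post_init__(self):
        if self.delta_t <= 0:
            raise ValidationError(
                f"delta_t must be positive for {self.metabolite!r}, got {self.delta_t}"
            )
        if not 0.0 <= self.H <= 1.0:
            raise ValidationError(f"H must lie in [0, 1] for {self.metabolite!r}, got {self.H}")


@dataclass
class FluxDataset:
    """A collection of apparent-flux observations with condition metadata."""

    observations: list[FluxObservation] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.observations)

    def __iter__(self):
        return iter(self.observations)

    @property
    def metabolites(self) -> list[str]:
        seen: dict[str, None] = {}
        for obs in self.observations:
            seen.setdefault(obs.metabolite)
        return list(seen)

    @property
    def conditions(self) -> dict[str, float]:
        """Condition id -> hypoxia level; H must be consistent per condition."""
        out: dict[str, float] = {}
        for obs in self.observations:
            if obs.condition in out and out[obs.condition] != obs.H:
                raise ValidationError(
                    f"condition {obs.condition!r} has inconsistent H values"
                )
            out[obs.condition] = obs.H
        return out

    def for_condition(self, condition: str) -> list[FluxObservation]:
        return [o for o in self.observations if o.condition == condition]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "metabolite": o.metabolite,
                    "condition": o.condition,
                    "H": o.H,
                    "M_initial_mM": o.M_initial,
                    "M_final_mM": o.M_final,
                    "delta_t_h": o.delta_t,
                    "v_exp_mM_per_h": o.v_exp,
                    "sd": o.sd,
                }
                for o in self.observations
            ]
        )


class ObservableMapping:
    """Map from metabolite name to a signed combination of flux terms.

    ``mapping`` is ``{metabolite: [(term_name, sign), ...]}`` with sign +1
    for terms contributing to net uptake and -1 for secretion-signed terms.
    """

    def __init__(self, mapping: dict[str, Sequence[tuple[str, int]]]):
        clean: dict[str, list[tuple[str, int]]] = {}
        for metabolite, pairs in mapping.items():
            entries = []
            for term, sign in pairs:
                if term not in FLUX_TERM_NAMES:
                    raise MappingError(
                        f"unknown flux term {term!r} for metabolite {metabolite!r}; "
                        f"available: {list(FLUX_TERM_NAMES)}"
                    )
                if sign not in (-1, 1):
                    raise ValidationError(f"sign must be +1 or -1, got {sign!r}")
                entries.append((term, int(sign)))
            clean[metabolite] = entries
        self._mapping = clean

    @property
    def metabolites(self) -> list[str]:
        return list(self._mapping)

    def __contains__(self, metabolite: str) -> bool:
        return metabolite in self._mapping

    def terms_for(self, metabolite: str) -> list[tuple[str, int]]:
        if metabolite not in self._mapping:
            raise MappingError(
                f"metabolite {metabolite!r} has no mapping; available: {self.metabolites}"
            )
        return list(self._mapping[metabolite])

    def to_dict(self) -> dict:
        return {m: [list(p) for p in pairs] for m, pairs in self._mapping.items()}

    @classmethod
    def from_dict(cls, d: dict) -> "ObservableMapping":
        return cls({m: [(t, s) for t, s in pairs] for m, pairs in d.items()})


def default_mapping() -> ObservableMapping:
    """Cysteine -> uptake; everything else requires an explicit mapping."""
    return ObservableMapping({"cysteine": [("uptake", 1)]})


def model_flux_for_metabolite(
    traj: Trajectory,
    params: ModelParameters,
    mapping: ObservableMapping,
    metabolite: str,
    window=None,
) -> float:
    """Signed sum of time-averaged flux terms mapped to ``metabolite``."""
    total = 0.0
    for term, sign in mapping.terms_for(metabolite):
        total += sign * mean_model_flux(traj, params, term, window)
    return total


def _parse_float(text: str, column: str, row: int) -> Optional[float]:
    text = text.strip()
    if text == "":
        return None
    try:
        return float(text)
    except ValueError as exc:
        raise ParseError(f"row {row}: non-numeric value {text!r} in column {column!r}") from exc


def read_flux_table(path) -> FluxDataset:
    """Read a delimited flux table (see :data:`TABLE_COLUMNS`).

    ``v_exp_mM_per_h`` may be omitted when both concentrations are present,
    in which case it is recomputed; when both are present their consistency
    is checked within :data:`CONSISTENCY_TOL` (warning, not error — printed
    source tables may carry higher-precision fluxes than their concentration
    pairs).  Unknown extra columns are ignored.
    """
    observations = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing = set(TABLE_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise ParseError(f"missing column(s): {sorted(missing)}")
        for i, row in enumerate(reader, start=2):  # header is row 1
            Mi = _parse_float(row["M_initial_mM"], "M_initial_mM", i)
            Mf = _parse_float(row["M_final_mM"], "M_final_mM", i)
            dt = _parse_float(row["delta_t_h"], "delta_t_h", i)
            v = _parse_float(row["v_exp_mM_per_h"], "v_exp_mM_per_h", i)
            sd = _parse_float(row["sd"], "sd", i)
            H = _parse_float(row["H"], "H", i)
            if dt is None or H is None:
                raise ParseError(f"row {i}: delta_t_h and H are required")
            if dt <= 0:
                raise ParseError(f"row {i}: delta_t_h must be positive, got {dt}")
            if v is None:
                if Mi is None or Mf is None:
                    raise ParseError(
                        f"row {i}: need v_exp_mM_per_h or both concentration columns"
                    )
                v = apparent_flux(Mi, Mf, dt)
            elif Mi is not None and Mf is not None:
                recomputed = apparent_flux(Mi, Mf, dt)
                if abs(recomputed - v) > CONSISTENCY_TOL:
                    warnings.warn(
                        f"row {i} ({row['metabolite']}): stored flux {v} differs from "
                        f"recomputed {recomputed:.6g} by more than {CONSISTENCY_TOL}",
                        stacklevel=2,
                    )
            try:
                observations.append(
                    FluxObservation(
                        metabolite=row["metabolite"].strip(),
                        condition=row["condition"].strip(),
                        H=H,
                        v_exp=v,
                        delta_t=dt,
                        M_initial=Mi,
                        M_final=Mf,
                        sd=sd,
                    )
                )
            except ValidationError as exc:
                raise ParseError(f"row {i}: {exc}") from exc
    return FluxDataset(observations)


def _fmt(x: Optional[float]) -> str:
    return "" if x is None else repr(float(x))


def write_flux_table(dataset: FluxDataset, path) -> None:
    """Write a dataset in the table dialect; floats use round-trip repr."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(TABLE_COLUMNS)
        for o in dataset:
            writer.writerow(
                [
                    o.metabolite,
                    o.condition,
                    _fmt(o.H),
                    _fmt(o.M_initial),
                    _fmt(o.M_final),
                    _fmt(o.delta_t),
                    _fmt(o.v_exp),
                    _fmt(o.sd),
                ]
            )


def load_es2_table2() -> pd.DataFrame:
    """Packaged measured-flux table for the ES2 line under hypoxia.

    Returns a DataFrame with the standard table columns plus the published
    model-flux column (``v_model_mM_per_h``) and the published relative
    deviations (``rel_dev_percent``).  Values are verbatim printed numbers.
    """
    ref = resources.files("cysredox.data").joinpath("es2_hypoxia_table2.csv")
    with resources.as_file(ref) as p:
        return pd.read_csv(p)


def load_es2_dataset() -> FluxDataset:
    """Packaged ES2 hypoxia fluxes as a :class:`FluxDataset`."""
    ref = resources.files("cysredox.data").joinpath("es2_hypoxia_table2.csv")
    with resources.as_file(ref) as p:
        return read_flux_table(p)
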