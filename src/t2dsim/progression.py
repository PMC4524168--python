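"""Risk-factor natural history and first-cycle treatment effects.

The validation set-up applies each arm's treatment-effect deltas once, in the
first model cycle, and thereafter evolves risk factors deterministically:
weight drifts upward (+0.1 kg/year), eGFR declines (-0.7 ml/min/1.73m^2 per
year, floored), WBC / LDL / albuminuria / heart rate (and haemoglobin) are
held constant, and the glycaemic/blood-pressure/lipid-ratio panel factors
(HbA1c, SBP, TC:HDL) follow a configurable parametric time path anchored at
the post-treatment baseline value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .state import ANCHORED_FACTORS, Cohort, PatientState, patient_as_cohort

#: Factors an ArmSpec delta or trajectory floor may address.
ADJUSTABLE_FACTORS = (
    "hba1c", "sbp", "tchdl", "ldl", "weight", "egfr", "wbc",
    "haemoglobin", "heart_rate",
)

DEFAULT_FLOORS: Mapping[str, float] = {
    # physiological lower bounds; keep equation covariates finite/sane
    "hba1c": 4.0,
    "sbp": 70.0,
    "tchdl": 1.0,
    "ldl": 0.3,
    "weight": 35.0,
    "egfr": 10.0,
    "wbc": 1.0,
    "haemoglobin": 60.0,
    "heart_rate": 40.0,
}


class ProgressionError(RuntimeError):
    """Raised on misuse of the progression contract (dead patient, double treatment)."""


@dataclass(frozen=True)
class CurveSpec:
    """A baseline-anchored parametric time path for a panel factor.

    ``linear``      — value(t) = anchor + slope * t
    ``asymptotic``  — value(t) = asymptote + (anchor - asymptote) * exp(-rate * t)
    """

    name: str = "linear"
    params: Mapping[str, float] = field(default_factory=dict)

    def evaluate(self, anchor: np.ndarray, t: float) -> np.ndarray:
        if self.name == "linear":
            return anchor + self.params.get("slope", 0.0) * t
        if self.name == "asymptotic":
            asymptote = self.params.get("asymptote", 0.0)
            rate = self.params.get("rate", 0.0)
            return asymptote + (anchor - asymptote) * np.exp(-rate * t)
        raise ValueError(f"unknown trajectory curve {self.name!r}")


@dataclass(frozen=True)
class TrajectoryConfig:
    """Natural-history configuration shared by every simulated arm."""

    weight_drift: float = 0.1          # kg/year
    egfr_drift: float = -0.7           # ml/min/1.73m^2 per year
    egfr_floor: float = 10.0
    held_constant: tuple[str, ...] = (
        "wbc", "ldl", "albuminuria", "heart_rate", "haemoglobin",
    )
    panel: Mapping[str, CurveSpec] = field(
        default_factory=lambda: {
            "hba1c": CurveSpec("linear", {"slope": 0.15}),   # %/year upward drift
            "sbp": CurveSpec("linear", {"slope": 0.5}),      # mmHg/year
            "tchdl": CurveSpec("linear", {"slope": 0.0}),
        }
    )
    floors: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_FLOORS))

    def __post_init__(self):
        overlap = set(self.held_constant) & set(self.panel)
        if overlap:
            raise ValueError(f"factors both held constant and on panel curves: {sorted(overlap)}")
        if self.egfr_floor < 0:
            raise ValueError("eGFR floor must be >= 0")


@dataclass(frozen=True)
class ArmSpec:
    """One treatment arm of a validation study."""

    label: str
    effects: Mapping[str, float] = field(default_factory=dict)  # absolute deltas
    followup_years: float | None = None  # None -> inherit the trial's follow-up
    n: int | None = None                 # None -> pipeline cohort size

    def __post_init__(self):
        unknown = set(self.effects) - set(ADJUSTABLE_FACTORS)
        if unknown:
            raise ValueError(f"arm {self.label!r}: unrecognised effect factors {sorted(unknown)}")
        if self.followup_years is not None and self.followup_years <= 0:
            raise ValueError(f"arm {self.label!r}: follow-up must be > 0")


def apply_treatment_effect(
    patient: PatientState | Cohort,
    arm: ArmSpec,
    cfg: TrajectoryConfig | None = None,
) -> PatientState | Cohort:
    """Shift each listed risk factor by its delta, once, at cycle 0.

    Shifted factors are clamped at their configured floors, and the panel
    trajectory anchors are re-based on the post-treatment values so natural
    history proceeds from the treated baseline. Mutates and returns its input;
    a second invocation on the same patient raises :class:`ProgressionError`.
    """
    cfg = cfg or TrajectoryConfig()
    scalar = isinstance(patient, PatientState)
    cohort = patient_as_cohort(patient) if scalar else patient
    if np.any(cohort.treated):
        raise ProgressionError("treatment effect already applied to this cohort/patient")
    for name, delta in arm.effects.items():
        values = getattr(cohort, name) + delta
        floor = cfg.floors.get(name)
        if floor is not None:
            values = np.maximum(values, floor)
        setattr(cohort, name, values)
        if name in ANCHORED_FACTORS:
            setattr(cohort, f"{name}_anchor", values.copy())
    cohort.treated[:] = True
    if scalar:
        out = cohort.patient(0)
        _copy_into(out, patient)
        return patient
    return cohort


def update_risk_factors(
    patient: PatientState | Cohort,
    cycle_index: int,
    cfg: TrajectoryConfig | None = None,
    dt: float = 0.5,
) -> PatientState | Cohort:
    """Advance risk factors by one cycle of natural history.

    Called at the start of cycle ``cycle_index`` (0-based), before risk
    evaluation; after the update the factors hold their values for elapsed
    time ``(cycle_index + 1) * dt``. Held-constant factors are untouched.
    Raises :class:`ProgressionError` for dead patients.
    """
    cfg = cfg or TrajectoryConfig()
    scalar = isinstance(patient, PatientState)
    cohort = patient_as_cohort(patient) if scalar else patient
    if scalar and not cohort.alive[0]:
        raise ProgressionError("cannot update risk factors of a dead patient")

    alive = cohort.alive
    t = (cycle_index + 1) * dt

    cohort.weight[alive] += cfg.weight_drift * dt
    egfr = cohort.egfr[alive] + cfg.egfr_drift * dt
    cohort.egfr[alive] = np.maximum(egfr, cfg.egfr_floor)

    for name, curve in cfg.panel.items():
        if name in cfg.held_constant:
            continue
        anchor = getattr(cohort, f"{name}_anchor")
        values = curve.evaluate(anchor[alive], t)
        floor = cfg.floors.get(name)
        if floor is not None:
            values = np.maximum(values, floor)
        getattr(cohort, name)[alive] = values

    if scalar:
        _copy_into(cohort.patient(0), patient)
        return patient
    return cohort


def _copy_into(src: PatientState, dst: PatientState) -> None:
    for name, value in vars(src).items():
        setattr(dst, name, value)
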