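"""Patient-level state containers for the microsimulation.

Two views of the same state are provided: :class:`PatientState`, a scalar
dataclass for one simulated individual, and :class:`Cohort`, a
structure-of-arrays container the cycle loop operates on vectorised.
``Cohort`` indexes and iterates as ``PatientState`` records, so code written
against "a list of patients" works unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np

#: Continuous risk factors every equation may reference (units in docstrings
#: of :class:`t2dsim.synthetic.RiskFactorProfile`).
CONTINUOUS_FACTORS: tuple[str, ...] = (
    "age",          # years
    "duration",     # diabetes duration, years
    "hba1c",        # %
    "sbp",          # mmHg
    "tchdl",        # total:HDL cholesterol ratio
    "ldl",          # mmol/l
    "weight",       # kg
    "egfr",         # ml/min/1.73m^2
    "wbc",          # 10^6/ml
    "haemoglobin",  # g/l
    "heart_rate",   # bpm
)

#: Binary risk factors (0/1 flags).
BINARY_FACTORS: tuple[str, ...] = ("female", "smoker", "albuminuria", "af", "pvd")

#: Event-history counters (repeatable events).
HISTORY_COUNTS: tuple[str, ...] = ("mi_count", "stroke_count")

#: Event-history flags (absorbing first events).
HISTORY_FLAGS: tuple[str, ...] = ("chf", "ihd", "amputation", "ulcer", "blindness", "esrd")

#: Every field an equation covariate name may resolve to.
COVARIATE_FIELDS: tuple[str, ...] = (
    CONTINUOUS_FACTORS + BINARY_FACTORS + HISTORY_COUNTS + HISTORY_FLAGS
)

#: The risk factors introduced by the expanded (UKPDS-82-style) equation sets.
EXPANDED_COVARIATES: frozenset[str] = frozenset(
    {"wbc", "ldl", "egfr", "heart_rate", "haemoglobin", "albuminuria"}
)

#: Factors whose natural-history trajectory is anchored at the (post-treatment)
#: baseline value.
ANCHORED_FACTORS: tuple[str, ...] = ("hba1c", "sbp", "tchdl")


@dataclass
class PatientState:
    """One simulated individual."""

    id: int = 0
    age: float = 60.0
    duration: float = 8.0
    hba1c: float = 7.5
    sbp: float = 140.0
    tchdl: float = 4.0
    ldl: float = 3.0
    weight: float = 85.0
    egfr: float = 77.7
    wbc: float = 6.9
    haemoglobin: float = 145.0
    heart_rate: float = 72.0
    female: int = 0
    smoker: int = 0
    albuminuria: int = 0
    af: int = 0
    pvd: int = 0
    mi_count: int = 0
    stroke_count: int = 0
    chf: int = 0
    ihd: int = 0
    amputation: int = 0
    ulcer: int = 0
    blindness: int = 0
    esrd: int = 0
    alive: bool = True
    time_in_model: float = 0.0
    treated: bool = False
    # trajectory anchors; None means "current baseline value"
    hba1c_anchor: float | None = None
    sbp_anchor: float | None = None
    tchdl_anchor: float | None = None

    def __post_init__(self) -> None:
        for name in ANCHORED_FACTORS:
            if getattr(self, f"{name}_anchor") is None:
                setattr(self, f"{name}_anchor", getattr(self, name))


_INT_FIELDS = BINARY_FACTORS + HISTORY_COUNTS + HISTORY_FLAGS


class Cohort:
    """Structure-of-arrays view of ``n`` patients.

    All simulation-facing fields are numpy arrays of equal length. Continuous
    fields are float64; flags and counters are int64; ``alive`` is bool.
    """

    _FLOAT_FIELDS = CONTINUOUS_FACTORS + ("time_in_model",) + tuple(
        f"{f}_anchor" for f in ANCHORED_FACTORS
    )
    _BOOL_FIELDS = ("alive", "treated")

    def __init__(self, n: int):
        if n < 1:
            raise ValueError(f"cohort size must be >= 1, got {n}")
        self.n = int(n)
        self.id = np.arange(n, dtype=np.int64)
        for name in self._FLOAT_FIELDS:
            setattr(self, name, np.zeros(n, dtype=np.float64))
        for name in _INT_FIELDS:
            setattr(self, name, np.zeros(n, dtype=np.int64))
        self.alive = np.ones(n, dtype=bool)
        self.treated = np.zeros(n, dtype=bool)

    # -- conversions ------------------------------------------------------

    @classmethod
    def from_patients(cls, patients: "list[PatientState]") -> "Cohort":
        cohort = cls(len(patients))
        for i, p in enumerate(patients):
            cohort.id[i] = p.id
            for name in cls._FLOAT_FIELDS + _INT_FIELDS:
                getattr(cohort, name)[i] = getattr(p, name)
            cohort.alive[i] = p.alive
            cohort.treated[i] = p.treated
        return cohort

    def patient(self, i: int) -> PatientState:
        kwargs = {"id": int(self.id[i])}
        for name in CONTINUOUS_FACTORS + ("time_in_model",):
            kwargs[name] = float(getattr(self, name)[i])
        for name in _INT_FIELDS:
            kwargs[name] = int(getattr(self, name)[i])
        for name in ANCHORED_FACTORS:
            kwargs[f"{name}_anchor"] = float(getattr(self, f"{name}_anchor")[i])
        kwargs["alive"] = bool(self.alive[i])
        kwargs["treated"] = bool(self.treated[i])
        return PatientState(**kwargs)

    def __len__(self) -> int:
        return self.n

    def __getitem__(self, i: int) -> PatientState:
        return self.patient(i)

    def __iter__(self) -> Iterator[PatientState]:
        return (self.patient(i) for i in range(self.n))

    def copy(self) -> "Cohort":
        out = Cohort.__new__(Cohort)
        out.n = self.n
        out.id = self.id.copy()
        for name in self._FLOAT_FIELDS + _INT_FIELDS + self._BOOL_FIELDS:
            setattr(out, name, getattr(self, name).copy())
        return out

    def covariate(self, name: str) -> np.ndarray:
        """Resolve an equation covariate name to its array.

        Raises ``KeyError`` for names outside :data:`COVARIATE_FIELDS`.
        """
        if name not in COVARIATE_FIELDS:
            raise KeyError(name)
        return getattr(self, name)


def patient_as_cohort(patient: PatientState) -> Cohort:
    """Wrap a single patient as a length-1 cohort (for scalar APIs)."""
    return Cohort.from_patients([patient])
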