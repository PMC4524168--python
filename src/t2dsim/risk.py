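"""Parametric event-risk equation engine.

Each equation is a linear predictor over transformed risk factors feeding one
of four hazard families:

* ``exponential``  — cumulative hazard ``H(t) = exp(lp) * t``
* ``weibull``      — ``H(t) = exp(lp) * t**shape``
* ``gompertz``     — ``H(t) = exp(lp) * (exp(shape*t) - 1) / shape``
* ``logistic``     — annual probability ``1 / (1 + exp(-lp))``

For the survival families the probability of an event in a cycle ``[t, t+dt)``
is ``1 - exp(H(t) - H(t+dt))``; the logistic annual probability is converted
to the cycle length as ``1 - (1 - p_annual)**dt``. Time ``t`` is diabetes
duration in years, updated each cycle.

Equation sets are named registries serialisable to JSON. Two styles carry
extra validation: ``ukpds68``-style sets must not reference the expanded
risk factors (WBC, LDL, eGFR, heart rate, haemoglobin, albuminuria) and
``ukpds82``-style sets must reference all of them and include secondary-event
equations, mirroring the two generations of UKPDS outcome equations.
"""

from __future__ import annotations

import json
import operator
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Mapping

import numpy as np
from scipy.special import expit

from .state import COVARIATE_FIELDS, EXPANDED_COVARIATES, Cohort, PatientState, patient_as_cohort

FORMS = ("exponential", "weibull", "gompertz", "logistic")
TRANSFORMS = ("identity", "offset", "indicator", "log")


class RegistryError(ValueError):
    """Raised when an equation registry violates its schema or invariants."""


class MissingCovariateError(KeyError):
    """Raised when a patient lacks a covariate an equation references."""


# --------------------------------------------------------------------------
# eligibility mini-grammar: comparisons "field op number" joined by and/or
# --------------------------------------------------------------------------

_OPS: Mapping[str, Callable] = {
    "==": operator.eq,
    "!=": operator.ne,
    ">=": operator.ge,
    "<=": operator.le,
    ">": operator.gt,
    "<": operator.lt,
}

_ATOM_RE = re.compile(r"^\s*(\w+)\s*(==|!=|>=|<=|>|<)\s*(-?\d+(?:\.\d+)?)\s*$")


def parse_eligibility(expr: str) -> Callable[[Cohort], np.ndarray]:
    """Compile an eligibility expression into a pure cohort predicate.

    Grammar: ``true`` | atom (``and`` atom)* joined by ``or``; an atom is
    ``<covariate> <op> <number>``. ``or`` binds loosest.
    """
    expr = expr.strip()
    if expr.lower() in ("true", "always", ""):
        return lambda cohort: np.ones(len(cohort), dtype=bool)

    or_terms = []
    for disjunct in re.split(r"\bor\b", expr):
        atoms = []
        for atom in re.split(r"\band\b", disjunct):
            m = _ATOM_RE.match(atom)
            if not m:
                raise RegistryError(f"cannot parse eligibility atom {atom!r} in {expr!r}")
            name, op, value = m.group(1), m.group(2), float(m.group(3))
            if name not in COVARIATE_FIELDS:
                raise RegistryError(f"unknown covariate {name!r} in eligibility {expr!r}")
            atoms.append((name, _OPS[op], value))
        or_terms.append(atoms)

    def predicate(cohort: Cohort) -> np.ndarray:
        result = np.zeros(len(cohort), dtype=bool)
        for atoms in or_terms:
            term = np.ones(len(cohort), dtype=bool)
            for name, op, value in atoms:
                term &= op(cohort.covariate(name), value)
            result |= term
        return result

    return predicate


# --------------------------------------------------------------------------
# equation specification
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Covariate:
    name: str
    coefficient: float
    transform: str = "identity"
    parameter: float = 0.0  # centring offset / indicator threshold

    def apply(self, x: np.ndarray) -> np.ndarray:
        if self.transform == "identity":
            return x
        if self.transform == "offset":
            return x - self.parameter
        if self.transform == "indicator":
            return (x > self.parameter).astype(np.float64)
        if self.transform == "log":
            return np.log(x)
        raise RegistryError(f"unknown transform {self.transform!r}")


@dataclass(frozen=True)
class RiskEquationSpec:
    """One parametric event-risk equation."""

    endpoint: str
    form: str
    intercept: float
    covariates: tuple[Covariate, ...] = ()
    shape: float | None = None
    eligibility: str = "true"
    kind: str = "event"  # "event" | "mortality"

    def __post_init__(self):
        if self.form not in FORMS:
            raise RegistryError(f"{self.endpoint}: unknown form {self.form!r}")
        if self.form in ("weibull", "gompertz"):
            if self.shape is None or self.shape <= 0:
                raise RegistryError(
                    f"{self.endpoint}: form {self.form!r} requires shape > 0, got {self.shape}"
                )
        for cov in self.covariates:
            if cov.name not in COVARIATE_FIELDS:
                raise RegistryError(f"{self.endpoint}: unknown covariate {cov.name!r}")
            if cov.transform not in TRANSFORMS:
                raise RegistryError(f"{self.endpoint}: unknown transform {cov.transform!r}")
        if self.kind not in ("event", "mortality"):
            raise RegistryError(f"{self.endpoint}: kind must be event|mortality")
        # compile once; stored via object.__setattr__ because frozen
        object.__setattr__(self, "_eligible", parse_eligibility(self.eligibility))

    @property
    def covariate_names(self) -> frozenset[str]:
        return frozenset(c.name for c in self.covariates)


def linear_predictor(eq: RiskEquationSpec, patient: PatientState | Cohort):
    """Evaluate ``intercept + sum(coef * transform(x))``.

    Accepts a single patient (returns float) or a cohort (returns array).
    Raises :class:`MissingCovariateError` rather than imputing silently.
    """
    scalar = isinstance(patient, PatientState)
    cohort = patient_as_cohort(patient) if scalar else patient
    lp = np.full(len(cohort), eq.intercept, dtype=np.float64)
    for cov in eq.covariates:
        try:
            x = cohort.covariate(cov.name)
        except KeyError as exc:
            raise MissingCovariateError(
                f"equation {eq.endpoint!r} requires covariate {cov.name!r}"
            ) from exc
        x = np.asarray(x, dtype=np.float64)
        if scalar and not np.isfinite(x).all():
            raise MissingCovariateError(
                f"equation {eq.endpoint!r}: covariate {cov.name!r} is not finite"
            )
        lp += cov.coefficient * cov.apply(x)
    return float(lp[0]) if scalar else lp


def cumulative_hazard(eq: RiskEquationSpec, lp, t):
    """``H(t)`` for the survival forms; ``t`` is diabetes duration, years."""
    lp = np.asarray(lp, dtype=np.float64)
    t = np.asarray(t, dtype=np.float64)
    rate = np.exp(lp)
    if eq.form == "exponential":
        return rate * t
    if eq.form == "weibull":
        return rate * np.power(t, eq.shape)
    if eq.form == "gompertz":
        return rate * np.expm1(eq.shape * t) / eq.shape
    raise RegistryError(f"form {eq.form!r} has no cumulative hazard")


def cycle_event_probability(
    eq: RiskEquationSpec, patient: PatientState | Cohort, t, dt: float = 0.5
):
    """Probability of the event within the cycle ``[t, t+dt)``.

    Ineligible patients receive probability 0 (no error). Result lies in
    ``[0, 1)`` and is non-decreasing in the linear predictor.
    """
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    if np.any(np.asarray(t) < 0):
        raise ValueError("t must be >= 0")
    scalar = isinstance(patient, PatientState)
    cohort = patient_as_cohort(patient) if scalar else patient
    lp = linear_predictor(eq, cohort)
    if eq.form == "logistic":
        p_annual = expit(lp)
        p = 1.0 - np.power(1.0 - p_annual, dt)
    else:
        p = -np.expm1(cumulative_hazard(eq, lp, t) - cumulative_hazard(eq, lp, t + dt))
    p = np.minimum(p, np.nextafter(1.0, 0.0))  # contract: probability in [0, 1)
    p = p * eligible(eq, cohort)
    return float(p[0]) if scalar else p


def eligible(eq: RiskEquationSpec, patient: PatientState | Cohort):
    """Evaluate the equation's eligibility predicate (pure, no mutation)."""
    scalar = isinstance(patient, PatientState)
    cohort = patient_as_cohort(patient) if scalar else patient
    mask = eq._eligible(cohort)
    return bool(mask[0]) if scalar else mask


# --------------------------------------------------------------------------
# registries
# --------------------------------------------------------------------------

@dataclass
class EquationSet:
    """A named registry of event and mortality equations."""

    name: str
    style: str = "custom"  # "ukpds68" | "ukpds82" | "custom"
    equations: tuple[RiskEquationSpec, ...] = ()

    def __post_init__(self):
        ids = [eq.endpoint for eq in self.equations]
        dupes = {e for e in ids if ids.count(e) > 1}
        if dupes:
            raise RegistryError(f"{self.name}: duplicate endpoint ids {sorted(dupes)}")
        referenced = set()
        for eq in self.equations:
            referenced |= {c.name for c in eq.covariates}
        if self.style == "ukpds68":
            bad = referenced & EXPANDED_COVARIATES
            if bad:
                raise RegistryError(
                    f"{self.name}: ukpds68-style set must not reference expanded "
                    f"covariates, found {sorted(bad)}"
                )
            if any(eq.endpoint.startswith("secondary_") for eq in self.equations):
                raise RegistryError(
                    f"{self.name}: ukpds68-style set must not include secondary-event equations"
                )
        elif self.style == "ukpds82":
            missing = EXPANDED_COVARIATES - referenced
            if missing:
                raise RegistryError(
                    f"{self.name}: ukpds82-style set must reference expanded "
                    f"covariates, missing {sorted(missing)}"
                )
            if not any(eq.endpoint.startswith("secondary_") for eq in self.equations):
                raise RegistryError(
                    f"{self.name}: ukpds82-style set must include secondary-event equations"
                )
        elif self.style != "custom":
            raise RegistryError(f"{self.name}: unknown style {self.style!r}")

    @property
    def event_equations(self) -> tuple[RiskEquationSpec, ...]:
        return tuple(eq for eq in self.equations if eq.kind == "event")

    @property
    def mortality_equations(self) -> tuple[RiskEquationSpec, ...]:
        return tuple(eq for eq in self.equations if eq.kind == "mortality")

    @property
    def endpoints(self) -> tuple[str, ...]:
        return tuple(eq.endpoint for eq in self.equations)

    @property
    def required_covariates(self) -> frozenset[str]:
        out: set[str] = set()
        for eq in self.equations:
            out |= {c.name for c in eq.covariates}
        return frozenset(out)

    def __getitem__(self, endpoint: str) -> RiskEquationSpec:
        for eq in self.equations:
            if eq.endpoint == endpoint:
                return eq
        raise KeyError(endpoint)

    # -- (de)serialisation ------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "style": self.style,
            "equations": [
                {
                    "endpoint": eq.endpoint,
                    "kind": eq.kind,
                    "form": eq.form,
                    **({"shape": eq.shape} if eq.shape is not None else {}),
                    "intercept": eq.intercept,
                    "eligibility": eq.eligibility,
                    "covariates": [
                        {
                            "name": c.name,
                            "coefficient": c.coefficient,
                            "transform": c.transform,
                            "parameter": c.parameter,
                        }
                        for c in eq.covariates
                    ],
                }
                for eq in self.equations
            ],
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "EquationSet":
        try:
            equations = []
            for raw in payload["equations"]:
                covs = tuple(
                    Covariate(
                        name=c["name"],
                        coefficient=float(c["coefficient"]),
                        transform=c.get("transform", "identity"),
                        parameter=float(c.get("parameter", 0.0)),
                    )
                    for c in raw.get("covariates", [])
                )
                equations.append(
                    RiskEquationSpec(
                        endpoint=raw["endpoint"],
                        form=raw["form"],
                        intercept=float(raw["intercept"]),
                        covariates=covs,
                        shape=float(raw["shape"]) if "shape" in raw and raw["shape"] is not None else None,
                        eligibility=raw.get("eligibility", "true"),
                        kind=raw.get("kind", "event"),
                    )
                )
        except (KeyError, TypeError) as exc:
            raise RegistryError(f"malformed equation registry: {exc}") from exc
        return cls(
            name=payload.get("name", "unnamed"),
            style=payload.get("style", "custom"),
            equations=tuple(equations),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def load_equation_set(path: str | Path) -> EquationSet:
    """Load and validate a JSON equation registry."""
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise RegistryError(f"cannot read equation registry {path}: {exc}") from exc
    return EquationSet.from_dict(payload)
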