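"""The discrete-time patient-level cycle loop.

Each simulated cohort advances in fixed six-month increments over at most a
40-year horizon. Within a cycle: (1) natural-history progression updates the
risk factors; (2) every eligible nonfatal event equation is evaluated as an
independent Bernoulli draw at its cycle probability, with eligibility frozen
at the cycle start; (3) mortality equations are evaluated last, against the
post-event state, so a nonfatal event and death can co-occur in one cycle;
(4) age, diabetes duration and time-in-model advance. Person-time accrues in
full cycles, with death ending accrual at cycle end (no half-cycle
correction).

Results aggregate to annualized endpoint rates (events per 100 person-years
at risk), including two composites: ``acm`` (all-cause mortality, the union
of every mortality equation) and ``mvd`` (microvascular disease, the union
of first ulcer/blindness/ESRD events present in the equation set).
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .progression import ArmSpec, TrajectoryConfig, apply_treatment_effect, update_risk_factors
from .risk import EquationSet, cycle_event_probability, eligible
from .state import Cohort, PatientState, patient_as_cohort
from .synthetic import RATE_UNITS, TrialSpec, generate_cohort

logger = logging.getLogger(__name__)

DEFAULT_DT = 0.5          # years per cycle (six-monthly)
MAX_HORIZON = 40.0        # years

#: Microvascular first events pooled into the ``mvd`` composite.
MVD_MEMBERS = ("ulcer", "blindness", "esrd")

COMPOSITE_ENDPOINTS = ("acm", "mvd")

#: State update applied when an event endpoint fires.
_EVENT_UPDATES = {
    "mi": ("mi_count", "increment"),
    "secondary_mi": ("mi_count", "increment"),
    "stroke": ("stroke_count", "increment"),
    "secondary_stroke": ("stroke_count", "increment"),
    "chf": ("chf", "flag"),
    "ihd": ("ihd", "flag"),
    "amputation": ("amputation", "flag"),
    "ulcer": ("ulcer", "flag"),
    "blindness": ("blindness", "flag"),
    "esrd": ("esrd", "flag"),
}


class SimulationError(RuntimeError):
    pass


class UndefinedRateError(ZeroDivisionError):
    """An endpoint accrued zero person-years, so its rate is undefined."""


class ConfigurationError(ValueError):
    """A trial references endpoints the equation set cannot produce."""


@dataclass
class SimulationResult:
    """Aggregated outcome of one simulated arm."""

    study: str
    arm: str
    n: int
    followup_years: float
    dt: float
    endpoints: pd.DataFrame  # endpoint, events, patients_at_risk, person_years, rate
    trace: pd.DataFrame      # cycle, time_years, endpoint, events
    seed: int | None = None


def _n_cycles(horizon: float, dt: float) -> int:
    if horizon <= 0:
        raise SimulationError(f"horizon must be > 0, got {horizon}")
    if dt <= 0:
        raise SimulationError(f"dt must be > 0, got {dt}")
    k = horizon / dt
    if abs(k - round(k)) > 1e-9:
        raise SimulationError(f"dt={dt} does not divide horizon={horizon}")
    return int(round(k))


def _apply_events(cohort: Cohort, endpoint: str, mask: np.ndarray) -> None:
    update = _EVENT_UPDATES.get(endpoint)
    if update is None:
        return  # custom endpoint without state tracking: repeatable event
    name, mode = update
    arr = getattr(cohort, name)
    if mode == "increment":
        arr[mask] += 1
    else:
        arr[mask] = 1


def _simulate_cohort(
    cohort: Cohort,
    equations: EquationSet,
    horizon: float,
    dt: float,
    rng: np.random.Generator,
    trajectory: TrajectoryConfig | None = None,
    record_events: bool = False,
) -> tuple[dict, pd.DataFrame, list]:
    """Run the cycle loop in place; return aggregates, trace and event log."""
    trajectory = trajectory or TrajectoryConfig()
    n_cycles = _n_cycles(horizon, dt)
    event_eqs = equations.event_equations
    mort_eqs = equations.mortality_equations
    has_mvd_flags = [m for m in MVD_MEMBERS if m in equations.endpoints]

    stats = {
        eq.endpoint: {"events": 0, "person_years": 0.0,
                      "patients_at_risk": int(np.sum(cohort.alive & eligible(eq, cohort)))}
        for eq in equations.equations
    }
    stats["acm"] = {"events": 0, "person_years": 0.0,
                    "patients_at_risk": int(np.sum(cohort.alive))}
    mvd_flag = np.zeros(len(cohort), dtype=bool)
    for m in has_mvd_flags:
        mvd_flag |= getattr(cohort, m) > 0
    stats["mvd"] = {"events": 0, "person_years": 0.0,
                    "patients_at_risk": int(np.sum(cohort.alive & ~mvd_flag))}

    trace_rows: list[dict] = []
    event_log: list[tuple[float, str, int]] = []

    for k in range(n_cycles):
        alive_start = cohort.alive.copy()
        if not alive_start.any():
            break
        update_risk_factors(cohort, k, trajectory, dt=dt)
        t = cohort.duration  # hazard time is diabetes duration at cycle start
        cycle_events: dict[str, int] = {}

        # person-time accrual (full cycles, frozen at cycle start)
        stats["acm"]["person_years"] += dt * int(alive_start.sum())
        mvd_at_risk = alive_start & ~mvd_flag
        stats["mvd"]["person_years"] += dt * int(mvd_at_risk.sum())

        # nonfatal events: eligibility and probabilities frozen at cycle start
        fired: list[tuple[str, np.ndarray]] = []
        for eq in event_eqs:
            elig = alive_start & eligible(eq, cohort)
            stats[eq.endpoint]["person_years"] += dt * int(elig.sum())
            p = cycle_event_probability(eq, cohort, t, dt)
            u = rng.random(len(cohort))  # drawn for all patients: common random numbers
            mask = elig & (u < p)
            fired.append((eq.endpoint, mask))
        for endpoint, mask in fired:
            count = int(mask.sum())
            if count:
                _apply_events(cohort, endpoint, mask)
                stats[endpoint]["events"] += count
            cycle_events[endpoint] = count
            if record_events and count:
                for idx in np.nonzero(mask)[0]:
                    event_log.append(((k + 1) * dt, endpoint, int(idx)))

        # mvd composite: newly flagged members among those at risk
        if has_mvd_flags:
            new_flag = np.zeros(len(cohort), dtype=bool)
            for m in has_mvd_flags:
                new_flag |= getattr(cohort, m) > 0
            mvd_events = mvd_at_risk & new_flag & ~mvd_flag
            stats["mvd"]["events"] += int(mvd_events.sum())
            cycle_events["mvd"] = int(mvd_events.sum())
            mvd_flag |= new_flag

        # mortality last, against the post-event state
        dead = np.zeros(len(cohort), dtype=bool)
        for eq in mort_eqs:
            elig = alive_start & eligible(eq, cohort)
            stats[eq.endpoint]["person_years"] += dt * int(elig.sum())
            p = cycle_event_probability(eq, cohort, t, dt)
            u = rng.random(len(cohort))
            mask = elig & (u < p)
            count = int(mask.sum())
            stats[eq.endpoint]["events"] += count
            cycle_events[eq.endpoint] = count
            if record_events and count:
                for idx in np.nonzero(mask)[0]:
                    event_log.append(((k + 1) * dt, eq.endpoint, int(idx)))
            dead |= mask
        newly_dead = dead & alive_start
        stats["acm"]["events"] += int(newly_dead.sum())
        cycle_events["acm"] = int(newly_dead.sum())
        cohort.alive &= ~newly_dead

        # clock advances for patients who entered the cycle alive
        cohort.age[alive_start] += dt
        cohort.duration[alive_start] += dt
        cohort.time_in_model[alive_start] += dt

        for endpoint, count in cycle_events.items():
            trace_rows.append(
                {"cycle": k, "time_years": (k + 1) * dt, "endpoint": endpoint, "events": count}
            )

    trace = pd.DataFrame(trace_rows, columns=["cycle", "time_years", "endpoint", "events"])
    return stats, trace, event_log


def run_patient(
    patient: PatientState,
    equations: EquationSet,
    horizon: float,
    dt: float = DEFAULT_DT,
    rng: np.random.Generator | int | None = None,
    trajectory: TrajectoryConfig | None = None,
) -> list[tuple[float, str]]:
    """Simulate one patient; returns the event history as (time, endpoint)
    pairs and leaves the patient in its final state."""
    if not patient.alive:
        raise SimulationError("patient must be alive at simulation start")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    cohort = patient_as_cohort(patient)
    _, _, log = _simulate_cohort(
        cohort, equations, horizon, dt, rng, trajectory, record_events=True
    )
    final = cohort.patient(0)
    for name, value in vars(final).items():
        setattr(patient, name, value)
    return [(time, endpoint) for time, endpoint, _ in log]


def simulate_cohort(
    cohort: Cohort,
    equations: EquationSet,
    horizon: float,
    dt: float = DEFAULT_DT,
    rng: np.random.Generator | int | None = None,
    trajectory: TrajectoryConfig | None = None,
    study: str = "adhoc",
    arm: str = "adhoc",
) -> SimulationResult:
    """Run the cycle loop on an already-constructed cohort (mutated in place)."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    n = len(cohort)
    stats, trace, _ = _simulate_cohort(cohort, equations, horizon, dt, rng, trajectory)
    return SimulationResult(
        study=study, arm=arm, n=n, followup_years=horizon, dt=dt,
        endpoints=_stats_frame(stats), trace=trace,
    )


def _stats_frame(stats: dict) -> pd.DataFrame:
    rows = []
    for endpoint, s in stats.items():
        py = s["person_years"]
        rate = 100.0 * s["events"] / py if py > 0 else np.nan
        rows.append(
            {"endpoint": endpoint, "events": s["events"],
             "patients_at_risk": s["patients_at_risk"],
             "person_years": py, "rate": rate}
        )
    return pd.DataFrame(rows)


def _arm_seed_sequence(seed: int, study: str, arm: str) -> np.random.SeedSequence:
    # one stream per (study, arm): adding arms never perturbs existing ones
    return np.random.SeedSequence(
        [int(seed), zlib.crc32(study.encode()), zlib.crc32(arm.encode())]
    )


def run_arm(
    trial: TrialSpec,
    arm: ArmSpec,
    equations: EquationSet,
    n: int,
    seed: int,
    dt: float = DEFAULT_DT,
    trajectory: TrajectoryConfig | None = None,
    max_horizon: float = MAX_HORIZON,
) -> SimulationResult:
    """Generate the arm's cohort, apply its first-cycle treatment effect and
    run every patient to the arm's follow-up (capped at the model horizon)."""
    if n < 1:
        raise SimulationError(f"cohort size must be >= 1, got {n}")
    ss = _arm_seed_sequence(seed, trial.id, arm.label)
    cohort_ss, events_ss = ss.spawn(2)
    cohort = generate_cohort(trial.profile, n, cohort_ss)
    apply_treatment_effect(cohort, arm, trajectory)
    horizon = min(trial.arm_followup(arm), max_horizon)
    stats, trace, _ = _simulate_cohort(
        cohort, equations, horizon, dt, np.random.default_rng(events_ss), trajectory
    )
    return SimulationResult(
        study=trial.id, arm=arm.label, n=n, followup_years=horizon, dt=dt,
        endpoints=_stats_frame(stats), trace=trace, seed=seed,
    )


def annualize(result: SimulationResult, strict: bool = True) -> pd.DataFrame:
    """Annualized endpoint rate table: 100 × events / person-years.

    With ``strict`` (default), an endpoint with zero person-years raises
    :class:`UndefinedRateError`; otherwise such endpoints are dropped with a
    warning.
    """
    table = result.endpoints.copy()
    undefined = table.loc[table["person_years"] <= 0, "endpoint"].tolist()
    if undefined:
        if strict:
            raise UndefinedRateError(
                f"{result.study}/{result.arm}: zero person-years for endpoints {undefined}"
            )
        logger.warning(
            "%s/%s: dropping endpoints with zero person-years: %s",
            result.study, result.arm, undefined,
        )
        table = table.loc[table["person_years"] > 0]
    table = table.assign(rate_units=RATE_UNITS)
    return table[["endpoint", "events", "patients_at_risk", "person_years", "rate", "rate_units"]]


def run_validation(
    trials: list[TrialSpec],
    equations: EquationSet,
    n: int = 2000,
    seed: int = 0,
    dt: float = DEFAULT_DT,
    trajectory: TrajectoryConfig | None = None,
    max_horizon: float = MAX_HORIZON,
):
    """Simulate every (study, arm) and pair predicted with observed rates.

    Returns a :class:`t2dsim.gof.EndpointPairSet` with one record per
    study × arm × reported endpoint, labelled internal/external. Every
    reported endpoint must map to an equation endpoint or a composite.
    """
    from .gof import EndpointPairSet  # circular-by-layering; resolved locally

    known: set[str] = set()
    records = []
    for trial in trials:
        if trial.observed is None or trial.observed.empty:
            raise ConfigurationError(f"trial {trial.id} carries no observed endpoint table")
        available = set(equations.endpoints) | set(COMPOSITE_ENDPOINTS)
        unmappable = sorted(set(trial.endpoints) - available)
        if unmappable:
            raise ConfigurationError(
                f"trial {trial.id}: endpoints {unmappable} not in equation set "
                f"{equations.name!r} (available: {sorted(available)})"
            )
        for arm in trial.arms:
            arm_n = arm.n or n
            result = run_arm(trial, arm, equations, arm_n, seed, dt, trajectory, max_horizon)
            predicted = annualize(result, strict=False).set_index("endpoint")["rate"]
            obs = trial.observed
            obs_arm = obs.loc[obs["arm"] == arm.label]
            for row in obs_arm.itertuples(index=False):
                if row.endpoint not in trial.endpoints:
                    continue
                if row.endpoint not in predicted.index:
                    logger.warning(
                        "%s/%s: no predicted rate for %s; pair skipped",
                        trial.id, arm.label, row.endpoint,
                    )
                    continue
                records.append(
                    {
                        "study": trial.id,
                        "arm": arm.label,
                        "endpoint": row.endpoint,
                        "stratum": trial.stratum,
                        "observed": float(row.rate),
                        "predicted": float(predicted.loc[row.endpoint]),
                    }
                )
        known |= set(trial.endpoints)
    return EndpointPairSet(pd.DataFrame.from_records(
        records, columns=["study", "arm", "endpoint", "stratum", "observed", "predicted"]
    ))
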