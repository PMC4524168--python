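"""Configuration-driven end-to-end validation runner.

A pipeline run loads trial specifications, observed-endpoint tables and one
or more equation registries, simulates every (study, arm) under each
equation set, and writes pair sets, fit tables, optional uncertainty-sweep
tables and a plain-text run report to the output directory. All randomness
flows from a single master seed recorded in the report.
"""

from __future__ import annotations

import importlib.resources
import logging
import re
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from .gof import (
    EndpointPairSet,
    FitSummary,
    SweepResult,
    SWEEPABLE_FACTORS,
    ols_observed_on_predicted,
    stratified_fit,
    uncertainty_sweep,
)
from .risk import EquationSet, load_equation_set
from .simulate import DEFAULT_DT, MAX_HORIZON, run_validation
from .synthetic import (
    RATE_UNITS,
    TrialSpec,
    demo_trials,
    generate_pseudo_observed,
    load_trial_spec,
    read_endpoint_table,
    save_trial_spec,
    write_endpoint_table,
)

logger = logging.getLogger(__name__)

MIN_COHORT_SIZE = 100


class PipelineConfigError(ValueError):
    pass


class ComparisonError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """Validated configuration of one pipeline run."""

    trial_specs: tuple[str, ...]
    observed_tables: tuple[str, ...]
    equation_registries: tuple[str, ...]
    out_dir: str = "t2dsim-out"
    n_patients: int = 2000
    seed: int = 0
    dt: float = DEFAULT_DT
    max_horizon: float = MAX_HORIZON
    sweep: bool = False
    sweep_factors: tuple[str, ...] = SWEEPABLE_FACTORS
    rate_units: str = RATE_UNITS

    def __post_init__(self):
        if self.dt <= 0:
            raise PipelineConfigError(f"cycle length must be > 0, got {self.dt}")
        if not 0 < self.max_horizon <= MAX_HORIZON:
            raise PipelineConfigError(
                f"horizon must lie in (0, {MAX_HORIZON}], got {self.max_horizon}"
            )
        if self.n_patients < MIN_COHORT_SIZE:
            raise PipelineConfigError(
                f"cohort size per arm must be >= {MIN_COHORT_SIZE}, got {self.n_patients}"
            )
        if not self.trial_specs:
            raise PipelineConfigError("at least one trial spec required")
        if not self.equation_registries:
            raise PipelineConfigError("at least one equation registry required")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        payload = yaml.safe_load(path.read_text())
        base = path.parent

        def resolve(p: str) -> str:
            q = Path(p)
            return str(q if q.is_absolute() else base / q)

        def resolve_all(key) -> tuple[str, ...]:
            return tuple(resolve(p) for p in payload.get(key, []))

        kwargs = {
            "trial_specs": resolve_all("trial_specs"),
            "observed_tables": resolve_all("observed_tables"),
            "equation_registries": resolve_all("equation_registries"),
        }
        if "out_dir" in payload:
            kwargs["out_dir"] = resolve(payload["out_dir"])
        for key in ("n_patients", "seed", "dt", "max_horizon", "sweep", "rate_units"):
            if key in payload:
                kwargs[key] = payload[key]
        if "sweep_factors" in payload:
            kwargs["sweep_factors"] = tuple(payload["sweep_factors"])
        return cls(**kwargs)


@dataclass
class SetReport:
    """Everything computed for one equation set."""

    equation_set: str
    pairs: EndpointPairSet
    fit: FitSummary
    by_study: pd.DataFrame
    by_endpoint: pd.DataFrame
    by_stratum: pd.DataFrame
    sweeps: dict[str, SweepResult] = field(default_factory=dict)


@dataclass
class RunReport:
    config: PipelineConfig
    reports: dict[str, SetReport]
    comparison: pd.DataFrame | None
    outputs: list[str]
    warnings: list[str]
    elapsed_seconds: float


def _slug(name: str) -> str:
    return re.sub(r"[^a-z0-9]+", "-", name.lower()).strip("-")


def _load_inputs(config: PipelineConfig) -> tuple[list[TrialSpec], list[EquationSet]]:
    """Fail-fast loading: nothing simulates until every input validates."""
    for path in config.trial_specs + config.observed_tables + config.equation_registries:
        if not Path(path).exists():
            raise PipelineConfigError(f"input file not found: {path}")
    trials = [load_trial_spec(p) for p in config.trial_specs]
    observed = (
        pd.concat([read_endpoint_table(p) for p in config.observed_tables], ignore_index=True)
        if config.observed_tables
        else None
    )
    if observed is not None:
        trials = [t.with_observed(observed) for t in trials]
    equation_sets = [load_equation_set(p) for p in config.equation_registries]
    names = [s.name for s in equation_sets]
    if len(set(names)) != len(names):
        raise PipelineConfigError(f"equation set names are not unique: {names}")
    return trials, equation_sets


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Run the full validation for every configured equation set."""
    start = time.perf_counter()
    trials, equation_sets = _load_inputs(config)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: list[str] = []
    warnings: list[str] = []
    reports: dict[str, SetReport] = {}

    def emit(frame: pd.DataFrame, name: str) -> None:
        path = out_dir / name
        frame.to_csv(path, index=False)
        outputs.append(str(path))

    for eqset in equation_sets:
        logger.info("simulating equation set %s", eqset.name)
        pairs = run_validation(
            trials, eqset,
            n=config.n_patients, seed=config.seed,
            dt=config.dt, max_horizon=config.max_horizon,
        )
        fit = ols_observed_on_predicted(pairs)
        if fit.n_excluded_zero_observed:
            warnings.append(
                f"{eqset.name}: excluded {fit.n_excluded_zero_observed} "
                "zero-observed pairs from MAPE"
            )
        slug = _slug(eqset.name)
        emit(pairs.records, f"pairs_{slug}.csv")
        emit(pd.DataFrame([asdict(fit)]), f"fit_overall_{slug}.csv")
        by_study = stratified_fit(pairs, "study")
        by_endpoint = stratified_fit(pairs, "endpoint")
        by_stratum = stratified_fit(pairs, "stratum")
        emit(by_study, f"fit_by_study_{slug}.csv")
        emit(by_endpoint, f"fit_by_endpoint_{slug}.csv")
        emit(by_stratum, f"fit_by_stratum_{slug}.csv")

        sweeps: dict[str, SweepResult] = {}
        swept_factors = tuple(
            f for f in config.sweep_factors if f in eqset.required_covariates
        )
        if config.sweep and swept_factors:
            for trial in trials:
                sweep = uncertainty_sweep(
                    trial, eqset, swept_factors,
                    n=config.n_patients, seed=config.seed, dt=config.dt,
                )
                sweeps[trial.id] = sweep
                emit(sweep.table, f"sweep_{slug}_{_slug(trial.id)}.csv")
        reports[eqset.name] = SetReport(
            equation_set=eqset.name, pairs=pairs, fit=fit,
            by_study=by_study, by_endpoint=by_endpoint, by_stratum=by_stratum,
            sweeps=sweeps,
        )

    comparison = None
    if len(equation_sets) >= 2:
        first, second = equation_sets[0].name, equation_sets[1].name
        comparison = compare_equation_sets(reports[first], reports[second])
        emit(comparison, "comparison.csv")

    elapsed = time.perf_counter() - start
    report = RunReport(
        config=config, reports=reports, comparison=comparison,
        outputs=outputs, warnings=warnings, elapsed_seconds=elapsed,
    )
    _write_report_text(report, out_dir / "report.txt")
    report.outputs.append(str(out_dir / "report.txt"))
    return report


def _write_report_text(report: RunReport, path: Path) -> None:
    lines = [
        "t2dsim validation run report",
        f"master seed: {report.config.seed}",
        f"cohort size per arm: {report.config.n_patients}",
        f"cycle length: {report.config.dt} years; horizon cap: {report.config.max_horizon} years",
        "",
    ]
    for name, sub in report.reports.items():
        fit = sub.fit
        lines.append(
            f"[{name}] n={fit.n} MAPE={fit.mape:.2f}% R2={fit.r2:.3f} "
            f"intercept={fit.intercept:.3f} (SE {fit.intercept_se:.3f}) "
            f"slope={fit.slope:.3f} (SE {fit.slope_se:.3f})"
        )
    if report.warnings:
        lines.append("")
        lines.append("warnings:")
        lines.extend(f"  - {w}" for w in report.warnings)
    lines.append("")
    lines.append("outputs:")
    lines.extend(f"  - {Path(o).name}" for o in report.outputs)
    path.write_text("\n".join(lines) + "\n")


def compare_equation_sets(report_a: SetReport, report_b: SetReport) -> pd.DataFrame:
    """Side-by-side MAPE/R^2 per stratum for two equation sets.

    Both reports must cover identical (study, arm, endpoint) keys.
    """
    keys_a = set(map(tuple, report_a.pairs.records[["study", "arm", "endpoint"]].to_numpy()))
    keys_b = set(map(tuple, report_b.pairs.records[["study", "arm", "endpoint"]].to_numpy()))
    if keys_a != keys_b:
        raise ComparisonError(
            "pair keys differ between equation sets: "
            f"only in {report_a.equation_set}: {sorted(keys_a - keys_b)}; "
            f"only in {report_b.equation_set}: {sorted(keys_b - keys_a)}"
        )
    a, b = report_a.equation_set, report_b.equation_set
    if a == b:  # self-comparison: disambiguate column labels
        a, b = f"{a}.1", f"{b}.2"
    frames = []
    for group, table_a, table_b in (
        ("overall", report_a.by_stratum, report_b.by_stratum),
        ("study", report_a.by_study, report_b.by_study),
        ("endpoint", report_a.by_endpoint, report_b.by_endpoint),
    ):
        key_col = table_a.columns[0]
        merged = table_a.merge(table_b, on=[key_col, "n"], suffixes=(f"_{a}", f"_{b}"))
        merged = merged.rename(columns={key_col: "key"})
        if group == "overall":
            merged = merged[merged["key"].isin(["internal", "external", "overall"])]
        merged.insert(0, "group", group if group != "overall" else "stratum")
        frames.append(merged)
    out = pd.concat(frames, ignore_index=True)
    out["mape_diff"] = out[f"mape_pct_{b}"] - out[f"mape_pct_{a}"]
    return out


# --------------------------------------------------------------------------
# bundled demo inputs
# --------------------------------------------------------------------------

def packaged_registry_path(style: str) -> Path:
    """Path of a shipped placeholder registry (style 'ukpds68' or 'ukpds82')."""
    name = f"{style}_placeholder.json"
    with importlib.resources.as_file(
        importlib.resources.files("t2dsim.data").joinpath(name)
    ) as p:
        return Path(p)


def make_synthetic_inputs(
    out_dir: str | Path,
    seed: int = 0,
    n_pseudo: int = 20000,
    n_patients: int = 2000,
) -> Path:
    """Write a complete self-contained demo input set and return the config path.

    Two synthetic trials, both placeholder registries, and a pseudo-observed
    endpoint table generated by simulating the expanded-set registry at
    ``n_pseudo`` patients per arm. Validating against these inputs is a
    closed-loop (parameter-recovery) exercise.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    trials = demo_trials()
    eq82 = load_equation_set(packaged_registry_path("ukpds82"))
    eq68 = load_equation_set(packaged_registry_path("ukpds68"))

    trial_paths, observed_frames = [], []
    for trial in trials:
        path = out_dir / f"trial_{_slug(trial.id)}.yaml"
        save_trial_spec(trial, path)
        trial_paths.append(path.name)
        observed_frames.append(generate_pseudo_observed(trial, eq82, n=n_pseudo, seed=seed))
    observed = pd.concat(observed_frames, ignore_index=True)
    observed_path = out_dir / "observed_endpoints.csv"
    write_endpoint_table(observed, observed_path)

    reg82 = out_dir / "ukpds82_placeholder.json"
    reg68 = out_dir / "ukpds68_placeholder.json"
    eq82.save(reg82)
    eq68.save(reg68)

    config = {
        "trial_specs": trial_paths,
        "observed_tables": [observed_path.name],
        "equation_registries": [reg82.name, reg68.name],
        "out_dir": "results",
        "n_patients": n_patients,
        "seed": seed + 1,  # validation seeds independent of the generating seed
        "sweep": True,
    }
    config_path = out_dir / "config.yaml"
    config_path.write_text(yaml.safe_dump(config, sort_keys=False))
    return config_path
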