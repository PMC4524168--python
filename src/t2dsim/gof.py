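"""Observed-versus-predicted goodness-of-fit statistics.

Validation quality is summarised three ways, all computed on annualized
endpoint rates: the mean absolute percentage error

    MAPE = (1/n) * sum_i | (Y_i - X_i) / Y_i * 100 |

with Y the observed and X the predicted rates; the coefficient of
determination R^2 (squared Pearson correlation of X and Y); and an ordinary
least squares regression of observed on predicted, Y = a + b X, whose
intercept/slope (with SEs, t statistics and two-sided p values) quantify
systematic bias. A baseline-uncertainty sweep re-simulates with each
expanded risk factor fixed at the ends of its ±2-standard-error interval and
reports the induced prediction range per endpoint.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace as dc_replace
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .synthetic import (
    ALBUMINURIA_PREVALENCE_RANGE,
    SWEEP_HALF_WIDTHS,
    TrialSpec,
)

logger = logging.getLogger(__name__)

SWEEPABLE_FACTORS = ("albuminuria", "egfr", "heart_rate", "ldl", "wbc")


class UndefinedStatisticError(ValueError):
    pass


class ZeroObservedError(ZeroDivisionError):
    """A pair with observed rate 0 makes the percentage error undefined."""


class SweepConfigurationError(ValueError):
    pass


@dataclass
class EndpointPairSet:
    """Matched observed (Y) and predicted (X) annualized endpoint rates."""

    records: pd.DataFrame  # study, arm, endpoint, stratum, observed, predicted

    REQUIRED = ("study", "arm", "endpoint", "stratum", "observed", "predicted")

    def __post_init__(self):
        missing = set(self.REQUIRED) - set(self.records.columns)
        if missing:
            raise UndefinedStatisticError(f"pair set missing columns {sorted(missing)}")

    @property
    def n(self) -> int:
        return len(self.records)

    @property
    def observed(self) -> np.ndarray:
        return self.records["observed"].to_numpy(dtype=float)

    @property
    def predicted(self) -> np.ndarray:
        return self.records["predicted"].to_numpy(dtype=float)

    @property
    def residuals(self) -> np.ndarray:
        """Z = Y - X, the paired observed-minus-predicted differences."""
        return self.observed - self.predicted

    def subset(self, mask) -> "EndpointPairSet":
        return EndpointPairSet(self.records.loc[mask].reset_index(drop=True))

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "EndpointPairSet":
        return cls(pd.read_csv(path))


@dataclass(frozen=True)
class FitSummary:
    """Fit statistics for one pair set (or one stratum of it)."""

    n: int
    mape: float
    r2: float | None
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_t: float | None = None
    intercept_p: float | None = None
    slope: float | None = None
    slope_se: float | None = None
    slope_t: float | None = None
    slope_p: float | None = None
    n_excluded_zero_observed: int = 0


def _drop_zero_observed(pairs: EndpointPairSet, zero_policy: str) -> tuple[EndpointPairSet, int]:
    zero = pairs.records["observed"] == 0
    if not zero.any():
        return pairs, 0
    if zero_policy == "error":
        offenders = pairs.records.loc[zero, ["study", "arm", "endpoint"]]
        raise ZeroObservedError(
            "observed rate is 0 for records "
            f"{offenders.to_dict(orient='records')}: percentage error undefined"
        )
    kept = pairs.subset(~zero)
    logger.warning("excluded %d zero-observed pairs from MAPE", int(zero.sum()))
    return kept, int(zero.sum())


def mape(pairs: EndpointPairSet, zero_policy: str = "error") -> float:
    """Mean absolute percentage error of predicted against observed, in %.

    ``zero_policy`` controls records with observed rate 0, where the formula
    is undefined: ``"error"`` (default) raises naming the records,
    ``"exclude"`` drops them with a logged count.
    """
    pairs, _ = _drop_zero_observed(pairs, zero_policy)
    if pairs.n < 1:
        raise UndefinedStatisticError("MAPE requires at least one pair")
    y, x = pairs.observed, pairs.predicted
    return float(np.mean(np.abs((y - x) / y * 100.0)))


def r_squared(pairs: EndpointPairSet) -> float:
    """Squared Pearson correlation of observed and predicted rates."""
    if pairs.n < 2:
        raise UndefinedStatisticError("R^2 requires at least two pairs")
    y, x = pairs.observed, pairs.predicted
    if np.var(y) == 0 or np.var(x) == 0:
        raise UndefinedStatisticError("R^2 undefined: degenerate variance")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def ols_observed_on_predicted(
    pairs: EndpointPairSet, zero_policy: str = "exclude"
) -> FitSummary:
    """OLS of observed on predicted rates, Y = a + bX, with MAPE and R^2.

    A well-calibrated model has intercept a ≈ 0 and slope b ≈ 1.
    """
    if pairs.n < 3:
        raise UndefinedStatisticError("OLS requires at least three pairs")
    x = pairs.predicted
    if np.var(x) == 0:
        raise UndefinedStatisticError("OLS undefined: zero variance in predicted rates")
    y = pairs.observed
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    kept, n_excluded = _drop_zero_observed(pairs, zero_policy)
    return FitSummary(
        n=pairs.n,
        mape=mape(kept),
        r2=r_squared(pairs),
        intercept=float(fit.params[0]),
        intercept_se=float(fit.bse[0]),
        intercept_t=float(fit.tvalues[0]),
        intercept_p=float(fit.pvalues[0]),
        slope=float(fit.params[1]),
        slope_se=float(fit.bse[1]),
        slope_t=float(fit.tvalues[1]),
        slope_p=float(fit.pvalues[1]),
        n_excluded_zero_observed=n_excluded,
    )


def stratified_fit(pairs: EndpointPairSet, by: str) -> pd.DataFrame:
    """MAPE and R^2 per stratum (plus an overall row).

    ``by`` is one of ``study``, ``endpoint``, ``stratum``. Strata with fewer
    than two pairs, or degenerate variance, report MAPE with R^2 unavailable
    (NaN); empty strata are skipped with a warning.
    """
    if by not in ("study", "endpoint", "stratum"):
        raise UndefinedStatisticError(f"cannot stratify by {by!r}")

    def one(label: str, subset: EndpointPairSet) -> dict | None:
        if subset.n == 0:
            logger.warning("stratum %s=%s is empty; skipped", by, label)
            return None
        kept, _ = _drop_zero_observed(subset, "exclude")
        row = {by: label, "n": subset.n}
        row["mape_pct"] = mape(kept) if kept.n else np.nan
        try:
            row["r2"] = r_squared(subset)
        except UndefinedStatisticError:
            row["r2"] = np.nan
        return row

    rows = []
    for label in pd.unique(pairs.records[by]):
        row = one(str(label), pairs.subset(pairs.records[by] == label))
        if row is not None:
            rows.append(row)
    overall = one("overall", pairs)
    if overall is not None:
        rows.append(overall)
    return pd.DataFrame(rows, columns=[by, "n", "mape_pct", "r2"])


# --------------------------------------------------------------------------
# baseline risk-factor uncertainty sweep
# --------------------------------------------------------------------------

@dataclass
class SweepResult:
    """Per-(arm, endpoint, factor) prediction ranges from the baseline sweep.

    ``table`` columns: arm, endpoint, factor, lower, point, upper, width,
    most_influential. ``coverage`` is the fraction of (arm, endpoint) records
    whose observed rate lies inside the across-factor envelope (NaN when the
    trial carries no observed table).
    """

    table: pd.DataFrame
    coverage: float


def _fix_factor(trial: TrialSpec, factor: str, end: str) -> TrialSpec:
    profile = trial.profile
    if factor == "albuminuria":
        lo, hi = ALBUMINURIA_PREVALENCE_RANGE
        return dc_replace(trial, profile=dc_replace(profile, albuminuria=lo if end == "low" else hi))
    half_width = SWEEP_HALF_WIDTHS[factor]
    mean = getattr(profile, f"{factor}_mean")
    value = mean - half_width if end == "low" else mean + half_width
    return dc_replace(
        trial,
        profile=dc_replace(profile, **{f"{factor}_mean": value, f"{factor}_sd": 0.0}),
    )


def uncertainty_sweep(
    trial: TrialSpec,
    equations,
    factors: Sequence[str],
    n: int,
    seed: int,
    dt: float = 0.5,
) -> SweepResult:
    """Prediction ranges induced by baseline uncertainty in the expanded
    risk factors.

    For each factor the trial is re-simulated twice with that factor fixed at
    the lower and upper end of its ±2-SE interval (albuminuria: prevalence at
    the ends of its uniform range), everything else at the trial profile.
    Identical RNG streams are used across settings (common random numbers) so
    ranges reflect the factor, not simulation noise. The widest-range factor
    per (arm, endpoint) is flagged most influential.
    """
    from .simulate import annualize, run_arm  # local import avoids cycle

    unknown = sorted(set(factors) - set(SWEEPABLE_FACTORS))
    if unknown:
        raise SweepConfigurationError(
            f"unknown sweep factors {unknown}; choose from {SWEEPABLE_FACTORS}"
        )

    rows = []
    for arm in trial.arms:
        point = annualize(run_arm(trial, arm, equations, n, seed, dt), strict=False)
        point = point.set_index("endpoint")["rate"]
        for factor in factors:
            low_trial = _fix_factor(trial, factor, "low")
            high_trial = _fix_factor(trial, factor, "high")
            low = annualize(run_arm(low_trial, arm, equations, n, seed, dt), strict=False)
            high = annualize(run_arm(high_trial, arm, equations, n, seed, dt), strict=False)
            low = low.set_index("endpoint")["rate"]
            high = high.set_index("endpoint")["rate"]
            for endpoint in trial.endpoints:
                if endpoint not in point.index:
                    continue
                lo = float(min(low.get(endpoint, np.nan), high.get(endpoint, np.nan)))
                hi = float(max(low.get(endpoint, np.nan), high.get(endpoint, np.nan)))
                rows.append(
                    {
                        "arm": arm.label,
                        "endpoint": endpoint,
                        "factor": factor,
                        "lower": lo,
                        "point": float(point.loc[endpoint]),
                        "upper": hi,
                        "at_upper_factor_value": float(high.get(endpoint, np.nan))
                        >= float(low.get(endpoint, np.nan)),
                        "width": hi - lo,
                    }
                )

    table = pd.DataFrame(rows)
    if not table.empty:
        widest = table.groupby(["arm", "endpoint"])["width"].transform("max")
        table["most_influential"] = table["width"] >= widest

    coverage = float("nan")
    if trial.observed is not None and not trial.observed.empty and not table.empty:
        envelope = table.groupby(["arm", "endpoint"]).agg(
            env_lower=("lower", "min"), env_upper=("upper", "max")
        )
        merged = trial.observed.merge(
            envelope.reset_index(), on=["arm", "endpoint"], how="inner"
        )
        if len(merged):
            inside = (merged["rate"] >= merged["env_lower"]) & (
                merged["rate"] <= merged["env_upper"]
            )
            coverage = float(inside.mean())
    return SweepResult(table=table, coverage=coverage)
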