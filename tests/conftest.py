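import numpy as np
import pytest

import t2dsim as t
from t2dsim.risk import Covariate, EquationSet, RiskEquationSpec


@pytest.fixture(scope="session")
def eq82() -> EquationSet:
    return t.load_equation_set(t.packaged_registry_path("ukpds82"))


@pytest.fixture(scope="session")
def eq68() -> EquationSet:
    return t.load_equation_set(t.packaged_registry_path("ukpds68"))


@pytest.fixture(scope="session")
def demo():
    return t.demo_trials()


def single_equation_set(
    form: str,
    intercept: float,
    shape: float | None = None,
    covariates: tuple[Covariate, ...] = (),
    endpoint: str = "mi",
    eligibility: str = "mi_count == 0",
) -> EquationSet:
    """A one-equation registry for closed-form oracle experiments."""
    eq = RiskEquationSpec(
        endpoint=endpoint, form=form, intercept=intercept, shape=shape,
        covariates=covariates, eligibility=eligibility, kind="event",
    )
    return EquationSet(name=f"single-{form}", style="custom", equations=(eq,))


def mortality_only_set(intercept: float) -> EquationSet:
    eq = RiskEquationSpec(
        endpoint="death", form="exponential", intercept=intercept, kind="mortality",
    )
    return EquationSet(name="mortality-only", style="custom", equations=(eq,))


def flat_cohort(n: int, duration: float = 0.0) -> t.Cohort:
    """A covariate-free cohort: all factors zero, duration as given."""
    cohort = t.Cohort(n)
    cohort.duration[:] = duration
    return cohort


@pytest.fixture(scope="session")
def still_trajectory() -> t.TrajectoryConfig:
    """No drift anywhere: risk factors frozen for the whole horizon."""
    return t.TrajectoryConfig(
        weight_drift=0.0,
        egfr_drift=0.0,
        panel={
            "hba1c": t.CurveSpec("linear", {"slope": 0.0}),
            "sbp": t.CurveSpec("linear", {"slope": 0.0}),
            "tchdl": t.CurveSpec("linear", {"slope": 0.0}),
        },
    )
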