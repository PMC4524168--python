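"""MAPE, R^2, observed-on-predicted OLS and the uncertainty sweep."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import t2dsim as t
from conftest import single_equation_set
from t2dsim.gof import (
    SweepConfigurationError,
    UndefinedStatisticError,
    ZeroObservedError,
)
from t2dsim.risk import Covariate


def pair_set(observed, predicted, **labels):
    n = len(observed)
    return t.EndpointPairSet(pd.DataFrame({
        "study": labels.get("study", ["s"] * n),
        "arm": labels.get("arm", ["a"] * n),
        "endpoint": labels.get("endpoint", [f"e{i}" for i in range(n)]),
        "stratum": labels.get("stratum", ["internal"] * n),
        "observed": observed,
        "predicted": predicted,
    }))


# independent brute-force oracles -------------------------------------------

def mape_oracle(y, x):
    total = 0.0
    for yi, xi in zip(y, x):
        total += abs((yi - xi) / yi * 100.0)
    return total / len(y)


def ols_oracle(y, x):
    # closed-form normal equations for y = a + b x
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = len(x)
    b = ((x * y).sum() - x.sum() * y.sum() / n) / ((x * x).sum() - x.sum() ** 2 / n)
    a = y.mean() - b * x.mean()
    return a, b


class TestMape:
    def test_perfect_prediction_is_zero(self):
        assert t.mape(pair_set([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])) == 0.0

    def test_hand_arithmetic(self):
        assert t.mape(pair_set([10.0, 20.0], [5.0, 30.0])) == pytest.approx(50.0)
        assert t.mape(pair_set([8.0], [10.0])) == pytest.approx(25.0)

    def test_zero_observed_raises_naming_record(self):
        pairs = pair_set([1.0, 0.0], [1.0, 1.0], endpoint=["mi", "esrd"])
        with pytest.raises(ZeroObservedError, match="esrd"):
            t.mape(pairs)

    def test_zero_observed_excluded_under_policy(self):
        pairs = pair_set([10.0, 0.0], [5.0, 1.0])
        assert t.mape(pairs, zero_policy="exclude") == pytest.approx(50.0)

    @given(
        st.lists(st.tuples(st.floats(0.1, 50), st.floats(0, 50)),
                 min_size=1, max_size=30),
        st.floats(0.01, 100),
    )
    @settings(max_examples=200, deadline=None)
    def test_scale_invariance(self, yx, c):
        y = [p[0] for p in yx]
        x = [p[1] for p in yx]
        base = t.mape(pair_set(y, x))
        scaled = t.mape(pair_set([c * v for v in y], [c * v for v in x]))
        assert scaled == pytest.approx(base, rel=1e-9)


class TestRSquared:
    def test_perfect_affine_relation_is_one(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert t.r_squared(pair_set([2 * v + 3 for v in x], x)) == pytest.approx(1.0)

    def test_constructed_zero_correlation(self):
        # balanced design: X symmetric, Y even in X -> sample covariance 0
        x = [-2.0, -1.0, 1.0, 2.0]
        y = [4.0, 1.0, 1.0, 4.0]
        assert t.r_squared(pair_set(y, x)) == pytest.approx(0.0, abs=1e-12)

    def test_three_point_hand_oracle(self):
        x, y = [1.0, 2.0, 3.0], [1.0, 3.0, 2.0]
        r_num = np.cov(x, y, ddof=1)[0, 1]
        r = r_num / (np.std(x, ddof=1) * np.std(y, ddof=1))
        assert t.r_squared(pair_set(y, x)) == pytest.approx(r * r, rel=1e-12)

    def test_degenerate_variance_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            t.r_squared(pair_set([1.0, 1.0], [0.5, 0.7]))


class TestOls:
    def test_noiseless_identity(self):
        x = [0.5, 1.0, 2.0, 4.0]
        fit = t.ols_observed_on_predicted(pair_set(x, x))
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)
        assert fit.slope == pytest.approx(1.0, rel=1e-12)
        assert fit.r2 == pytest.approx(1.0)

    def test_three_point_exact_fit(self):
        fit = t.ols_observed_on_predicted(pair_set([1.0, 2.0, 3.0], [0.0, 1.0, 2.0]))
        assert fit.intercept == pytest.approx(1.0)
        assert fit.slope == pytest.approx(1.0)

    def test_parameter_recovery_on_noisy_linear_data(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 10, 10_000)
        y = 2.0 + 0.9 * x + rng.normal(0, 0.3, x.size)
        fit = t.ols_observed_on_predicted(pair_set(y, x))
        assert abs(fit.intercept - 2.0) < 3 * fit.intercept_se
        assert abs(fit.slope - 0.9) < 3 * fit.slope_se

    def test_too_few_pairs_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            t.ols_observed_on_predicted(pair_set([1.0, 2.0], [1.0, 2.0]))


class TestStratifiedFit:
    def test_single_study_matches_overall(self):
        pairs = pair_set([1.0, 2.0, 4.0], [1.1, 1.9, 3.5])
        table = t.stratified_fit(pairs, "study").set_index("study")
        assert table.loc["s", "mape_pct"] == pytest.approx(table.loc["overall", "mape_pct"])
        assert table.loc["s", "r2"] == pytest.approx(table.loc["overall", "r2"])

    def test_pooled_mape_is_record_weighted_mean_of_strata(self):
        pairs = pair_set(
            [1.0, 2.0, 4.0, 8.0, 10.0], [1.2, 2.1, 3.0, 9.0, 12.0],
            study=["A", "A", "B", "B", "B"],
        )
        table = t.stratified_fit(pairs, "study").set_index("study")
        weighted = (2 * table.loc["A", "mape_pct"] + 3 * table.loc["B", "mape_pct"]) / 5
        assert table.loc["overall", "mape_pct"] == pytest.approx(weighted)

    def test_single_pair_stratum_reports_mape_without_r2(self):
        pairs = pair_set([1.0, 2.0, 3.0], [1.1, 2.2, 2.7],
                         endpoint=["mvd", "mi", "mi"])
        table = t.stratified_fit(pairs, "endpoint").set_index("endpoint")
        assert table.loc["mvd", "mape_pct"] == pytest.approx(10.0)
        assert np.isnan(table.loc["mvd", "r2"])

    def test_unknown_stratifier_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            t.stratified_fit(pair_set([1.0], [1.0]), "country")


class TestUncertaintySweep:
    def test_unknown_factor_rejected(self, demo, eq82):
        with pytest.raises(SweepConfigurationError):
            t.uncertainty_sweep(demo[0], eq82, ["bmi"], n=100, seed=0)

    def test_no_influence_factor_gives_degenerate_range(self, demo, still_trajectory):
        # heart rate appears in no equation here -> identical runs under CRN
        eqs = single_equation_set(
            "exponential", intercept=-4.0,
            covariates=(Covariate("hba1c", 0.1, "offset", 7.5),),
        )
        trial = dataclasses.replace(demo[0], endpoints=("mi",))
        result = t.uncertainty_sweep(trial, eqs, ["heart_rate"], n=400, seed=3)
        assert (result.table["lower"] == result.table["upper"]).all()

    def test_positive_coefficient_upper_end_from_upper_value(self, demo):
        eqs = single_equation_set(
            "exponential", intercept=-4.5,
            covariates=(Covariate("wbc", 0.25, "offset", 6.9),),
        )
        trial = dataclasses.replace(demo[0], endpoints=("mi",))
        result = t.uncertainty_sweep(trial, eqs, ["wbc"], n=2000, seed=4)
        assert result.table["at_upper_factor_value"].all()
        assert (result.table["upper"] > result.table["lower"]).all()

    def test_ranges_contain_point_prediction_within_mc_error(self, demo, eq82):
        result = t.uncertainty_sweep(demo[0], eq82, ["egfr", "wbc"], n=3000, seed=5)
        env = result.table.groupby(["arm", "endpoint"]).agg(
            lower=("lower", "min"), upper=("upper", "max"), point=("point", "first"),
        )
        rates = env["point"]
        slack = 3 * rates / np.sqrt(np.maximum(rates * 0.01 * 3000 * 5, 1.0))
        assert ((env["point"] >= env["lower"] - slack) &
                (env["point"] <= env["upper"] + slack)).all()

    def test_widest_factor_flagged_most_influential(self, demo, eq82):
        result = t.uncertainty_sweep(demo[0], eq82, ["egfr", "wbc"], n=1500, seed=6)
        flagged = result.table[result.table["most_influential"]]
        by_key = result.table.groupby(["arm", "endpoint"])["width"].max()
        for row in flagged.itertuples(index=False):
            assert row.width == by_key.loc[(row.arm, row.endpoint)]
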