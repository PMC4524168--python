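"""Risk-equation engine: linear predictors, hazard forms, registries."""

import json
import math

import pytest
from hypothesis import given, settings, strategies as st

import t2dsim as t
from t2dsim.risk import (
    Covariate,
    EquationSet,
    MissingCovariateError,
    RegistryError,
    RiskEquationSpec,
)


class TestRegistry:
    def test_shipped_expanded_registry_has_13_equations(self, eq82):
        assert len(eq82.equations) == 13
        assert eq82.style == "ukpds82"
        assert any(e.endpoint.startswith("secondary_") for e in eq82.equations)

    def test_shipped_classic_registry_excludes_expanded_covariates(self, eq68):
        from t2dsim.state import EXPANDED_COVARIATES

        assert eq68.style == "ukpds68"
        assert not (eq68.required_covariates & EXPANDED_COVARIATES)

    def test_negative_weibull_shape_rejected(self):
        with pytest.raises(RegistryError):
            RiskEquationSpec(endpoint="mi", form="weibull", intercept=-5.0, shape=-1.0)

    def test_unknown_covariate_rejected(self):
        with pytest.raises(RegistryError):
            RiskEquationSpec(
                endpoint="mi", form="exponential", intercept=-5.0,
                covariates=(Covariate("bmi_squared", 0.1),),
            )

    def test_save_load_round_trip(self, eq82, tmp_path):
        path = tmp_path / "set.json"
        eq82.save(path)
        back = t.load_equation_set(path)
        assert back.to_dict() == eq82.to_dict()

    def test_classic_style_referencing_expanded_covariate_rejected(self):
        eq = RiskEquationSpec(
            endpoint="mi", form="exponential", intercept=-5.0,
            covariates=(Covariate("wbc", 0.1),),
        )
        with pytest.raises(RegistryError, match="expanded"):
            EquationSet(name="bad", style="ukpds68", equations=(eq,))

    def test_expanded_style_requires_secondary_equations(self, eq82):
        primaries = tuple(
            e for e in eq82.equations if not e.endpoint.startswith("secondary_")
        )
        with pytest.raises(RegistryError, match="secondary"):
            EquationSet(name="bad", style="ukpds82", equations=primaries)

    def test_malformed_file_names_problem(self, tmp_path):
        path = tmp_path / "broken.json"
        path.write_text(json.dumps({"name": "x", "equations": [{"endpoint": "mi"}]}))
        with pytest.raises(RegistryError):
            t.load_equation_set(path)

    def test_duplicate_endpoints_rejected(self):
        eq = RiskEquationSpec(endpoint="mi", form="exponential", intercept=-5.0)
        with pytest.raises(RegistryError, match="duplicate"):
            EquationSet(name="dup", equations=(eq, eq))


class TestLinearPredictor:
    def test_no_covariates_returns_intercept(self):
        eq = RiskEquationSpec(endpoint="mi", form="exponential", intercept=-1.25)
        assert t.linear_predictor(eq, t.PatientState()) == -1.25

    def test_hand_arithmetic_single_identity_covariate(self):
        # -1 + 0.2 * 5 == 0
        eq = RiskEquationSpec(
            endpoint="mi", form="exponential", intercept=-1.0,
            covariates=(Covariate("tchdl", 0.2, "identity"),),
        )
        patient = t.PatientState(tchdl=5.0)
        assert t.linear_predictor(eq, patient) == pytest.approx(0.0)

    def test_transforms(self):
        eq = RiskEquationSpec(
            endpoint="mi", form="exponential", intercept=0.0,
            covariates=(
                Covariate("sbp", 1.0, "offset", 140.0),
                Covariate("smoker", 2.0, "indicator"),
                Covariate("wbc", 1.0, "log"),
            ),
        )
        patient = t.PatientState(sbp=150.0, smoker=1, wbc=math.e)
        assert t.linear_predictor(eq, patient) == pytest.approx(10.0 + 2.0 + 1.0)

    def test_non_finite_covariate_raises_not_imputes(self):
        eq = RiskEquationSpec(
            endpoint="chf", form="exponential", intercept=0.0,
            covariates=(Covariate("heart_rate", 0.01),),
        )
        patient = t.PatientState(heart_rate=float("nan"))
        with pytest.raises(MissingCovariateError, match="heart_rate"):
            t.linear_predictor(eq, patient)


class TestCycleProbability:
    def test_exponential_closed_form(self):
        # hazard 0.1/yr over half a year: 1 - exp(-0.05)
        eq = RiskEquationSpec(endpoint="mi", form="exponential",
                              intercept=math.log(0.1), eligibility="true")
        p = t.cycle_event_probability(eq, t.PatientState(), t=0.0, dt=0.5)
        assert p == pytest.approx(1 - math.exp(-0.05), rel=1e-12)

    def test_zero_hazard_gives_zero_for_every_form(self):
        for form, shape in (("exponential", None), ("weibull", 1.3),
                            ("gompertz", 0.1), ("logistic", None)):
            intercept = -800.0  # exp(lp) underflows to exactly 0
            eq = RiskEquationSpec(endpoint="mi", form=form, intercept=intercept,
                                  shape=shape, eligibility="true")
            assert t.cycle_event_probability(eq, t.PatientState(), t=1.0, dt=0.5) == 0.0

    def test_weibull_shape_one_equals_exponential(self):
        lp = -2.3
        exp_eq = RiskEquationSpec(endpoint="mi", form="exponential",
                                  intercept=lp, eligibility="true")
        wei_eq = RiskEquationSpec(endpoint="mi", form="weibull", shape=1.0,
                                  intercept=lp, eligibility="true")
        for tt, dt in ((0.0, 0.5), (3.0, 0.5), (7.5, 1.0)):
            a = t.cycle_event_probability(exp_eq, t.PatientState(), tt, dt)
            b = t.cycle_event_probability(wei_eq, t.PatientState(), tt, dt)
            assert abs(a - b) < 1e-12

    def test_gompertz_small_shape_converges_to_exponential(self):
        lp = -2.0
        exp_eq = RiskEquationSpec(endpoint="mi", form="exponential",
                                  intercept=lp, eligibility="true")
        gom_eq = RiskEquationSpec(endpoint="mi", form="gompertz", shape=1e-8,
                                  intercept=lp, eligibility="true")
        a = t.cycle_event_probability(exp_eq, t.PatientState(), 1.0, 0.5)
        b = t.cycle_event_probability(gom_eq, t.PatientState(), 1.0, 0.5)
        assert abs(a - b) / a < 1e-6

    def test_logistic_annual_probability_conversion(self):
        eq = RiskEquationSpec(endpoint="mi", form="logistic", intercept=0.0,
                              eligibility="true")
        # lp = 0 -> annual probability 0.5; over 2 years: 1 - 0.5^2
        assert t.cycle_event_probability(eq, t.PatientState(), 0.0, dt=2.0) == pytest.approx(0.75)

    @given(
        lp=st.floats(-8, 1),
        bump=st.floats(0, 3),
        tt=st.floats(0, 30),
        dt=st.floats(0.1, 2.0),
        form_shape=st.sampled_from(
            [("exponential", None), ("weibull", 0.7), ("weibull", 1.8),
             ("gompertz", 0.1), ("logistic", None)]
        ),
    )
    @settings(max_examples=200, deadline=None)
    def test_probability_bounded_and_monotone_in_lp(self, lp, bump, tt, dt, form_shape):
        form, shape = form_shape
        lo = RiskEquationSpec(endpoint="mi", form=form, intercept=lp,
                              shape=shape, eligibility="true")
        hi = RiskEquationSpec(endpoint="mi", form=form, intercept=lp + bump,
                              shape=shape, eligibility="true")
        p_lo = t.cycle_event_probability(lo, t.PatientState(), tt, dt)
        p_hi = t.cycle_event_probability(hi, t.PatientState(), tt, dt)
        assert 0.0 <= p_lo < 1.0 and 0.0 <= p_hi < 1.0
        assert p_hi >= p_lo

    def test_probability_vanishes_as_dt_shrinks(self):
        eq = RiskEquationSpec(endpoint="mi", form="weibull", shape=1.4,
                              intercept=-2.0, eligibility="true")
        p = [t.cycle_event_probability(eq, t.PatientState(), 2.0, dt)
             for dt in (0.5, 0.05, 0.005, 0.0005)]
        assert all(a > b for a, b in zip(p, p[1:]))
        assert p[-1] < 1e-3


class TestEligibility:
    def test_secondary_event_requires_first_event(self, eq82):
        eq = eq82["secondary_mi"]
        assert not t.eligible(eq, t.PatientState(mi_count=0))
        assert t.eligible(eq, t.PatientState(mi_count=1))

    def test_first_events_are_not_repeatable(self, eq82):
        assert not t.eligible(eq82["mi"], t.PatientState(mi_count=1))
        assert not t.eligible(eq82["blindness"], t.PatientState(blindness=1))

    def test_ineligible_patient_gets_zero_probability_not_error(self, eq82):
        p = t.cycle_event_probability(eq82["secondary_mi"],
                                      t.PatientState(mi_count=0), 0.0, 0.5)
        assert p == 0.0

    def test_or_conjunction_grammar(self, eq82):
        eq = eq82["death_hist"]
        assert t.eligible(eq, t.PatientState(stroke_count=2))
        assert t.eligible(eq, t.PatientState(chf=1))
        assert not t.eligible(eq, t.PatientState())

    def test_predicate_is_pure(self, eq82):
        patient = t.PatientState(mi_count=1, chf=1)
        before = vars(patient).copy()
        t.eligible(eq82["death_hist"], patient)
        assert vars(patient) == before
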