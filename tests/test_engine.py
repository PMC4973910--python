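"""DPP accounting: PARF, regression approach, rounding, full scenarios."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chdimpact import (
    Scenario,
    dpp_parf,
    dpp_regression,
    parf,
    round_to_5,
    run_scenario,
    strata_index,
)


class TestParf:
    @pytest.mark.parametrize(
        "p,rr,expected",
        [(0.0, 2.0, 0.0), (0.5, 1.0, 0.0), (0.5, 3.0, 0.5), (1.0, 3.0, 2 / 3)],
    )
    def test_known_values(self, p, rr, expected):
        assert parf(p, rr) == pytest.approx(expected)

    @given(p=st.floats(0, 1), rr=st.floats(0.01, 10))
    @settings(deadline=None, max_examples=300)
    def test_agrees_with_direct_formula_on_grid(self, p, rr):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            value = parf(p, rr)
        assert value == pytest.approx(p * (rr - 1) / (1 + p * (rr - 1)))
        if rr >= 1:
            assert 0 <= value < 1

    def test_protective_rr_warns(self):
        with pytest.warns(UserWarning, match="protective"):
            assert parf(0.5, 0.5) < 0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            parf(1.5, 2.0)
        with pytest.raises(ValueError):
            parf(0.5, 0.0)


class TestDppRegression:
    def test_zero_change_zero_dpp(self):
        assert dpp_regression(1000, 0.0, 0.3) == 0.0

    def test_linear_closed_form(self):
        # 1000 deaths, 0.5 mmol/L reduction, beta 0.30 -> 150 prevented
        assert dpp_regression(1000, -0.5, 0.30) == pytest.approx(150.0)

    def test_loglinear_closed_form(self):
        expected = 1000 * (1 - np.exp(-0.15))
        got = dpp_regression(1000, -0.5, 0.30, form="loglinear")
        assert got == pytest.approx(expected)  # ~139.3
        assert got == pytest.approx(139.29, abs=0.01)

    def test_sign_convention_improvement_positive(self):
        assert dpp_regression(1000, -0.5, 0.30) > 0
        assert dpp_regression(1000, 0.5, 0.30) < 0
        assert dpp_regression(1000, 0.5, 0.30, form="loglinear") < 0

    @given(delta=st.floats(-2, 2), beta=st.floats(0, 1), deaths=st.floats(0, 1e4))
    @settings(deadline=None, max_examples=100)
    def test_loglinear_never_exceeds_linear_magnitude(self, delta, beta, deaths):
        lin = dpp_regression(deaths, delta, beta)
        log = dpp_regression(deaths, delta, beta, form="loglinear")
        assert abs(log) <= abs(lin) + 1e-9
        # 1-exp(-x) may underflow to exactly 0 for denormal x
        assert np.sign(log) == np.sign(lin) or log == 0

    def test_unknown_form_rejected(self):
        with pytest.raises(ValueError):
            dpp_regression(10, 1.0, 0.1, form="quadratic")


class TestDppParf:
    @pytest.mark.parametrize(
        "deaths,before,after,expected",
        [(5975, 0.2, 0.2, 0.0), (1000, 0.25, 0.15, 100.0), (1000, 0.15, 0.25, -100.0)],
    )
    def test_known_values(self, deaths, before, after, expected):
        assert dpp_parf(deaths, before, after) == pytest.approx(expected)

    @given(deaths=st.floats(0, 1e4), a=st.floats(-0.9, 0.9), b=st.floats(-0.9, 0.9))
    @settings(deadline=None, max_examples=100)
    def test_antisymmetric_under_swap(self, deaths, a, b):
        assert dpp_parf(deaths, a, b) == pytest.approx(-dpp_parf(deaths, b, a))

    def test_parf_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            dpp_parf(1000, 1.0, 0.5)


class TestRoundTo5:
    @pytest.mark.parametrize(
        "x,expected",
        [(378, 380), (812.4, 810), (2.5, 5), (-2.5, -5), (0, 0), (-813, -815),
         (7.49, 5), (7.5, 10)],
    )
    def test_known_values(self, x, expected):
        assert round_to_5(x) == expected

    @given(x=st.floats(-1e6, 1e6))
    @settings(deadline=None, max_examples=200)
    def test_always_multiple_of_5_within_half_step(self, x):
        r = round_to_5(x)
        assert r % 5 == 0
        assert abs(r - x) <= 2.5


@pytest.fixture()
def inputs(baseline, params):
    return dict(
        deaths_2010=baseline.deaths_2010,
        risk_factors_2010=baseline.risk_factors_2010,
        expected_2025=baseline.expected_2025,
        params=params,
    )


class TestRunScenario:
    def test_null_scenario_all_zero(self, inputs):
        res = run_scenario(Scenario(name="null"), **inputs)
        assert (res.dpp == 0).all().all()
        assert res.net_expected_2025 == pytest.approx(
            float(inputs["expected_2025"].sum())
        )

    def test_additivity_total_equals_sum_of_parts(self, inputs, baseline):
        scen = Scenario(
            name="a", target_sfa=10.0,
            sfa_baseline={"male": 15.9, "female": 14.4},
            salt_delta=-1.0, smoking_delta=-0.05, inactivity_delta=-0.05,
        )
        res = run_scenario(scen, **inputs)
        assert res.total_dpp == pytest.approx(float(res.dpp.to_numpy().sum()))
        assert res.by_factor.sum() == pytest.approx(res.total_dpp)
        assert res.by_sex.sum() == pytest.approx(res.total_dpp)

    def test_single_stratum_smoking_matches_hand_computation(self, inputs, params):
        """Engine output for one stratum equals the standalone PARF difference."""
        scen = Scenario(name="smoke", smoking_delta=-0.05)
        res = run_scenario(scen, **inputs)
        key = ("male", "55-64")
        p0 = inputs["risk_factors_2010"].loc[key, "smoking_prev"]
        rr = params.rr_smoking[key]
        expected = inputs["expected_2025"][key] * (
            parf(p0, rr) - parf(p0 - 0.05, rr)
        )
        assert res.dpp.loc[key, "smoking"] == pytest.approx(expected)
        assert (res.dpp["cholesterol"] == 0).all()
        assert (res.dpp["sbp"] == 0).all()

    def test_single_stratum_cholesterol_matches_standalone_op(self, inputs, params):
        scen = Scenario(name="chol", target_sfa=10.0, sfa_baseline={"male": 15.9})
        res = run_scenario(scen, **inputs)
        key = ("male", "65-74")
        delta = (10.0 - 15.9) * 0.075
        expected = dpp_regression(
            inputs["deaths_2010"][key], delta, params.beta_chol[key]
        )
        assert res.dpp.loc[key, "cholesterol"] == pytest.approx(expected)
        # female strata untouched by a male-only diet baseline
        assert (res.dpp.loc["female", "cholesterol"] == 0).all()

    @pytest.mark.parametrize("form", ["linear", "loglinear"])
    def test_monotone_in_improvement_size(self, inputs, form):
        def total(salt_delta, smoking_delta):
            scen = Scenario(name="m", salt_delta=salt_delta,
                            smoking_delta=smoking_delta)
            return run_scenario(scen, **inputs, form=form).total_dpp

        assert total(-2.0, -0.05) > total(-1.0, -0.05) > total(-1.0, -0.02) > 0

    def test_prevalence_above_one_errors_naming_stratum(self, inputs):
        scen = Scenario(name="bad", smoking_delta=0.90)
        with pytest.raises(ValueError, match="female/45-54"):
            run_scenario(scen, **inputs)

    def test_prevalence_floored_at_zero(self, inputs):
        # a -10 pp reduction exceeds the 6% male smoking prevalence in 75-84
        scen = Scenario(name="floor", smoking_delta=-0.10)
        res = run_scenario(scen, **inputs)
        assert np.isfinite(res.total_dpp)
        assert res.dpp.loc[("male", "75-84"), "smoking"] > 0

    def test_missing_sfa_baseline_rejected(self, inputs):
        with pytest.raises(ValueError, match="sfa_baseline"):
            run_scenario(Scenario(name="x", target_sfa=10.0), **inputs)

    def test_tidy_rounding_within_2p5_of_raw(self, inputs):
        scen = Scenario(name="a", target_sfa=10.0,
                        sfa_baseline={"male": 15.9, "female": 14.4},
                        salt_delta=-1.0, smoking_delta=-0.05,
                        inactivity_delta=-0.05)
        tidy = run_scenario(scen, **inputs).tidy()
        assert (tidy["dpp_rounded"] % 5 == 0).all()
        assert (np.abs(tidy["dpp_rounded"] - tidy["dpp_raw"]) <= 2.5).all()
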