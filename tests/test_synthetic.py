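"""Fixture tables, regional weighting and the synthetic generators."""

import numpy as np
import pandas as pd
import pytest

from chdimpact import (
    AGE_BANDS,
    SEXES,
    Stratum,
    generate_effect_parameters,
    generate_mortality_series,
    load_fixture_risk_factors,
    weighted_national_mean,
)

# every printed cell of the published summary table (1986/2002/2010)
SUMMARY_GOLDEN = {
    ("male", 1986): dict(chol_mean=6.15, smoking_prev=0.313, sbp_mean=135.0,
                         diabetes_prev=0.028, bmi_mean=24.8, inactivity_prev=0.159),
    ("male", 2002): dict(chol_mean=5.51, smoking_prev=0.176, sbp_mean=132.9,
                         diabetes_prev=0.042, bmi_mean=26.0, inactivity_prev=0.127),
    ("male", 2010): dict(chol_mean=5.48, smoking_prev=0.132, sbp_mean=134.3,
                         diabetes_prev=0.067, bmi_mean=26.3, inactivity_prev=0.173),
    ("female", 1986): dict(chol_mean=6.19, smoking_prev=0.266, sbp_mean=132.7,
                           diabetes_prev=0.025, bmi_mean=23.8, inactivity_prev=0.156),
    ("female", 2002): dict(chol_mean=5.51, smoking_prev=0.195, sbp_mean=129.7,
                           diabetes_prev=0.034, bmi_mean=24.8, inactivity_prev=0.104),
    ("female", 2010): dict(chol_mean=5.53, smoking_prev=0.152, sbp_mean=130.8,
                           diabetes_prev=0.051, bmi_mean=24.9, inactivity_prev=0.120),
}

# every printed cell of the published 2010 age-detail table
AGE_GOLDEN_2010 = {
    "male": dict(
        chol_mean=[4.98, 5.36, 5.48, 5.56, 5.57, 5.48],
        smoking_prev=[0.118, 0.105, 0.138, 0.181, 0.158, 0.060],
        sbp_mean=[125.9, 126.4, 131.7, 139.2, 145.4, 151.3],
        diabetes_prev=[0.009, 0.018, 0.043, 0.094, 0.152, 0.180],
        bmi_mean=[25.5, 26.7, 26.7, 26.6, 26.5, 25.6],
        inactivity_prev=[0.114, 0.200, 0.197, 0.187, 0.148, 0.209],
    ),
    "female": dict(
        chol_mean=[4.66, 4.92, 5.51, 5.51, 5.8, 5.68],
        smoking_prev=[0.113, 0.143, 0.242, 0.167, 0.133, 0.063],
        sbp_mean=[118.3, 119.1, 126.5, 136.9, 144.2, 153.3],
        diabetes_prev=[0.008, 0.014, 0.029, 0.059, 0.104, 0.141],
        bmi_mean=[23.6, 24.5, 25.4, 25.3, 25.8, 25.2],
        inactivity_prev=[0.090, 0.128, 0.106, 0.099, 0.120, 0.233],
    ),
}


@pytest.mark.parametrize("year", [1986, 2002, 2010])
def test_summary_fixture_matches_every_printed_cell(year):
    table = load_fixture_risk_factors(year)
    for sex in SEXES:
        for col, value in SUMMARY_GOLDEN[(sex, year)].items():
            assert table.summary.loc[sex, col] == pytest.approx(value, abs=1e-12)


def test_2010_age_detail_matches_every_printed_cell():
    table = load_fixture_risk_factors(2010)
    assert table.by_stratum is not None and len(table.by_stratum) == 12
    for sex in SEXES:
        for col, values in AGE_GOLDEN_2010[sex].items():
            for band, value in zip(AGE_BANDS, values):
                assert table.by_stratum.loc[(sex, band), col] == pytest.approx(
                    value, abs=1e-12
                )


def test_age_detail_only_for_2010_and_unknown_year_rejected():
    assert load_fixture_risk_factors(1986).by_stratum is None
    with pytest.raises(ValueError, match="1986"):
        load_fixture_risk_factors(1999)


@pytest.mark.parametrize(
    "north,south,wn,ws,expected",
    [
        (5.0, 5.0, 0.15, 0.85, 5.0),
        (6.0, 5.0, 0.15, 0.85, 5.15),
        (123.4, 99.9, 1.0, 0.0, 123.4),
    ],
)
def test_weighted_national_mean(north, south, wn, ws, expected):
    assert weighted_national_mean(north, south, wn, ws) == pytest.approx(expected)


def test_weighted_national_mean_rejects_bad_weights():
    with pytest.raises(ValueError):
        weighted_national_mean(5, 5, 0.2, 0.85)
    with pytest.raises(ValueError):
        weighted_national_mean(5, 5, -0.1, 1.1)


class TestMortalityGenerator:
    pop = pd.Series(1_000_000.0, index=range(1986, 2011))
    stratum = Stratum("male", "65-74")

    def test_zero_decay_gives_constant_rates(self):
        s = generate_mortality_series(self.stratum, 1e-3, 0.0, self.pop)
        assert np.allclose(s.rate, 1e-3)

    def test_first_year_deaths_equal_rate_times_population(self):
        s = generate_mortality_series(self.stratum, 1e-3, 0.03, self.pop)
        assert s.deaths[0] == pytest.approx(1e-3 * 1_000_000)

    def test_expected_rate_follows_exponential_decay(self):
        s = generate_mortality_series(self.stratum, 1e-3, 0.03, self.pop)
        t = s.years - 1986
        assert np.allclose(s.rate, 1e-3 * np.exp(-0.03 * t), rtol=1e-3)

    def test_poisson_counts_reproducible_and_mean_matches(self):
        a = generate_mortality_series(self.stratum, 1e-3, 0.03, self.pop,
                                      noise="poisson", seed=42)
        b = generate_mortality_series(self.stratum, 1e-3, 0.03, self.pop,
                                      noise="poisson", seed=42)
        assert np.array_equal(a.deaths, b.deaths)

        n_rep = 500
        draws = np.stack([
            generate_mortality_series(self.stratum, 1e-3, 0.03, self.pop,
                                      noise="poisson", seed=s).deaths
            for s in range(n_rep)
        ])
        mean_expected = 1e-3 * np.exp(-0.03 * (np.arange(25))) * 1_000_000
        se = np.sqrt(mean_expected / n_rep)
        assert np.all(np.abs(draws.mean(axis=0) - mean_expected) < 3 * se)
        # Poisson: empirical variance tracks the mean
        ratio = draws.var(axis=0, ddof=1) / mean_expected
        assert np.all((ratio > 0.8) & (ratio < 1.2))

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            generate_mortality_series(self.stratum, -1e-3, 0.03, self.pop)
        with pytest.raises(ValueError, match="decay"):
            generate_mortality_series(self.stratum, 1e-3, -0.01, self.pop)
        with pytest.raises(ValueError):
            generate_mortality_series(self.stratum, 1e-3, 0.03, self.pop,
                                      noise="gamma")


class TestEffectParameterGenerator:
    def test_same_seed_bitwise_identical(self):
        a = generate_effect_parameters(seed=11)
        b = generate_effect_parameters(seed=11)
        for f in ("beta_chol", "beta_sbp", "rr_smoking", "rr_inactivity"):
            assert getattr(a, f).equals(getattr(b, f))

    @pytest.mark.parametrize("seed", [0, 1, 1234])
    def test_contracts_hold_for_any_seed(self, seed):
        p = generate_effect_parameters(seed=seed)
        assert (p.rr_smoking > 1).all()
        assert (p.rr_inactivity > 1).all()
        assert (p.beta_chol > 0).all() and (p.beta_sbp > 0).all()
        # effect magnitudes attenuate with age within each sex
        for sex in SEXES:
            for field in ("beta_chol", "beta_sbp"):
                vals = getattr(p, field)[sex].to_numpy()
                assert np.all(np.diff(vals) <= 0)
        # translation constants are fixed, never sampled
        assert p.clarke_pufa == 0.078
        assert p.clarke_mufa == 0.048
        assert p.salt_sbp_hyp == 7.2 and p.salt_sbp_norm == 3.6
        assert p.hyp_prev == 0.37
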