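"""Synthetic model inputs and packaged survey fixtures.

Two kinds of input live here:

* **Fixtures** — the published national risk-factor tables for 1986, 2002 and
  2010 (population means of total cholesterol and systolic blood pressure,
  smoking / physical-inactivity / diabetes prevalence, BMI), stratified by sex
  and, for 2010, by 10-year age band. These are real printed survey values and
  are returned exactly.

* **Generators** — seeded synthetic stand-ins for the inputs that are not
  publicly deposited: age-specific mortality count series with exponential
  decline and optional Poisson noise, and per-stratum effect parameters
  (regression coefficients and relative risks). Generated values are plausible
  for a Western European population but are synthetic, not measured.

All per-stratum quantities are pandas Series/DataFrames indexed by the
canonical (sex, age_band) MultiIndex from :mod:`chdimpact.strata`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .strata import AGE_BANDS, SEXES, Stratum, strata_index

FIXTURE_YEARS = (1986, 2002, 2010)

# Published national summary values (population means / prevalences) by year.
# Prevalences are stored as percentages here, converted to fractions on load.
_SUMMARY_ROWS = {
    # (sex, year): chol mmol/L, smoking %, SBP mm Hg, diabetes %, BMI, inactivity %
    ("male", 1986): (6.15, 31.3, 135.0, 2.8, 24.8, 15.9),
    ("male", 2002): (5.51, 17.6, 132.9, 4.2, 26.0, 12.7),
    ("male", 2010): (5.48, 13.2, 134.3, 6.7, 26.3, 17.3),
    ("female", 1986): (6.19, 26.6, 132.7, 2.5, 23.8, 15.6),
    ("female", 2002): (5.51, 19.5, 129.7, 3.4, 24.8, 10.4),
    ("female", 2010): (5.53, 15.2, 130.8, 5.1, 24.9, 12.0),
}

# Published 2010 values by 10-year age band (age detail exists only for 2010).
_BY_AGE_2010 = {
    "male": {
        "chol": [4.98, 5.36, 5.48, 5.56, 5.57, 5.48],
        "smoking_pct": [11.8, 10.5, 13.8, 18.1, 15.8, 6.0],
        "sbp": [125.9, 126.4, 131.7, 139.2, 145.4, 151.3],
        "diabetes_pct": [0.9, 1.8, 4.3, 9.4, 15.2, 18.0],
        "bmi": [25.5, 26.7, 26.7, 26.6, 26.5, 25.6],
        "inactivity_pct": [11.4, 20.0, 19.7, 18.7, 14.8, 20.9],
    },
    "female": {
        "chol": [4.66, 4.92, 5.51, 5.51, 5.8, 5.68],
        "smoking_pct": [11.3, 14.3, 24.2, 16.7, 13.3, 6.3],
        "sbp": [118.3, 119.1, 126.5, 136.9, 144.2, 153.3],
        "diabetes_pct": [0.8, 1.4, 2.9, 5.9, 10.4, 14.1],
        "bmi": [23.6, 24.5, 25.4, 25.3, 25.8, 25.2],
        "inactivity_pct": [9.0, 12.8, 10.6, 9.9, 12.0, 23.3],
    },
}

_PROFILE_COLUMNS = [
    "chol_mean",
    "sbp_mean",
    "smoking_prev",
    "inactivity_prev",
    "diabetes_prev",
    "bmi_mean",
]


def _validate_profile(df: pd.DataFrame) -> None:
    for col in ("smoking_prev", "inactivity_prev", "diabetes_prev"):
        bad = df[(df[col] < 0) | (df[col] > 1)]
        if not bad.empty:
            raise ValueError(f"{col} outside [0,1] for {bad.index.tolist()}")
    if ((df["chol_mean"] <= 2) | (df["chol_mean"] >= 12)).any():
        raise ValueError("cholesterol mean outside plausible range (2, 12) mmol/L")
    if ((df["sbp_mean"] <= 80) | (df["sbp_mean"] >= 220)).any():
        raise ValueError("SBP mean outside plausible range (80, 220) mm Hg")


@dataclass(frozen=True)
class RiskFactorTable:
    """Risk-factor fixture for one survey year.

    ``summary`` holds the sex-level population means (index: sex);
    ``by_stratum`` holds the full 12-stratum detail, available for 2010 only.
    Prevalence columns are fractions in [0, 1].
    """

    year: int
    summary: pd.DataFrame
    by_stratum: pd.DataFrame | None = None


def load_fixture_risk_factors(year: int) -> RiskFactorTable:
    """Return the published risk-factor table for ``year``.

    Parameters
    ----------
    year
        One of 1986, 2002 or 2010. Age-band detail is returned only for
        2010; the earlier years carry sex-level summaries.
    """
    if year not in FIXTURE_YEARS:
        raise ValueError(
            f"no risk-factor fixture for year {year}; available: {FIXTURE_YEARS}"
        )
    rows = []
    for sex in SEXES:
        chol, smoke, sbp, diab, bmi, inact = _SUMMARY_ROWS[(sex, year)]
        rows.append(
            {
                "sex": sex,
                "chol_mean": chol,
                "sbp_mean": sbp,
                "smoking_prev": smoke / 100.0,
                "inactivity_prev": inact / 100.0,
                "diabetes_prev": diab / 100.0,
                "bmi_mean": bmi,
            }
        )
    summary = pd.DataFrame(rows).set_index("sex")[_PROFILE_COLUMNS]

    by_stratum = None
    if year == 2010:
        data = {}
        for sex in SEXES:
            cols = _BY_AGE_2010[sex]
            for i, band in enumerate(AGE_BANDS):
                data[(sex, band)] = {
                    "chol_mean": cols["chol"][i],
                    "sbp_mean": cols["sbp"][i],
                    "smoking_prev": cols["smoking_pct"][i] / 100.0,
                    "inactivity_prev": cols["inactivity_pct"][i] / 100.0,
                    "diabetes_prev": cols["diabetes_pct"][i] / 100.0,
                    "bmi_mean": cols["bmi"][i],
                }
        by_stratum = pd.DataFrame.from_dict(data, orient="index")[_PROFILE_COLUMNS]
        by_stratum.index = pd.MultiIndex.from_tuples(
            by_stratum.index, names=["sex", "age_band"]
        )
        by_stratum = by_stratum.reindex(strata_index())
        _validate_profile(by_stratum)
    _validate_profile(summary)
    return RiskFactorTable(year=year, summary=summary, by_stratum=by_stratum)


def weighted_national_mean(
    north_value: float, south_value: float, w_north: float, w_south: float
) -> float:
    """Combine regional survey means into a national mean.

    National cholesterol and SBP levels are weighted averages of a northern
    cohort (weight 0.15) and a southern/urban cohort (weight 0.85), matching
    the national population distribution.
    """
    if w_north < 0 or w_south < 0:
        raise ValueError("weights must be non-negative")
    if abs(w_north + w_south - 1.0) > 1e-9:
        raise ValueError(f"weights must sum to 1, got {w_north + w_south}")
    return w_north * north_value + w_south * south_value


@dataclass(frozen=True)
class DietProfile:
    """Population dietary fat profile (percent of energy) and salt intake."""

    sfa_e: float
    mufa_e: float
    pufa_e: float
    salt: float  # g/day

    def __post_init__(self) -> None:
        if min(self.sfa_e, self.mufa_e, self.pufa_e, self.salt) < 0:
            raise ValueError("dietary quantities must be non-negative")
        if self.sfa_e + self.mufa_e + self.pufa_e > 100:
            raise ValueError("fat energy percentages exceed 100 E%")


#: Mean national salt intake, g/day (all ages, both sexes).
DEFAULT_SALT_G_PER_DAY = 10.0

#: Sex-specific baseline saturated-fat intakes (E%) used when evaluating the
#: low-fat scenario. Reverse-engineered calibration fixtures consistent with
#: the printed per-sex cholesterol deltas; overridable in configuration.
LOWFAT_SFA_BASELINE = {"male": 15.9, "female": 14.4}

#: Same for the high-fat scenario (consistent with +0.19 / +0.30 mmol/L).
HIGHFAT_SFA_BASELINE = {"male": 17.5, "female": 16.0}


def default_diet() -> DietProfile:
    """A current-intake diet profile typical of recent national surveys."""
    return DietProfile(sfa_e=16.0, mufa_e=14.0, pufa_e=6.0, salt=DEFAULT_SALT_G_PER_DAY)


@dataclass
class MortalitySeries:
    """Annual death counts, populations and rates for a single stratum."""

    stratum: Stratum
    years: np.ndarray
    deaths: np.ndarray
    population: np.ndarray

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.deaths = np.asarray(self.deaths, dtype=float)
        self.population = np.asarray(self.population, dtype=float)
        if not (len(self.years) == len(self.deaths) == len(self.population)):
            raise ValueError("years, deaths and population must have equal length")
        if np.any(np.diff(self.years) <= 0):
            raise ValueError("years must be strictly increasing")
        if np.any(self.deaths < 0):
            raise ValueError("death counts must be non-negative")
        if np.any(self.population <= 0):
            raise ValueError("populations must be positive")

    @property
    def rate(self) -> np.ndarray:
        """Per-capita mortality rate, deaths / population, per year."""
        return self.deaths / self.population

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sex": self.stratum.sex,
                "age_band": self.stratum.age_band,
                "year": self.years,
                "population": self.population,
                "deaths": self.deaths,
                "rate": self.rate,
            }
        )


def generate_mortality_series(
    stratum: Stratum,
    rate_start: float,
    decay: float,
    population_by_year: pd.Series,
    noise: str = "none",
    seed: int | None = None,
) -> MortalitySeries:
    """Simulate an exponentially declining age-specific mortality series.

    The expected rate in calendar year ``t`` is
    ``rate_start * exp(-decay * (t - t0))`` with ``t0`` the first year of
    ``population_by_year``. With ``noise="none"`` the death counts are the
    expected counts rounded to integers; with ``noise="poisson"`` they are
    Poisson draws with the expected count as mean.
    """
    if rate_start <= 0:
        raise ValueError("rate_start must be positive")
    if decay < 0:
        raise ValueError("decay must be non-negative (mortality decline model)")
    if noise not in ("none", "poisson"):
        raise ValueError(f"unknown noise model {noise!r}")
    pop = population_by_year.sort_index()
    years = pop.index.to_numpy(dtype=int)
    expected = rate_start * np.exp(-decay * (years - years[0])) * pop.to_numpy(float)
    if noise == "none":
        deaths = np.round(expected)
    else:
        rng = np.random.default_rng(seed)
        deaths = rng.poisson(expected).astype(float)
    return MortalitySeries(
        stratum=stratum, years=years, deaths=deaths, population=pop.to_numpy(float)
    )


@dataclass
class EffectParameters:
    """Per-stratum effect sizes plus the fixed translation constants.

    ``beta_chol`` / ``beta_sbp`` are proportional changes in CHD mortality per
    unit *increase* of the risk factor (1 mmol/L total cholesterol, 1 mm Hg
    SBP); both are stored positive and applied with the sign of the exposure
    change. Relative risks compare exposed (current smoker, physically
    inactive) with unexposed. The scalar constants translate diet into the
    intermediate factors: ``clarke_pufa``/``clarke_mufa`` are mmol/L total
    cholesterol per 1 E% saturated fat replaced by poly-/monounsaturated fat,
    and ``salt_sbp_hyp``/``salt_sbp_norm`` are the mm Hg SBP reductions per
    6 g/day salt reduction in hypertensive/normotensive people.
    """

    beta_chol: pd.Series
    beta_chol_se: pd.Series
    beta_sbp: pd.Series
    beta_sbp_se: pd.Series
    rr_smoking: pd.Series
    rr_smoking_lo: pd.Series
    rr_smoking_hi: pd.Series
    rr_inactivity: pd.Series
    rr_inactivity_lo: pd.Series
    rr_inactivity_hi: pd.Series
    clarke_pufa: float = 0.078
    clarke_mufa: float = 0.048
    salt_sbp_hyp: float = 7.2
    salt_sbp_norm: float = 3.6
    hyp_prev: float = 0.37

    def __post_init__(self) -> None:
        idx = strata_index()
        for name in (
            "beta_chol",
            "beta_chol_se",
            "beta_sbp",
            "beta_sbp_se",
            "rr_smoking",
            "rr_smoking_lo",
            "rr_smoking_hi",
            "rr_inactivity",
            "rr_inactivity_lo",
            "rr_inactivity_hi",
        ):
            series = getattr(self, name).reindex(idx)
            if series.isna().any():
                raise ValueError(f"{name} is missing strata")
            setattr(self, name, series.astype(float))
        if (self.beta_chol_se < 0).any() or (self.beta_sbp_se < 0).any():
            raise ValueError("standard errors must be non-negative")
        if (self.rr_smoking < 0).any() or (self.rr_inactivity < 0).any():
            raise ValueError("relative risks must be non-negative")
        if not 0 <= self.hyp_prev <= 1:
            raise ValueError("hypertension prevalence must be in [0,1]")

    def copy(self) -> "EffectParameters":
        kwargs = {
            f: getattr(self, f).copy() if isinstance(getattr(self, f), pd.Series)
            else getattr(self, f)
            for f in self.__dataclass_fields__
        }
        return EffectParameters(**kwargs)


# Age profiles (25-34 ... 75-84) used by the effect-parameter generator and by
# the calibrated defaults. Relative mortality effects of continuous factors
# attenuate with age; relative risks of the binary exposures do likewise.
CHOL_BETA_SHAPE = np.array([0.48, 0.40, 0.32, 0.24, 0.17, 0.09])
SBP_BETA_SHAPE = np.array([0.0065, 0.0058, 0.0050, 0.0042, 0.0034, 0.0026])
RR_SMOKING_SHAPE = np.array([2.8, 2.4, 2.0, 1.8, 1.5, 1.3])
RR_INACTIVITY_SHAPE = np.array([1.9, 1.8, 1.7, 1.6, 1.5, 1.35])


def _stack(values_by_sex: dict[str, np.ndarray]) -> pd.Series:
    data = np.concatenate([values_by_sex[s] for s in SEXES])
    return pd.Series(data, index=strata_index())


def generate_effect_parameters(
    seed: int | None = None, scale: str = "default"
) -> EffectParameters:
    """Draw a plausible synthetic set of per-stratum effect parameters.

    Stand-in for unavailable published coefficient tables. Betas are positive,
    attenuate monotonically with age, and carry proportional standard errors;
    relative risks exceed 1 with lognormal-style confidence intervals. The
    diet-translation constants are fixed, not sampled. Identical seeds yield
    identical parameter sets.
    """
    if scale != "default":
        raise ValueError(f"unknown plausibility preset {scale!r}")
    rng = np.random.default_rng(seed)

    def jittered_decreasing(shape: np.ndarray, rel: float = 0.10) -> np.ndarray:
        vals = shape * rng.uniform(1 - rel, 1 + rel, size=shape.size)
        return np.sort(vals)[::-1]  # enforce attenuation with age

    def jittered_rr(shape: np.ndarray, rel: float = 0.15) -> np.ndarray:
        excess = (shape - 1.0) * rng.uniform(1 - rel, 1 + rel, size=shape.size)
        return 1.0 + np.sort(excess)[::-1]

    beta_chol = _stack({s: jittered_decreasing(CHOL_BETA_SHAPE) for s in SEXES})
    beta_sbp = _stack({s: jittered_decreasing(SBP_BETA_SHAPE) for s in SEXES})
    rr_smoke = _stack({s: jittered_rr(RR_SMOKING_SHAPE) for s in SEXES})
    rr_inact = _stack({s: jittered_rr(RR_INACTIVITY_SHAPE) for s in SEXES})
    ci_factor = np.exp(1.96 * 0.15)
    return EffectParameters(
        beta_chol=beta_chol,
        beta_chol_se=0.12 * beta_chol,
        beta_sbp=beta_sbp,
        beta_sbp_se=0.12 * beta_sbp,
        rr_smoking=rr_smoke,
        rr_smoking_lo=rr_smoke / ci_factor,
        rr_smoking_hi=rr_smoke * ci_factor,
        rr_inactivity=rr_inact,
        rr_inactivity_lo=rr_inact / ci_factor,
        rr_inactivity_hi=rr_inact * ci_factor,
    )
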