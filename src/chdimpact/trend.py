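"""Exponential-decay trend fitting and baseline mortality projection.

Age-specific CHD mortality rates have fallen roughly exponentially in Western
populations for decades, so the baseline ("no change in risk factors")
scenario fits ``rate(t) = rate_ref * exp(-lambda * (t - ref_year))`` to each
stratum's observed 1986–2010 rates and extrapolates to the projection year.
The constant-rate counterfactual simply freezes the reference-year rate.

Two fitting routes are provided: ordinary least squares on log-rates (the
default; exponential decay with multiplicative error) and a deaths-weighted
Poisson regression with a log link and population offset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .strata import Stratum, require_all_strata, strata_index
from .synthetic import MortalitySeries


@dataclass(frozen=True)
class TrendFit:
    """Fitted exponential decline for one stratum.

    ``lam`` is the per-year decay rate (positive = mortality falling);
    ``rate_ref`` is the fitted per-capita rate at ``ref_year`` (the last
    observed year), which anchors all projections.
    """

    stratum: Stratum
    lam: float
    rate_ref: float
    ref_year: int
    r_squared: float
    residual_sd: float
    method: str = "ols"

    def __post_init__(self) -> None:
        if self.rate_ref <= 0:
            raise ValueError("fitted reference rate must be positive")


def fit_exponential_decay(
    series: MortalitySeries,
    method: str = "ols",
    continuity_correction: bool = False,
) -> TrendFit:
    """Fit an exponential decay model to one stratum's mortality rates.

    Parameters
    ----------
    series
        Observed annual deaths and populations.
    method
        ``"ols"`` (default): least squares of log(rate) on year.
        ``"poisson"``: Poisson GLM of deaths with log(population) offset.
    continuity_correction
        Add 0.5 to the death count in years with zero deaths (only those
        years). Off by default: zero rates raise instead, because a silent
        correction changes the fit.
    """
    if method not in ("ols", "poisson"):
        raise ValueError(f"unknown fitting method {method!r}")
    deaths = series.deaths.copy()
    zero_years = series.years[deaths == 0]
    if zero_years.size:
        if not continuity_correction:
            raise ValueError(
                f"zero death counts in years {zero_years.tolist()} for "
                f"{series.stratum.sex}/{series.stratum.age_band}: enable the "
                "continuity correction (adds 0.5 to affected counts) to fit"
            )
        deaths[series.deaths == 0] = 0.5
    if series.years.size < 3:
        raise ValueError("need at least 3 observed years to fit a trend")

    ref_year = int(series.years[-1])
    t = (series.years - ref_year).astype(float)
    rate = deaths / series.population
    log_rate = np.log(rate)

    if method == "ols":
        X = sm.add_constant(t)
        res = sm.OLS(log_rate, X).fit()
        intercept, slope = res.params
        r2 = float(res.rsquared)
        resid_sd = float(np.std(res.resid, ddof=2))
    else:
        X = sm.add_constant(t)
        res = sm.GLM(
            deaths, X, family=sm.families.Poisson(), offset=np.log(series.population)
        ).fit()
        intercept, slope = res.params
        fitted_log = intercept + slope * t
        resid = log_rate - fitted_log
        ss_tot = float(np.sum((log_rate - log_rate.mean()) ** 2))
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
        resid_sd = float(np.std(resid, ddof=2))
    return TrendFit(
        stratum=series.stratum,
        lam=float(-slope),
        rate_ref=float(np.exp(intercept)),
        ref_year=ref_year,
        r_squared=r2,
        residual_sd=resid_sd,
        method=method,
    )


def project_rate(fit: TrendFit, year: int) -> float:
    """Extrapolate the fitted per-capita rate to ``year`` (>= ref_year)."""
    if year < fit.ref_year:
        raise ValueError(f"projection year {year} precedes reference {fit.ref_year}")
    return fit.rate_ref * np.exp(-fit.lam * (year - fit.ref_year))


def expected_deaths(
    fits: dict[tuple[str, str], TrendFit] | list[TrendFit],
    year: int,
    population_projection: pd.Series,
    constant_rate: bool = False,
) -> pd.Series:
    """Expected deaths per stratum in ``year`` under the fitted trends.

    Multiplies each stratum's projected rate by its projected population.
    With ``constant_rate=True`` the reference-year rate is used unchanged
    (the constant-rate counterfactual). Totals by sex or overall are plain
    sums of the returned Series, taken before any rounding.
    """
    if isinstance(fits, list):
        fits = {f.stratum.key: f for f in fits}
    require_all_strata(pd.Index(list(fits)), "trend fits")
    require_all_strata(population_projection.index, "population projection")
    if (population_projection <= 0).any():
        raise ValueError("projected populations must be positive")
    idx = strata_index()
    rates = pd.Series(
        [
            fits[key].rate_ref if constant_rate else project_rate(fits[key], year)
            for key in idx
        ],
        index=idx,
    )
    return rates * population_projection.reindex(idx)


def totals_by_sex(per_stratum: pd.Series) -> pd.Series:
    """Sum a per-stratum Series over age bands, keeping the sex split."""
    return per_stratum.groupby(level="sex", sort=False).sum()
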