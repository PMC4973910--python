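"""Deaths-prevented-or-postponed (DPP) accounting engine.

Continuous risk factors (total cholesterol, SBP) contribute via the
regression approach: observed baseline-year deaths multiplied by the absolute
risk-factor change and an age/sex-specific coefficient for the relative
mortality change per unit. Binary factors (smoking, physical inactivity)
contribute via the population-attributable-risk-fraction (PARF) difference:
projected target-year deaths multiplied by PARF(baseline prevalence) minus
PARF(scenario prevalence).

Signs follow the convention that a risk-factor *improvement* yields a
*positive* DPP. Stratum and factor contributions are additive; all internal
accounting uses raw values and rounding to the nearest 5 deaths happens only
at reporting time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .strata import require_all_strata, strata_index
from .synthetic import EffectParameters
from .translate import ReplacementMix, salt_delta_to_sbp_delta, scenario_cholesterol_delta

FACTORS = ("cholesterol", "sbp", "smoking", "inactivity")


def parf(p: float, rr: float) -> float:
    """Population attributable risk fraction, ``p(rr-1) / (1 + p(rr-1))``.

    The share of mortality removable by eliminating an exposure with
    prevalence ``p`` and relative risk ``rr``. Negative (protective) values
    are allowed for ``rr < 1`` but flagged with a warning.
    """
    p_arr = np.asarray(p, dtype=float)
    rr_arr = np.asarray(rr, dtype=float)
    if np.any((p_arr < 0) | (p_arr > 1)):
        raise ValueError(f"prevalence must lie in [0,1], got {p}")
    if np.any(rr_arr <= 0):
        raise ValueError(f"relative risk must be positive, got {rr}")
    if np.any(rr_arr < 1):
        warnings.warn("relative risk < 1: PARF is negative (protective exposure)",
                      stacklevel=2)
    excess = p_arr * (rr_arr - 1.0)
    out = excess / (1.0 + excess)
    return out.item() if np.isscalar(p) and np.isscalar(rr) else out


def dpp_regression(deaths_2010, delta_rf: float, beta, form: str = "linear"):
    """DPP for a continuous risk factor via the regression approach.

    ``deaths_2010`` and ``beta`` may be scalars or aligned Series. The linear
    form is ``deaths × |Δ| × β``; the loglinear alternative is
    ``deaths × (1 − exp(−β|Δ|))``. Either way the sign is chosen so that a
    risk-factor reduction (Δ < 0) prevents deaths (positive DPP).
    """
    if form not in ("linear", "loglinear"):
        raise ValueError(f"unknown regression form {form!r}")
    if np.any(np.asarray(deaths_2010, dtype=float) < 0):
        raise ValueError("death counts must be non-negative")
    sign = -np.sign(delta_rf)
    mag = abs(delta_rf)
    if form == "linear":
        return sign * deaths_2010 * mag * beta
    return sign * deaths_2010 * (1.0 - np.exp(-beta * mag))


def dpp_parf(expected_deaths_2025, parf_before, parf_after):
    """DPP for a binary risk factor via the PARF difference.

    Target-year expected deaths times the drop in attributable fraction;
    positive when prevalence falls, antisymmetric under swapping
    before/after.
    """
    for v in np.atleast_1d(parf_before).tolist() + np.atleast_1d(parf_after).tolist():
        if not -1 < v < 1:
            raise ValueError("PARF values must lie in (-1, 1)")
    return expected_deaths_2025 * (np.asarray(parf_before) - np.asarray(parf_after))


def round_to_5(x):
    """Round to the nearest multiple of 5, ties away from zero."""
    x_arr = np.asarray(x, dtype=float)
    out = np.sign(x_arr) * 5.0 * np.floor(np.abs(x_arr) / 5.0 + 0.5)
    out = out.astype(int)
    return out.item() if np.isscalar(x) else out


@dataclass(frozen=True)
class Scenario:
    """A bundle of risk-factor changes applied between 2010 and 2025.

    ``target_sfa`` is the absolute saturated-fat intake (E%) the population
    moves to (None = diet unchanged); ``sfa_baseline`` gives the per-sex
    starting intakes. ``salt_delta`` is g/day (signed); smoking and
    inactivity deltas are absolute prevalence changes (e.g. -0.05 for a
    five-percentage-point reduction) applied uniformly to every stratum and
    floored at zero prevalence.
    """

    name: str
    target_sfa: float | None = None
    sfa_baseline: dict[str, float] = field(default_factory=dict)
    salt_delta: float = 0.0
    smoking_delta: float = 0.0
    inactivity_delta: float = 0.0


def null_scenario() -> Scenario:
    return Scenario(name="baseline")


@dataclass
class ScenarioResult:
    """Per-stratum, per-factor DPPs for one scenario plus bookkeeping."""

    scenario: Scenario
    dpp: pd.DataFrame  # index: strata; columns: FACTORS (raw values)
    baseline_expected_2025: pd.Series
    chol_delta: dict[str, float]
    sbp_delta: float
    regression_form: str

    @property
    def total_dpp(self) -> float:
        return float(self.dpp.to_numpy().sum())

    @property
    def by_factor(self) -> pd.Series:
        return self.dpp.sum(axis=0)

    @property
    def by_sex(self) -> pd.Series:
        return self.dpp.sum(axis=1).groupby(level="sex", sort=False).sum()

    @property
    def net_expected_2025(self) -> float:
        return float(self.baseline_expected_2025.sum()) - self.total_dpp

    def tidy(self) -> pd.DataFrame:
        """Long-format table: scenario, sex, age_band, factor, raw & rounded DPP."""
        long = (
            self.dpp.stack()
            .rename("dpp_raw")
            .reset_index()
            .rename(columns={"level_2": "factor"})
        )
        long.insert(0, "scenario", self.scenario.name)
        long["dpp_rounded"] = round_to_5(long["dpp_raw"].to_numpy())
        return long


def _shifted_prevalence(prev: pd.Series, delta: float, factor: str) -> pd.Series:
    shifted = prev + delta
    over = shifted[shifted > 1.0]
    if not over.empty:
        labels = ", ".join(f"{s}/{a}" for s, a in over.index)
        raise ValueError(f"{factor} prevalence exceeds 1 in strata: {labels}")
    return shifted.clip(lower=0.0)


def run_scenario(
    scenario: Scenario,
    deaths_2010: pd.Series,
    risk_factors_2010: pd.DataFrame,
    expected_2025: pd.Series,
    params: EffectParameters,
    mix: ReplacementMix | None = None,
    form: str = "linear",
) -> ScenarioResult:
    """Evaluate one scenario against the continuing-decline baseline.

    Cholesterol and SBP effects apply the regression approach to observed
    2010 deaths; smoking and inactivity apply the PARF difference to the
    2025 expected deaths. Returns raw (unrounded) per-stratum DPPs.
    """
    mix = mix or ReplacementMix()
    idx = strata_index()
    require_all_strata(deaths_2010.index, "2010 deaths")
    require_all_strata(risk_factors_2010.index, "2010 risk factors")
    require_all_strata(expected_2025.index, "2025 expected deaths")
    deaths_2010 = deaths_2010.reindex(idx)
    expected_2025 = expected_2025.reindex(idx)
    rf = risk_factors_2010.reindex(idx)

    dpp = pd.DataFrame(0.0, index=idx, columns=list(FACTORS))

    if scenario.target_sfa is not None:
        if not scenario.sfa_baseline:
            raise ValueError("scenario sets target_sfa but no per-sex sfa_baseline")
        chol_delta = scenario_cholesterol_delta(
            scenario.sfa_baseline, scenario.target_sfa, mix, params
        )
    else:
        chol_delta = {sex: 0.0 for sex in ("male", "female")}
    for sex, delta in chol_delta.items():
        sel = dpp.index.get_level_values("sex") == sex
        dpp.loc[sel, "cholesterol"] = dpp_regression(
            deaths_2010[sel], delta, params.beta_chol[sel], form=form
        )

    sbp_delta = salt_delta_to_sbp_delta(scenario.salt_delta, params)
    dpp["sbp"] = dpp_regression(deaths_2010, sbp_delta, params.beta_sbp, form=form)

    for factor, prev_col, rr, delta in (
        ("smoking", "smoking_prev", params.rr_smoking, scenario.smoking_delta),
        ("inactivity", "inactivity_prev", params.rr_inactivity, scenario.inactivity_delta),
    ):
        if delta == 0.0:
            continue
        p0 = rf[prev_col]
        p1 = _shifted_prevalence(p0, delta, factor)
        with warnings.catch_warnings():
            # protective draws (rr < 1) are legitimate under Monte Carlo
            # perturbation; the sign conventions handle them, so do not
            # flood the log with the per-call PARF warning here
            warnings.filterwarnings("ignore", message="relative risk < 1")
            parf_before = parf(p0.to_numpy(), rr.to_numpy())
            parf_after = parf(p1.to_numpy(), rr.to_numpy())
        dpp[factor] = dpp_parf(expected_2025.to_numpy(), parf_before, parf_after)

    return ScenarioResult(
        scenario=scenario,
        dpp=dpp,
        baseline_expected_2025=expected_2025,
        chol_delta=chol_delta,
        sbp_delta=sbp_delta,
        regression_form=form,
    )
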