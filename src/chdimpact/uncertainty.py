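"""Monte Carlo uncertainty propagation and the saturated-fat sensitivity sweep.

Parameter uncertainty is propagated by redrawing effect parameters from
configured distributions, re-evaluating the whole scenario model per draw,
and reporting empirical 2.5th/97.5th percentiles as 95% uncertainty
intervals. Draws are independent across parameters and iterations (no
correlation structure is modelled). Distribution defaults are normal on the
coefficient scale for regression betas and lognormal for relative risks so
draws stay positive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .engine import Scenario, run_scenario
from .synthetic import EffectParameters
from .translate import ReplacementMix

#: EffectParameters fields that may be targeted by a distribution, with the
#: companion field(s) describing their stored uncertainty.
_ARRAY_TARGETS = {
    "beta_chol": ("se", "beta_chol_se"),
    "beta_sbp": ("se", "beta_sbp_se"),
    "rr_smoking": ("ci", ("rr_smoking_lo", "rr_smoking_hi")),
    "rr_inactivity": ("ci", ("rr_inactivity_lo", "rr_inactivity_hi")),
}
_SCALAR_TARGETS = ("clarke_pufa", "clarke_mufa", "salt_sbp_hyp", "salt_sbp_norm",
                   "hyp_prev")


@dataclass(frozen=True)
class ParameterDistribution:
    """Sampling distribution for one parameter of :class:`EffectParameters`.

    ``target`` names the field. ``family`` is ``point`` (no noise),
    ``normal`` or ``lognormal``. ``scale`` is the dispersion on the
    documented scale (standard deviation for normal, sigma of log for
    lognormal); when None, the uncertainty stored on the parameter set
    itself (standard errors / confidence limits) is used. The location is
    always the current parameter value.
    """

    target: str
    family: str = "point"
    scale: float | None = None

    def __post_init__(self) -> None:
        if self.family not in ("point", "normal", "lognormal"):
            raise ValueError(f"unknown distribution family {self.family!r}")
        if self.scale is not None and self.scale < 0:
            raise ValueError("distribution scale must be non-negative")
        if self.family == "point" and self.scale:
            raise ValueError("point distributions must have zero scale")


@dataclass(frozen=True)
class UncertaintyInterval:
    """Central estimate with an empirical 95% uncertainty interval."""

    point: float
    low: float
    high: float
    n_draws: int
    seed: int | None

    def __post_init__(self) -> None:
        if self.low > self.high:
            raise ValueError("interval bounds out of order")
        if self.n_draws < 1:
            raise ValueError("need at least one draw")


def _stored_sigma(params: EffectParameters, target: str) -> np.ndarray:
    kind, ref = _ARRAY_TARGETS[target]
    if kind == "se":
        return getattr(params, ref).to_numpy()
    lo, hi = (getattr(params, r).to_numpy() for r in ref)
    return (np.log(hi) - np.log(lo)) / (2 * 1.96)  # sigma of log from 95% CI


def draw_parameters(
    params: EffectParameters,
    dists: list[ParameterDistribution],
    rng: np.random.Generator,
) -> EffectParameters:
    """One joint draw of a perturbed parameter set (i.i.d. across targets)."""
    drawn = params.copy()
    for dist in dists:
        if dist.target in _ARRAY_TARGETS:
            values = getattr(drawn, dist.target)
            if dist.family == "point":
                continue
            sigma = (
                np.full(len(values), dist.scale)
                if dist.scale is not None
                else _stored_sigma(params, dist.target)
            )
            if dist.family == "normal":
                new = values.to_numpy() + sigma * rng.standard_normal(len(values))
            else:
                new = values.to_numpy() * np.exp(sigma * rng.standard_normal(len(values)))
            setattr(drawn, dist.target, pd.Series(new, index=values.index))
        elif dist.target in _SCALAR_TARGETS:
            value = getattr(drawn, dist.target)
            if dist.family == "point":
                continue
            if dist.scale is None:
                raise ValueError(f"scalar target {dist.target!r} needs an explicit scale")
            if dist.family == "normal":
                value = value + dist.scale * rng.standard_normal()
            else:
                value = value * np.exp(dist.scale * rng.standard_normal())
            setattr(drawn, dist.target, value)
        else:
            raise ValueError(
                f"distribution targets unknown parameter {dist.target!r}; "
                f"known: {sorted(_ARRAY_TARGETS) + sorted(_SCALAR_TARGETS)}"
            )
    return drawn


def monte_carlo(
    model: Callable[[EffectParameters], Mapping[str, float]],
    params: EffectParameters,
    dists: list[ParameterDistribution],
    n_draws: int = 10_000,
    seed: int | None = None,
) -> dict[str, UncertaintyInterval]:
    """Propagate parameter uncertainty through ``model``.

    ``model`` maps a parameter set to named scalar outputs; it is evaluated
    once at the unperturbed parameters (the point estimate) and once per
    draw. Intervals are the empirical 2.5th and 97.5th percentiles across
    draws. Identical seeds give identical intervals.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    for dist in dists:  # validate targets before burning any draws
        if dist.target not in _ARRAY_TARGETS and dist.target not in _SCALAR_TARGETS:
            raise ValueError(f"distribution targets unknown parameter {dist.target!r}")
    rng = np.random.default_rng(seed)
    point = dict(model(params))
    samples: dict[str, np.ndarray] = {k: np.empty(n_draws) for k in point}
    for i in range(n_draws):
        drawn = draw_parameters(params, dists, rng)
        out = model(drawn)
        for k in samples:
            samples[k][i] = out[k]
    return {
        k: UncertaintyInterval(
            point=float(point[k]),
            low=float(np.percentile(samples[k], 2.5)),
            high=float(np.percentile(samples[k], 97.5)),
            n_draws=n_draws,
            seed=seed,
        )
        for k in samples
    }


def scenario_model(
    scenario: Scenario,
    deaths_2010: pd.Series,
    risk_factors_2010: pd.DataFrame,
    expected_2025: pd.Series,
    mix: ReplacementMix | None = None,
    form: str = "linear",
) -> Callable[[EffectParameters], dict[str, float]]:
    """Wrap one scenario evaluation as a Monte Carlo model function.

    Outputs: total DPP, per-sex DPP totals, per-factor totals and the net
    expected deaths in the projection year.
    """

    def evaluate(params: EffectParameters) -> dict[str, float]:
        res = run_scenario(
            scenario, deaths_2010, risk_factors_2010, expected_2025, params,
            mix=mix, form=form,
        )
        out = {"total_dpp": res.total_dpp, "net_expected_2025": res.net_expected_2025}
        for sex, v in res.by_sex.items():
            out[f"dpp_{sex}"] = float(v)
        for factor, v in res.by_factor.items():
            out[f"dpp_{factor}"] = float(v)
        return out

    return evaluate


def sfa_sensitivity_sweep(
    deltas: list[float],
    sfa_baseline: dict[str, float],
    deaths_2010: pd.Series,
    risk_factors_2010: pd.DataFrame,
    expected_2025: pd.Series,
    params: EffectParameters,
    mix: ReplacementMix | None = None,
    form: str = "linear",
) -> pd.DataFrame:
    """Diet-only DPPs for a list of saturated-fat intake changes (E%).

    Each delta is applied to the per-sex baseline intakes with all other
    risk factors unchanged. Returns a tidy frame (delta, sex, age_band,
    dpp) whose totals are monotone in delta.
    """
    frames = []
    for delta in deltas:
        if not np.isfinite(delta):
            raise ValueError("saturated-fat deltas must be finite")
        # a uniform E% shift means per-sex targets baseline+delta, so each
        # sex is evaluated against its own target intake
        rows = []
        for sex, baseline in sfa_baseline.items():
            scen = Scenario(
                name=f"sfa{delta:+g}",
                target_sfa=baseline + delta,
                sfa_baseline={sex: baseline},
            )
            res = run_scenario(
                scen, deaths_2010, risk_factors_2010, expected_2025, params,
                mix=mix, form=form,
            )
            sel = res.dpp.index.get_level_values("sex") == sex
            rows.append(res.dpp.loc[sel, "cholesterol"].rename("dpp").reset_index())
        frame = pd.concat(rows, ignore_index=True)
        frame.insert(0, "delta_sfa", delta)
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)
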