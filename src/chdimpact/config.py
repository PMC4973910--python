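"""Run configuration and end-to-end pipeline orchestration.

A single structured config (YAML) drives the whole analysis: data source
(calibrated synthetic defaults or CSV inputs), model options (fit method,
regression form, replacement mix, hypertension prevalence), the scenario
list and the Monte Carlo block. All randomness flows from one top-level seed
expanded into per-module substreams.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import defaults as d
from .engine import Scenario, ScenarioResult, round_to_5, run_scenario
from .io import write_dpp_csv, write_mortality_csv, write_projection_csv
from .strata import strata_index
from .synthetic import EffectParameters
from .translate import ReplacementMix
from .trend import TrendFit, expected_deaths, fit_exponential_decay, project_rate, totals_by_sex
from .uncertainty import ParameterDistribution, monte_carlo, scenario_model


@dataclass
class MCConfig:
    enabled: bool = False
    n_draws: int = 10_000
    distributions: list[ParameterDistribution] = field(default_factory=list)


@dataclass
class RunConfig:
    """Validated options for one pipeline run."""

    seed: int | None = None
    noise: str = "none"  # synthetic mortality noise: none | poisson
    projection_year: int = d.PROJECTION_YEAR
    fit_method: str = "ols"  # ols | poisson
    regression_form: str = "linear"  # linear | loglinear
    continuity_correction: bool = False
    frac_pufa: float = 0.90
    hyp_prev: float = 0.37
    scenarios: list[Scenario] = field(default_factory=d.default_scenarios)
    mc: MCConfig = field(default_factory=MCConfig)
    outdir: Path | None = None

    def __post_init__(self) -> None:
        problems = []
        if self.noise not in ("none", "poisson"):
            problems.append(f"noise must be none|poisson, got {self.noise!r}")
        if self.fit_method not in ("ols", "poisson"):
            problems.append(f"fit_method must be ols|poisson, got {self.fit_method!r}")
        if self.regression_form not in ("linear", "loglinear"):
            problems.append(
                f"regression_form must be linear|loglinear, got {self.regression_form!r}"
            )
        if not 0 <= self.frac_pufa <= 1:
            problems.append(f"frac_pufa must lie in [0,1], got {self.frac_pufa}")
        if not 0 <= self.hyp_prev <= 1:
            problems.append(f"hyp_prev must lie in [0,1], got {self.hyp_prev}")
        if self.projection_year < d.BASE_YEAR:
            problems.append("projection_year precedes the base year")
        stochastic = self.noise == "poisson" or self.mc.enabled
        if stochastic and self.seed is None:
            problems.append("a seed is mandatory when any stochastic element is enabled")
        if problems:
            raise ValueError("invalid configuration:\n- " + "\n- ".join(problems))

    @property
    def mix(self) -> ReplacementMix:
        return ReplacementMix(self.frac_pufa, 1.0 - self.frac_pufa)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        scenarios = raw.pop("scenarios", None)
        mc_raw = raw.pop("mc", None)
        kwargs = dict(raw)
        if scenarios is not None:
            kwargs["scenarios"] = [
                s if isinstance(s, Scenario) else Scenario(**s) for s in scenarios
            ]
        if mc_raw is not None:
            dists = [
                ParameterDistribution(**spec)
                for spec in mc_raw.pop("distributions", [])
            ]
            kwargs["mc"] = MCConfig(distributions=dists, **mc_raw)
        if kwargs.get("outdir") is not None:
            kwargs["outdir"] = Path(kwargs["outdir"])
        valid = {f.name for f in dataclasses.fields(cls)}
        unknown = set(kwargs) - valid
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**kwargs)


@dataclass
class PipelineResult:
    config: RunConfig
    fits: dict[tuple[str, str], TrendFit]
    expected_2025: pd.Series
    constant_2025: pd.Series
    scenario_results: list[ScenarioResult]
    mc_intervals: dict[str, dict] = field(default_factory=dict)

    @property
    def baseline_total(self) -> float:
        return float(self.expected_2025.sum())

    @property
    def constant_total(self) -> float:
        return float(self.constant_2025.sum())

    @property
    def percent_decline(self) -> float:
        """Percent fewer baseline-scenario deaths than the constant-rate count."""
        return 100.0 * (1.0 - self.baseline_total / self.constant_total)

    def projection_frame(self) -> pd.DataFrame:
        year = self.config.projection_year
        rows = []
        for key in strata_index():
            fit = self.fits[key]
            rows.append(
                {
                    "sex": key[0],
                    "age_band": key[1],
                    "year": year,
                    "rate": project_rate(fit, year),
                    "expected_deaths": float(self.expected_2025[key]),
                }
            )
        return pd.DataFrame(rows)

    def dpp_frame(self) -> pd.DataFrame:
        return pd.concat([r.tidy() for r in self.scenario_results], ignore_index=True)


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full analysis: simulate, fit, project, run scenarios, MC."""
    baseline = d.calibrated_baseline()
    params = d.calibrated_effect_parameters(baseline)
    params.hyp_prev = config.hyp_prev

    seed = None
    if config.seed is not None:
        seed = int(np.random.SeedSequence(config.seed).generate_state(1)[0] % (2**31))
    series = d.default_mortality_series(baseline, noise=config.noise, seed=seed)
    write_series = series
    fits = {
        s.stratum.key: fit_exponential_decay(
            s, method=config.fit_method,
            continuity_correction=config.continuity_correction,
        )
        for s in series
    }
    expected = expected_deaths(fits, config.projection_year, baseline.pop_2025)
    constant = expected_deaths(
        fits, config.projection_year, baseline.pop_2025, constant_rate=True
    )

    deaths_2010 = pd.Series(
        {s.stratum.key: float(s.deaths[-1]) for s in series}
    ).reindex(strata_index())
    scenario_results = [
        run_scenario(
            scen,
            deaths_2010,
            baseline.risk_factors_2010,
            expected,
            params,
            mix=config.mix,
            form=config.regression_form,
        )
        for scen in config.scenarios
    ]

    mc_intervals: dict[str, dict] = {}
    if config.mc.enabled:
        mc_seed = int(
            np.random.SeedSequence([config.seed, 1]).generate_state(1)[0] % (2**31)
        )
        for scen in config.scenarios:
            model = scenario_model(
                scen, deaths_2010, baseline.risk_factors_2010, expected,
                mix=config.mix, form=config.regression_form,
            )
            mc_intervals[scen.name] = monte_carlo(
                model, params, config.mc.distributions,
                n_draws=config.mc.n_draws, seed=mc_seed,
            )

    result = PipelineResult(
        config=config,
        fits=fits,
        expected_2025=expected,
        constant_2025=constant,
        scenario_results=scenario_results,
        mc_intervals=mc_intervals,
    )

    if config.outdir is not None:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_mortality_csv(write_series, outdir / "mortality_series.csv")
        write_projection_csv(result.projection_frame(), outdir / "projection.csv")
        write_dpp_csv(result.dpp_frame(), outdir / "dpp.csv")
        (outdir / "summary.md").write_text(render_summary(result))
    return result


def render_summary(result: PipelineResult) -> str:
    """Markdown report: baseline projection and per-scenario DPP tables.

    Percentages are computed from raw (unrounded) DPPs against the baseline
    expected deaths, then rounded to one decimal for display; death counts
    are shown rounded to the nearest 5.
    """
    lines = ["# CHD mortality projection summary", ""]
    by_sex = totals_by_sex(result.expected_2025)
    lines += [
        f"Projection year: {result.config.projection_year}",
        "",
        f"- Baseline expected deaths (continuing decline): "
        f"{result.baseline_total:.0f} "
        f"(men {by_sex['male']:.0f}, women {by_sex['female']:.0f})",
        f"- Constant-rate counterfactual: {result.constant_total:.0f}",
        f"- Decline versus constant rates: {result.percent_decline:.0f}%",
        "",
    ]
    for res in result.scenario_results:
        lines.append(f"## Scenario: {res.scenario.name}")
        lines.append("")
        lines.append(
            f"Regression form: {res.regression_form}; cholesterol change "
            f"(mmol/L): " + ", ".join(
                f"{s} {v:+.2f}" for s, v in res.chol_delta.items()
            ) + f"; SBP change {res.sbp_delta:+.2f} mm Hg"
        )
        lines.append("")
        lines.append("| factor | men | women | total |")
        lines.append("|---|---|---|---|")
        for factor in res.dpp.columns:
            per_sex = res.dpp[factor].groupby(level="sex", sort=False).sum()
            lines.append(
                f"| {factor} | {round_to_5(per_sex['male'])} "
                f"| {round_to_5(per_sex['female'])} "
                f"| {round_to_5(float(res.dpp[factor].sum()))} |"
            )
        sex_tot = res.by_sex
        lines.append(
            f"| **total** | {round_to_5(sex_tot['male'])} "
            f"| {round_to_5(sex_tot['female'])} "
            f"| {round_to_5(res.total_dpp)} |"
        )
        pct_change = -100.0 * res.total_dpp / result.baseline_total
        lines.append("")
        lines.append(
            f"Total DPP {round_to_5(res.total_dpp)} "
            f"({pct_change:+.1f}% change in expected deaths); net expected deaths "
            f"{res.net_expected_2025:.0f}."
        )
        if res.scenario.name in result.mc_intervals:
            ui = result.mc_intervals[res.scenario.name]["total_dpp"]
            lines.append(
                f"95% uncertainty interval for total DPP: "
                f"[{ui.low:.0f}, {ui.high:.0f}] ({ui.n_draws} draws)."
            )
        lines.append("")
    return "\n".join(lines)
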