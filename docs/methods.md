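# Methods

## Scope and structure

`chdimpact` projects coronary heart disease (CHD) mortality for a population
aged 25–84, stratified by sex and six closed 10-year age bands (twelve
strata), from a 2010 base year to 2025. It implements the risk-factor arm of
an IMPACT-style comparative risk assessment: baseline trend extrapolation,
translation of dietary exposures into intermediate risk factors, deaths
prevented or postponed (DPP) accounting, and Monte Carlo uncertainty. The
medical-treatment arm of such models, life-years gained, competing risks and
direct BMI/diabetes terms are out of scope (the last two are regarded as
absorbed into the observed mortality trend).

## Baseline trend model

Each stratum's age-specific mortality rate is assumed to decline
exponentially, rate(t) = rate_ref · exp(−λ(t − t_ref)). The default fit is
ordinary least squares of log(rate) on calendar year over 1986–2010, which
corresponds to exponential decay with multiplicative error and weights all
years equally. A deaths-weighted alternative — Poisson regression of counts
with a log link and log-population offset — sits behind
`fit_exponential_decay(..., method="poisson")`; on the package's synthetic
series the two agree closely because counts are large and the trend is
log-linear by construction. The reference year is the last observed year
(2010), so the fitted 2010 rate anchors all projections. λ is constrained to
the model's sign convention only at generation time (the generator refuses
negative decay); the fitter itself will report a negative λ if the data
trend upward, which the projection then propagates — flat or rising strata
are visible rather than silently clipped.

Zero death counts make log-rates undefined. The default is to raise with an
instruction rather than correct silently; with
`continuity_correction=True`, 0.5 is added to the count in the affected
years only. Fewer than three observed years is an error.

Expected deaths in the projection year are projected rate × projected
population per stratum; the constant-rate counterfactual uses the 2010
fitted rate unchanged. Totals are exact sums of unrounded stratum values.

## Diet translation

Saturated fat (SFA) → total cholesterol uses metabolic-ward metaregression
coefficients for isocaloric replacement: 0.078 mmol/L per E% replaced by
polyunsaturated fat, 0.048 by monounsaturated, combined by the replacement
mix (default 90/10), giving 0.075 mmol/L per E%. A figure of "0.3 mmol/L
per 1 E%" circulates for this combination, but the formula itself evaluates
to 0.075, and 0.075 is the value consistent with every downstream per-sex
cholesterol delta the package reproduces (0.44/0.33 mmol/L for the low-fat
scenario, 0.19/0.30 for the high-fat one); the package therefore uses the
computed 0.075. Linearity is assumed within 10–20 E%; outside that range the
function warns and extrapolates.

Salt → systolic blood pressure (SBP) uses trial-metaregression effects of a
6 g/day salt reduction — 7.2 mm Hg in hypertensive, 3.6 mm Hg in
normotensive people — weighted by a hypertension prevalence of 0.37 that is
held constant over the forecast period: 0.822 mm Hg per 1 g/day at the
default. With prevalence 0 or 1 the translation collapses to the pure
normotensive/hypertensive effects.

Both translations are exactly linear and sign-preserving by construction.

## DPP accounting

Continuous factors (cholesterol, SBP) use the regression approach applied
to observed 2010 deaths: DPP = D_2010 · |Δ| · β, with β the stratum-specific
proportional mortality change per unit. The default form is this linear
product; the classical log-linear form D·(1 − e^(−β|Δ|)) is available via
`form="loglinear"` and never exceeds the linear magnitude. Binary factors
(smoking, physical inactivity) use the PARF difference applied to 2025
expected deaths: DPP = E_2025 · [PARF(p_2010) − PARF(p_2025)], with
PARF = p(RR−1)/(1+p(RR−1)). That continuous and binary factors multiply
different base-year deaths follows the source procedure literally; it is
asymmetric, and is kept because recalibrating either side would change the
published anchors the defaults reproduce.

Scenario prevalence deltas are absolute percentage-point changes applied
uniformly to every stratum and floored at zero prevalence (a −5 pp change
to a 6% stratum leaves 1%); a delta that would push prevalence above 1
raises an error naming the stratum. Factors are treated as independent and
additive — no interaction or mediation adjustment — so the scenario total
is exactly the sum of per-stratum, per-factor contributions.

Rounding to the nearest 5 deaths (ties away from zero) is applied only when
reporting; all sums and percentages use raw values. Stratum-level rounding
followed by summation is not reproducible against any fixed total, which is
why raw-sum accounting is the package's single convention.

## Synthetic inputs and calibration

No stratum-level registry counts or effect-coefficient tables are publicly
available for the motivating analysis, so the package generates them:

* **Mortality series.** Twelve exponentially declining rate series with
  either deterministic (rounded expected counts) or Poisson noise.
  Hand-chosen 2010 rates and decline speeds, plausible for a Western
  European population of ~9.5 M (steep age gradient, male excess,
  3.5–5%/year declines), are rescaled by deterministic root-finding
  (`scipy.optimize.brentq`) so that the closed-form projection reproduces
  the published aggregate anchors: 4,010 (men) and 1,965 (women) expected
  deaths in 2025 and 11,000 at constant rates. The calibrated 2010 total is
  ~8,740 deaths. Historical stratum populations ramp linearly from 88% of
  the 2010 value in 1986.

* **Effect parameters.** Two routes. `generate_effect_parameters(seed)`
  draws seeded plausible stand-ins (positive betas attenuating with age,
  relative risks above 1) for property testing.
  `calibrated_effect_parameters()` keeps the age profiles fixed and solves
  one multiplicative level per sex and factor so the low-fat scenario's
  per-factor sex totals equal the published values (cholesterol 300/130,
  salt 90/50, smoking 90/60, inactivity 60/30 for men/women). The PARF
  solve brackets the smallest root because the PARF difference is
  non-monotone in the excess risk (it saturates). Uncertainty is attached
  as 12% proportional standard errors on betas and ±0.15 log-scale 95%
  confidence intervals on relative risks — stand-ins, since the true
  sampling distributions are unavailable.

* **Risk factors.** The 2010 stratum-level survey table (cholesterol, SBP,
  smoking, inactivity, diabetes, BMI) and the 1986/2002/2010 sex-level
  summaries are the published values, embedded exactly. Per-sex baseline
  saturated-fat intakes are reverse-engineered calibration fixtures:
  15.9/14.4 E% (men/women) for the low-fat scenario and 17.5/16.0 E% for
  the high-fat one, each chosen so the published cholesterol deltas emerge
  from the 0.075 mmol/L-per-E% translation; both are overridable per
  scenario.

What the synthetic data do **not** emulate: cohort effects or trend breaks
(each stratum has a single log-linear trend), migration or cohort ageing in
the population ramp, correlation between risk factors, measurement error in
surveys, and any real-registry idiosyncrasies (ICD coding changes, late
registrations). Passing tests therefore demonstrate the machinery's
correctness and internal consistency under the stated model — not that the
model describes any real population.

Because the engine is linear in the cholesterol delta, the calibrated
defaults cannot simultaneously match published low-fat *and* high-fat
cholesterol DPPs (the published pairs are not proportional to their
deltas); calibration targets the low-fat scenario, and the high-fat
scenario's outputs are the engine's own linear consequences.

## Monte Carlo uncertainty

Parameter uncertainty is propagated by redrawing effect parameters and
re-running the full scenario evaluation per draw: normal on the coefficient
scale for betas (per-stratum standard errors), lognormal for relative risks
(sigma from the log-width of the 95% CI), point (degenerate) otherwise.
Draws are i.i.d. across parameters and iterations; no correlation structure
is modelled. Intervals are empirical 2.5th/97.5th percentiles. By default
only effect parameters are sampled — risk-factor levels are treated as
known. All randomness flows from a single top-level seed expanded via
`numpy.random.SeedSequence` substreams, so identical configurations give
bitwise-identical outputs.

Default problem sizes: 10,000 draws for standalone interval estimation;
the packaged analysis drivers and the end-to-end reproduction script use
2,000 draws per scenario, at which the interval endpoints for the scenario
totals are stable to within a few deaths.

## Numerical choices and degenerate inputs

* Rounding ties (x.5 on the 5-death grid) go away from zero.
* Regional survey weighting validates weights to 1 within 1e-9.
* PARF accepts RR < 1 (protective) with a warning and a negative value;
  the engine suppresses that warning internally because protective draws
  arise legitimately under Monte Carlo perturbation.
* Calibration root-finds with xtol 1e-12; the resulting anchors are exact
  to ~1e-9 deaths.
* The noise-free generator rounds expected counts to integers (death counts
  are counts), which perturbs the fitted baseline total by a few deaths of
  5,975; the tests allow for this.

## Known limitations

Single-trend extrapolation over 15 years ignores trend breaks; the
regression and PARF arms use different base-year deaths (see above);
behavioural DPPs are identical across diet scenarios by construction, so a
published behavioural total that differs between scenarios cannot be
matched by this engine; and all headline absolute counts inherit the
calibration, so only the printed aggregate anchors — not independent
registry data — support them.
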