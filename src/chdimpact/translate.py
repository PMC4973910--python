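"""Diet-to-risk-factor translation equations.

Saturated-fat intake changes are translated into total-cholesterol changes
using metabolic-ward metaregression coefficients for isocaloric replacement
of saturated fat by polyunsaturated (0.078 mmol/L per E%) or monounsaturated
(0.048 mmol/L per E%) fat; the replacement mix defaults to 90% PUFA / 10%
MUFA, giving 0.075 mmol/L per E% (note this rounds to 0.08, not the 0.3
occasionally quoted). Salt-intake changes are translated into systolic blood
pressure changes via trial-metaregression effects of a 6 g/day reduction —
7.2 mm Hg in hypertensive and 3.6 mm Hg in normotensive people — weighted by
the national hypertension prevalence (37%, held constant over the forecast
period). Both translations are exactly linear and sign-preserving.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .synthetic import EffectParameters

#: Linearity range (E%) within which the saturated-fat equation is supported.
SFA_LINEAR_RANGE = (10.0, 20.0)


@dataclass(frozen=True)
class ReplacementMix:
    """How replaced saturated-fat energy is split between PUFA and MUFA."""

    frac_pufa: float = 0.90
    frac_mufa: float = 0.10

    def __post_init__(self) -> None:
        if not (0 <= self.frac_pufa <= 1 and 0 <= self.frac_mufa <= 1):
            raise ValueError("replacement fractions must lie in [0,1]")
        if abs(self.frac_pufa + self.frac_mufa - 1.0) > 1e-9:
            raise ValueError(
                f"replacement fractions must sum to 1, got "
                f"{self.frac_pufa + self.frac_mufa}"
            )


def cholesterol_per_epct(mix: ReplacementMix, params: EffectParameters) -> float:
    """mmol/L total-cholesterol change per 1 E% saturated-fat change."""
    return params.clarke_pufa * mix.frac_pufa + params.clarke_mufa * mix.frac_mufa


def sfa_delta_to_cholesterol_delta(
    delta_sfa: float,
    mix: ReplacementMix,
    params: EffectParameters,
    sfa_level: float | None = None,
) -> float:
    """Translate a signed saturated-fat change (E%) into mmol/L cholesterol.

    If ``sfa_level`` (the resulting intake) is given and falls outside the
    supported linearity range, a warning is issued but the linear value is
    still returned.
    """
    if sfa_level is not None and not (
        SFA_LINEAR_RANGE[0] <= sfa_level <= SFA_LINEAR_RANGE[1]
    ):
        warnings.warn(
            f"saturated-fat level {sfa_level} E% outside the supported "
            f"linearity range {SFA_LINEAR_RANGE}; extrapolating linearly",
            stacklevel=2,
        )
    return delta_sfa * cholesterol_per_epct(mix, params)


def salt_delta_to_sbp_delta(delta_salt: float, params: EffectParameters) -> float:
    """Translate a signed salt change (g/day) into mm Hg systolic pressure.

    Hypertension-prevalence-weighted average of the hypertensive and
    normotensive per-6-g effects; at the default 37% prevalence a 1 g/day
    reduction lowers population SBP by 0.822 mm Hg.
    """
    if not 0 <= params.hyp_prev <= 1:
        raise ValueError("hypertension prevalence must be in [0,1]")
    per_gram = (
        params.salt_sbp_hyp * params.hyp_prev
        + params.salt_sbp_norm * (1.0 - params.hyp_prev)
    ) / 6.0
    return delta_salt * per_gram


def scenario_cholesterol_delta(
    baseline_sfa: dict[str, float],
    target_sfa: float,
    mix: ReplacementMix,
    params: EffectParameters,
) -> dict[str, float]:
    """Per-sex cholesterol change (mmol/L) when intake moves to ``target_sfa``."""
    out = {}
    for sex, baseline in baseline_sfa.items():
        if not (0 < baseline < 40 and 0 < target_sfa < 40):
            raise ValueError("saturated-fat intakes must lie in (0, 40) E%")
        out[sex] = sfa_delta_to_cholesterol_delta(
            target_sfa - baseline, mix, params, sfa_level=target_sfa
        )
    return out
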