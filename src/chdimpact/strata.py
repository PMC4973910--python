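"""Population strata: sex × 10-year age band, the model's universal indexing unit.

The projection covers adults aged 25–84 split into six closed 10-year bands
per sex, giving exactly twelve strata. Age bands are carried as labelled
categories rather than numeric edges so that band membership is never subject
to 0/1-based boundary ambiguity.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

SEXES: tuple[str, str] = ("male", "female")

AGE_BANDS: tuple[str, ...] = ("25-34", "35-44", "45-54", "55-64", "65-74", "75-84")


@dataclass(frozen=True, order=True)
class Stratum:
    """One cell of the model: a sex and a closed 10-year age band."""

    sex: str
    age_band: str

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"unknown sex {self.sex!r}; expected one of {SEXES}")
        if self.age_band not in AGE_BANDS:
            raise ValueError(
                f"unknown age band {self.age_band!r}; expected one of {AGE_BANDS}"
            )

    @property
    def key(self) -> tuple[str, str]:
        return (self.sex, self.age_band)


def all_strata() -> list[Stratum]:
    """The twelve strata in canonical (sex, age) order."""
    return [Stratum(s, a) for s in SEXES for a in AGE_BANDS]


def strata_index() -> pd.MultiIndex:
    """Canonical pandas MultiIndex over (sex, age_band)."""
    return pd.MultiIndex.from_product([SEXES, AGE_BANDS], names=["sex", "age_band"])


def require_all_strata(index: pd.Index, what: str = "input") -> None:
    """Raise if any of the twelve strata is missing from ``index``."""
    missing = [k for k in strata_index() if k not in index]
    if missing:
        labels = ", ".join(f"{s}/{a}" for s, a in missing)
        raise ValueError(f"{what} is missing strata: {labels}")
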