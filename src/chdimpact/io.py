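"""CSV schemas and round-trip readers/writers for the pipeline artifacts."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .strata import Stratum
from .synthetic import MortalitySeries

MORTALITY_COLUMNS = ["sex", "age_band", "year", "population", "deaths", "rate"]
PROJECTION_COLUMNS = ["sex", "age_band", "year", "rate", "expected_deaths"]
DPP_COLUMNS = ["scenario", "sex", "age_band", "factor", "dpp_raw", "dpp_rounded"]


def write_mortality_csv(series: list[MortalitySeries], path: str | Path) -> None:
    frame = pd.concat([s.to_frame() for s in series], ignore_index=True)
    frame[MORTALITY_COLUMNS].to_csv(path, index=False)


def read_mortality_csv(path: str | Path) -> list[MortalitySeries]:
    frame = pd.read_csv(path)
    missing = set(MORTALITY_COLUMNS[:-1]) - set(frame.columns)
    if missing:
        raise ValueError(f"mortality CSV {path} lacks columns: {sorted(missing)}")
    out = []
    for (sex, band), grp in frame.groupby(["sex", "age_band"], sort=False):
        grp = grp.sort_values("year")
        out.append(
            MortalitySeries(
                stratum=Stratum(sex, band),
                years=grp["year"].to_numpy(),
                deaths=grp["deaths"].to_numpy(),
                population=grp["population"].to_numpy(),
            )
        )
    return out


def write_projection_csv(projection: pd.DataFrame, path: str | Path) -> None:
    projection[PROJECTION_COLUMNS].to_csv(path, index=False)


def write_dpp_csv(tidy: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in DPP_COLUMNS if c in tidy.columns]
    extra = [c for c in tidy.columns if c not in cols]
    tidy[cols + extra].to_csv(path, index=False)


def read_stratum_series_csv(path: str | Path, value_columns: list[str]) -> pd.DataFrame:
    """Read a per-stratum CSV into a (sex, age_band)-indexed frame."""
    frame = pd.read_csv(path)
    missing = {"sex", "age_band", *value_columns} - set(frame.columns)
    if missing:
        raise ValueError(f"{path} lacks columns: {sorted(missing)}")
    return frame.set_index(["sex", "age_band"])[value_columns]
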