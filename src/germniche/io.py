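"""Readers and writers for the long-format CSV schemas used throughout.

Counts CSV:   population,stage,temp_c,replicate,day,germinated,total
Params CSV:   population,storage_month,stage,Tl50,sigma_Tl,Th50,sigma_Th,
              theta_sub50,sigma_sub,theta_sup50,sigma_sup,R2
Climate CSV:  month,mean_temp_c
Cardinals:    YAML mapping population -> {Tb, To, Tm}
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Dict, List, Mapping, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .types import (
    STAGES,
    CardinalTemps,
    ClimateSeries,
    GerminationTimeCourse,
    StageParams,
    ThermalTimeParams,
    ThermalWindow,
)

__all__ = [
    "read_counts",
    "write_counts",
    "read_params",
    "write_params",
    "read_climate",
    "write_climate",
    "read_cardinals",
    "load_table1",
    "load_table2_expected",
]

PathLike = Union[str, Path]

COUNTS_COLUMNS = ["population", "stage", "temp_c", "replicate", "day", "germinated", "total"]
PARAMS_COLUMNS = [
    "population", "storage_month", "stage", "Tl50", "sigma_Tl", "Th50", "sigma_Th",
    "theta_sub50", "sigma_sub", "theta_sup50", "sigma_sup", "R2",
]

STAGE_MONTHS = {"D": 0, "M": 0, "AR1": 1, "AR2": 2, "AR5": 5}


class CountsFormatError(ValueError):
    """Malformed or inconsistent germination-census table."""


def read_counts(path: PathLike) -> List[GerminationTimeCourse]:
    """Parse a long-format census CSV into per-dish time-courses.

    Validates the schema, count ranges and cumulative monotonicity,
    naming the offending CSV row on failure.
    """
    df = pd.read_csv(path)
    missing = [c for c in COUNTS_COLUMNS if c not in df.columns]
    if missing:
        raise CountsFormatError(f"{path}: missing columns {missing}")
    if df.empty:
        raise CountsFormatError(f"{path}: no census rows")

    df = df.copy()
    df["_row"] = df.index + 2  # header is line 1
    for col in ("temp_c", "day", "germinated", "total"):
        bad = df[pd.to_numeric(df[col], errors="coerce").isna()]
        if not bad.empty:
            raise CountsFormatError(
                f"{path} row {int(bad['_row'].iloc[0])}: non-numeric value in column {col!r}"
            )
        df[col] = pd.to_numeric(df[col])

    over = df[(df["germinated"] < 0) | (df["germinated"] > df["total"])]
    if not over.empty:
        raise CountsFormatError(
            f"{path} row {int(over['_row'].iloc[0])}: germinated count outside [0, total]"
        )
    unknown = df[~df["stage"].isin(STAGES)]
    if not unknown.empty:
        raise CountsFormatError(
            f"{path} row {int(unknown['_row'].iloc[0])}: "
            f"unknown stage {unknown['stage'].iloc[0]!r}"
        )

    out: List[GerminationTimeCourse] = []
    keys = ["population", "stage", "temp_c", "replicate"]
    for (pop, stage, temp, rep), grp in df.groupby(keys, sort=True):
        grp = grp.sort_values("day")
        counts = grp["germinated"].to_numpy(dtype=float)
        if np.any(np.diff(counts) < 0):
            bad_row = int(grp["_row"].to_numpy()[np.argmax(np.diff(counts) < 0) + 1])
            raise CountsFormatError(
                f"{path} row {bad_row}: cumulative germinated count decreases"
            )
        totals = grp["total"].unique()
        if len(totals) != 1:
            raise CountsFormatError(
                f"{path} row {int(grp['_row'].iloc[0])}: dish total changes across days"
            )
        total = int(totals[0])
        frac = counts / total if total > 0 else counts * 0.0
        out.append(
            GerminationTimeCourse(
                temperature=float(temp),
                days=grp["day"].to_numpy(dtype=float),
                cum_fraction=frac,
                n_seeds=total,
                replicate=str(rep),
                population=str(pop),
                stage=str(stage),
            )
        )
    return out


def write_counts(timecourses: Sequence[GerminationTimeCourse], path: PathLike) -> None:
    rows = []
    for tc in timecourses:
        for day, frac in zip(tc.days, tc.cum_fraction):
            rows.append(
                {
                    "population": tc.population,
                    "stage": tc.stage,
                    "temp_c": tc.temperature,
                    "replicate": tc.replicate,
                    "day": day,
                    "germinated": int(round(frac * tc.n_seeds)),
                    "total": tc.n_seeds,
                }
            )
    pd.DataFrame(rows, columns=COUNTS_COLUMNS).to_csv(path, index=False)


def params_to_frame(params: Sequence[StageParams]) -> pd.DataFrame:
    rows = []
    for p in params:
        rows.append(
            {
                "population": p.population,
                "storage_month": STAGE_MONTHS.get(p.stage, ""),
                "stage": p.stage,
                "Tl50": p.window.Tl50,
                "sigma_Tl": p.window.sigma_Tl,
                "Th50": p.window.Th50,
                "sigma_Th": p.window.sigma_Th,
                "theta_sub50": p.timing.theta_sub50,
                "sigma_sub": p.timing.sigma_sub,
                "theta_sup50": p.timing.theta_sup50,
                "sigma_sup": p.timing.sigma_sup,
                "R2": p.r2 if p.r2 is not None else np.nan,
            }
        )
    return pd.DataFrame(rows, columns=PARAMS_COLUMNS)


def write_params(params: Sequence[StageParams], path: PathLike) -> None:
    params_to_frame(params).to_csv(path, index=False)


def frame_to_params(
    df: pd.DataFrame, cardinals: Mapping[str, CardinalTemps]
) -> List[StageParams]:
    out = []
    for _, row in df.iterrows():
        pop = str(row["population"])
        if pop not in cardinals:
            raise KeyError(f"no cardinal temperatures configured for population {pop!r}")
        r2 = row.get("R2")
        out.append(
            StageParams(
                population=pop,
                stage=str(row["stage"]),
                window=ThermalWindow(
                    float(row["Tl50"]), float(row["sigma_Tl"]),
                    float(row["Th50"]), float(row["sigma_Th"]),
                ),
                timing=ThermalTimeParams(
                    float(row["theta_sub50"]), float(row["sigma_sub"]),
                    float(row["theta_sup50"]), float(row["sigma_sup"]),
                ),
                cardinals=cardinals[pop],
                r2=None if r2 is None or pd.isna(r2) else float(r2),
            )
        )
    return out


def read_params(path: PathLike, cardinals: Mapping[str, CardinalTemps]) -> List[StageParams]:
    df = pd.read_csv(path)
    missing = [c for c in PARAMS_COLUMNS if c not in df.columns and c != "storage_month"]
    if missing:
        raise ValueError(f"{path}: missing parameter columns {missing}")
    return frame_to_params(df, cardinals)


def read_climate(path: PathLike) -> ClimateSeries:
    df = pd.read_csv(path)
    for col in ("month", "mean_temp_c"):
        if col not in df.columns:
            raise ValueError(f"{path}: climate CSV needs columns month, mean_temp_c")
    return ClimateSeries(
        months=[int(m) for m in df["month"]],
        mean_temp=[float(t) for t in df["mean_temp_c"]],
    )


def write_climate(climate: ClimateSeries, path: PathLike) -> None:
    pd.DataFrame({"month": climate.months, "mean_temp_c": climate.mean_temp}).to_csv(
        path, index=False
    )


def read_cardinals(path: PathLike) -> Dict[str, CardinalTemps]:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: cardinals YAML must map population -> {{Tb, To, Tm}}")
    out = {}
    for pop, vals in raw.items():
        try:
            out[str(pop)] = CardinalTemps(float(vals["Tb"]), float(vals["To"]), float(vals["Tm"]))
        except (KeyError, TypeError) as exc:
            raise ValueError(f"{path}: population {pop!r} needs Tb, To and Tm") from exc
    return out


def _load_packaged(name: str) -> pd.DataFrame:
    with resources.files("germniche.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


def load_table1() -> pd.DataFrame:
    """Published per-stage population parameters shipped as a fixture."""
    return _load_packaged("table1.csv")


def load_table2_expected() -> pd.DataFrame:
    """Published niche-widening regression results shipped as a fixture."""
    return _load_packaged("table2_expected.csv")
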