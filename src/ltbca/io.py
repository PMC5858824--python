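"""CSV and YAML readers/writers with strict schemas.

All numeric CSV output relies on Python's shortest-repr float formatting,
so reading a file back reproduces the in-memory values exactly.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .incidence import IncidencePoint
from .screening import ScreeningBehavior, SurveyBin

INCIDENCE_COLUMNS = ["age_lo", "age_hi", "rate_per_100k", "period"]
SCREENING_COLUMNS = ["stratum", "period", "age_lo", "age_hi", "k1", "k2"]
WEIGHTS_COLUMNS = ["stratum", "age_stratum", "weight"]
SURVEY_COLUMNS = [
    "stratum", "period", "age_lo", "age_hi",
    "n_total", "n_screened_1", "n_screened_2plus", "window_years",
]


class SchemaError(ValueError):
    """Raised when a CSV does not match its schema."""


def _fmt_float(value) -> str:
    """Shortest decimal repr that round-trips the double exactly."""
    return repr(float(value))


def _check_columns(df: pd.DataFrame, expected: list[str], path) -> None:
    if list(df.columns) != expected:
        raise SchemaError(
            f"{path}: expected columns {expected}, found {list(df.columns)}"
        )


def read_incidence_csv(path: str | Path) -> list[IncidencePoint]:
    df = pd.read_csv(path, float_precision="round_trip")
    _check_columns(df, INCIDENCE_COLUMNS, path)
    return [
        IncidencePoint(
            age_lo=float(r.age_lo), age_hi=float(r.age_hi),
            rate=float(r.rate_per_100k), period=str(r.period),
        )
        for r in df.itertuples()
    ]


def write_incidence_csv(df: pd.DataFrame, path: str | Path) -> None:
    _check_columns(df[INCIDENCE_COLUMNS], INCIDENCE_COLUMNS, path)
    df[INCIDENCE_COLUMNS].to_csv(path, index=False, float_format=_fmt_float)


def read_screening_csv(path: str | Path) -> dict[tuple[str, str], ScreeningBehavior]:
    """One step-function behavior per (stratum, period), bins sorted by age."""
    df = pd.read_csv(path, float_precision="round_trip")
    _check_columns(df, SCREENING_COLUMNS, path)
    behaviors: dict[tuple[str, str], ScreeningBehavior] = {}
    for (stratum, period), grp in df.groupby(["stratum", "period"], sort=False):
        grp = grp.sort_values("age_lo")
        edges = list(grp["age_lo"].astype(float))
        his = list(grp["age_hi"].astype(float))
        for lo, hi in zip(edges[1:], his[:-1]):
            if abs(lo - hi) > 1e-12:
                raise SchemaError(
                    f"{path}: non-contiguous bins for stratum={stratum} period={period}"
                )
        behaviors[(str(stratum), str(period))] = ScreeningBehavior(
            stratum=str(stratum), period=str(period),
            edges=tuple(edges + [his[-1]]),
            k1=tuple(grp["k1"].astype(float)),
            k2=tuple(grp["k2"].astype(float)),
        )
    return behaviors


def write_screening_csv(df: pd.DataFrame, path: str | Path) -> None:
    _check_columns(df[SCREENING_COLUMNS], SCREENING_COLUMNS, path)
    df[SCREENING_COLUMNS].to_csv(path, index=False, float_format=_fmt_float)


def read_weights_csv(path: str | Path) -> dict[str, dict[str, float]]:
    """stratum -> {age_stratum_label: weight}; key 'all' means shared."""
    df = pd.read_csv(path, float_precision="round_trip")
    _check_columns(df, WEIGHTS_COLUMNS, path)
    out: dict[str, dict[str, float]] = {}
    for r in df.itertuples():
        out.setdefault(str(r.stratum), {})[str(r.age_stratum)] = float(r.weight)
    return out


def write_weights_csv(df: pd.DataFrame, path: str | Path) -> None:
    _check_columns(df[WEIGHTS_COLUMNS], WEIGHTS_COLUMNS, path)
    df[WEIGHTS_COLUMNS].to_csv(path, index=False, float_format=_fmt_float)


def read_survey_csv(path: str | Path) -> dict[tuple[str, str], list[SurveyBin]]:
    df = pd.read_csv(path, float_precision="round_trip")
    _check_columns(df, SURVEY_COLUMNS, path)
    out: dict[tuple[str, str], list[SurveyBin]] = {}
    for r in df.itertuples():
        out.setdefault((str(r.stratum), str(r.period)), []).append(
            SurveyBin(
                age_lo=float(r.age_lo), age_hi=float(r.age_hi),
                n_total=int(r.n_total), n_screened_1=int(r.n_screened_1),
                n_screened_2plus=int(r.n_screened_2plus),
                window_years=float(r.window_years),
            )
        )
    return out


def write_scenario_yaml(scenario_dict: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(scenario_dict, fh, sort_keys=False)


def read_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise SchemaError(f"{path}: expected a mapping at the top level")
    return data
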