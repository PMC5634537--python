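"""Readers and writers for the four pipeline CSV schemas plus result JSON.

All tabular inputs are RFC-4180 CSV (UTF-8), dates ISO-8601, categorical
codes lowercase snake_case.  Readers validate types and closed categorical
sets and report the offending rows; a write -> read round trip is the
identity on the validated columns.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .filters import FLAG_COLUMNS, MECHANISMS
from .synthetic import INVESTIGATOR_LEVELS, URBANICITY_LEVELS, SimulationResult

__all__ = [
    "read_incidents",
    "read_mortality",
    "read_monthly_counts",
    "read_counties",
    "write_incidents",
    "write_mortality",
    "write_monthly_counts",
    "write_counties",
    "write_simulation",
    "write_json",
]

GENDERS = {"man", "woman", "missing"}
RACE_ETHNICITY = {"black", "white", "hispanic", "aian", "api", "missing"}

SCHEMA_VERSION = "1"


def _require(df: pd.DataFrame, columns, path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")


def _check_levels(df: pd.DataFrame, column: str, allowed, path, allow_na=False) -> None:
    values = df[column]
    bad = ~values.isin(list(allowed))
    if allow_na:
        bad &= ~values.isna()
    if bad.any():
        rows = df.index[bad].tolist()[:5]
        raise ValueError(
            f"{path}: column {column!r} has values outside {sorted(map(str, allowed))} at rows {rows}"
        )


def read_incidents(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"record_id": str, "state": str, "county_id": str})
    _require(
        df,
        ["record_id", "given_name", "surname", "age", "gender", "race_ethnicity",
         "injury_date", "state", "county_id", "mechanism"],
        path,
    )
    _check_levels(df, "mechanism", MECHANISMS, path)
    _check_levels(df, "gender", GENDERS, path, allow_na=True)
    _check_levels(df, "race_ethnicity", RACE_ETHNICITY, path, allow_na=True)
    df["injury_date"] = pd.to_datetime(df["injury_date"], format="ISO8601")
    for flag in FLAG_COLUMNS + ("external_confirmation",):
        if flag in df.columns:
            df[flag] = df[flag].fillna(False).astype(bool)
        else:
            df[flag] = False
    return df


def write_incidents(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["injury_date"] = pd.to_datetime(out["injury_date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def read_mortality(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"record_id": str, "death_state": str, "multiple_causes": str})
    _require(
        df,
        ["record_id", "given_name", "surname", "birth_year", "death_date",
         "death_state", "underlying_cause", "multiple_causes"],
        path,
    )
    if df["record_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate mortality record ids")
    df["death_date"] = pd.to_datetime(df["death_date"], format="ISO8601")
    df["birth_year"] = df["birth_year"].astype(int)
    causes = df["multiple_causes"].str.split(";")
    n_codes = causes.map(len)
    if (n_codes < 1).any() or (n_codes > 20).any():
        raise ValueError(f"{path}: multiple_causes must list 1-20 codes")
    underlying_in = [u in c for u, c in zip(df["underlying_cause"], causes)]
    if not all(underlying_in):
        rows = [i for i, ok in enumerate(underlying_in) if not ok][:5]
        raise ValueError(f"{path}: underlying cause missing from multiple causes at rows {rows}")
    return df


def write_mortality(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["death_date"] = pd.to_datetime(out["death_date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def read_monthly_counts(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, ["year", "month", "count"], path)
    if sorted(df["month"].astype(int)) != list(range(1, 13)):
        raise ValueError(f"{path}: monthly counts must cover months 1-12 exactly once")
    if (df["count"].astype(int) < 0).any():
        raise ValueError(f"{path}: negative monthly count")
    return df.astype({"year": int, "month": int, "count": int}).sort_values("month").reset_index(drop=True)


def write_monthly_counts(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_counties(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"county_id": str, "state_id": str})
    _require(df, ["county_id", "state_id", "income_quintile", "urbanicity", "investigator_type"], path)
    if df["county_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate county ids")
    df["income_quintile"] = df["income_quintile"].astype(int)
    if not df["income_quintile"].between(1, 5).all():
        raise ValueError(f"{path}: income_quintile outside 1..5")
    _check_levels(df, "urbanicity", URBANICITY_LEVELS, path)
    _check_levels(df, "investigator_type", INVESTIGATOR_LEVELS, path)
    return df


def write_counties(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def write_json(obj, path) -> None:
    """Deterministic JSON: sorted keys, numpy scalars unwrapped."""

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=default) + "\n")


def write_simulation(result: SimulationResult, outdir) -> dict[str, str]:
    """Write the four pipeline input CSVs plus the truth JSON; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "incidents": str(outdir / "incidents.csv"),
        "mortality": str(outdir / "mortality.csv"),
        "monthly_counts": str(outdir / "monthly_counts.csv"),
        "counties": str(outdir / "counties.csv"),
        "truth": str(outdir / "truth.json"),
    }
    write_incidents(result.incidents, paths["incidents"])
    write_mortality(result.mortality, paths["mortality"])
    write_monthly_counts(result.monthly_counts, paths["monthly_counts"])
    write_counties(result.counties, paths["counties"])
    truth = {
        "schema_version": SCHEMA_VERSION,
        "true_total": result.config.true_total,
        "seed": result.config.seed,
        "cells": result.truth_cells.to_dict(orient="records"),
        "flags": result.truth_flags.assign(
            death_date=pd.to_datetime(result.truth_flags["death_date"]).dt.strftime("%Y-%m-%d")
        ).to_dict(orient="records"),
    }
    write_json(truth, paths["truth"])
    return paths
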