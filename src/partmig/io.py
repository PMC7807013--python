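"""Delimited-table input/output with schema validation.

All tables are plain CSV with header rows, ISO-8601 dates and decimal
points. Validation is itemized: every offending row is reported (by table,
row index and reason) before any modelling happens.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

__all__ = ["SCHEMAS", "SchemaError", "validate_table", "read_table",
           "read_all", "write_all"]


@dataclass(frozen=True)
class TableSchema:
    required: tuple[str, ...]
    date_cols: tuple[str, ...] = ()
    numeric_cols: tuple[str, ...] = ()


SCHEMAS: dict[str, TableSchema] = {
    "captures": TableSchema(
        ("bird_id", "date", "age_class", "sex", "colony", "area", "mass",
         "wing_chord", "p8", "year"),
        date_cols=("date",), numeric_cols=("mass", "wing_chord", "p8")),
    "resightings": TableSchema(("bird_id", "date", "area"), date_cols=("date",)),
    "geolocator_fixes": TableSchema(
        ("bird_id", "datetime", "latitude", "longitude"),
        date_cols=("datetime",), numeric_cols=("latitude", "longitude")),
    "feather_isotopes": TableSchema(
        ("bird_id", "collection_year", "d13c"), numeric_cols=("d13c",)),
    "nests": TableSchema(
        ("nest_id", "colony", "area", "year", "parent1", "parent2",
         "observed_first_egg", "observed_first_hatch", "clutch_size"),
        numeric_cols=("clutch_size",)),
    "nest_chicks": TableSchema(
        ("nest_id", "chick_id", "date", "wing_chord", "p8", "mass",
         "known_age", "age_reached")),
    "ndvi": TableSchema(("pixel_id", "area", "date", "ndvi"),
                        date_cols=("date",), numeric_cols=("ndvi",)),
}


class SchemaError(ValueError):
    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__("schema validation failed:\n" + "\n".join(problems))


def validate_table(df: pd.DataFrame, name: str) -> list[str]:
    """Return an itemized list of schema problems (empty if valid)."""
    schema = SCHEMAS[name]
    problems = []
    missing = [c for c in schema.required if c not in df.columns]
    if missing:
        problems.append(f"{name}: missing columns {missing}")
        return problems
    for col in schema.date_cols:
        parsed = pd.to_datetime(df[col], errors="coerce")
        bad = df.index[df[col].notna() & parsed.isna()]
        for i in bad[:20]:
            problems.append(f"{name} row {i}: unparseable date {df.at[i, col]!r} in {col}")
    for col in schema.numeric_cols:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[df[col].notna() & coerced.isna()]
        for i in bad[:20]:
            problems.append(f"{name} row {i}: non-numeric {df.at[i, col]!r} in {col}")
    if name == "geolocator_fixes":
        lat = pd.to_numeric(df["latitude"], errors="coerce")
        bad = df.index[(lat < -90) | (lat > 90)]
        for i in bad[:20]:
            problems.append(f"{name} row {i}: latitude {df.at[i, 'latitude']} out of [-90, 90]")
    return problems


def read_table(path: str | Path, name: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    problems = validate_table(df, name)
    if problems:
        raise SchemaError(problems)
    return df


def read_all(directory: str | Path) -> dict[str, pd.DataFrame]:
    """Read the observation tables found in a directory (by canonical name)."""
    directory = Path(directory)
    tables = {}
    problems: list[str] = []
    for name in ("captures", "resightings", "geolocator_fixes",
                 "feather_isotopes", "nests", "nest_chicks"):
        p = directory / f"{name}.csv"
        if not p.exists():
            continue
        df = pd.read_csv(p)
        problems.extend(validate_table(df, name))
        tables[name] = df
    if problems:
        raise SchemaError(problems)
    return tables


def write_all(tables: dict[str, pd.DataFrame], directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, df in tables.items():
        df.to_csv(directory / f"{name}.csv", index=False)
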