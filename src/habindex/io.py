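"""Readers and writers for the pipeline's tabular artifacts.

Every table travels as a :class:`pandas.DataFrame` with a fixed column
schema (CSV, UTF-8, header row mandatory, decimal point).  Readers
validate each file against the schema invariants and raise
:class:`SchemaError` / :class:`DuplicateKeyError` naming the offending
row, so malformed inputs fail at the door rather than deep inside the
statistics.

Frequency classes are stored in files as Roman numerals (I-V), the NVC
convention, and mapped to integers 1-5 internally on demand.  Species
and habitat identifiers are opaque, case-sensitive strings; no fuzzy or
taxonomic matching is attempted.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "DuplicateKeyError",
    "FREQUENCY_CLASSES",
    "FLORISTICS_COLUMNS",
    "CORRESPONDENCE_COLUMNS",
    "AREAS_COLUMNS",
    "OCCUPANCY_COLUMNS",
    "COVER_COLUMNS",
    "WEIGHTS_COLUMNS",
    "INDEX_COLUMNS",
    "TRENDS_COLUMNS",
    "COMPARISON_COLUMNS",
    "read_floristic_table",
    "read_correspondence",
    "read_areas",
    "read_occupancy",
    "read_covers",
    "read_weights",
    "read_index_series",
    "read_trends",
    "write_table",
    "write_covers",
    "write_weights",
    "write_index_series",
    "write_trends",
    "write_comparison",
]


class SchemaError(ValueError):
    """A file or table violates its declared schema."""


class DuplicateKeyError(SchemaError):
    """A table contains duplicate rows for a key that must be unique."""


#: Roman-numeral frequency classes in ascending order (NVC convention).
FREQUENCY_CLASSES = ("I", "II", "III", "IV", "V")

FLORISTICS_COLUMNS = ["community_id", "species", "frequency_class", "domin"]
CORRESPONDENCE_COLUMNS = ["community_id", "habitat"]
AREAS_COLUMNS = ["habitat", "area"]
OCCUPANCY_COLUMNS = ["species", "year", "occupancy"]
COVER_COLUMNS = ["species", "habitat", "cover"]
WEIGHTS_COLUMNS = ["species", "habitat", "method", "weight"]
INDEX_COLUMNS = ["habitat", "method", "year", "di", "gsd", "coverage", "n_species"]
TRENDS_COLUMNS = ["species", "period", "start_year", "end_year", "trend"]
COMPARISON_COLUMNS = ["model", "term", "estimate", "se", "df", "stat", "p"]

# 12 significant digits: round-trips doubles through text losslessly for
# the value ranges used here while keeping files diffable.
_FLOAT_FMT = "%.12g"


def _read_csv(path, columns: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    return df[columns]


def _row(i: int) -> str:
    # +2: 1-based on-disk line numbers plus the header row
    return f"row {i + 2}"


def _to_numeric(df: pd.DataFrame, col: str, path, kind: str = "float") -> pd.Series:
    out = pd.to_numeric(df[col], errors="coerce")
    bad = out.isna()
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        raise SchemaError(
            f"{path}: column {col!r} is not numeric at {_row(i)} "
            f"(value {df[col].iloc[i]!r})"
        )
    if kind == "int":
        if not np.allclose(out, np.round(out)):
            i = int(np.flatnonzero(~np.isclose(out, np.round(out)))[0])
            raise SchemaError(f"{path}: column {col!r} must be integer at {_row(i)}")
        out = out.astype(int)
    return out


def _check_unique(df: pd.DataFrame, keys: list[str], path) -> None:
    dup = df.duplicated(subset=keys)
    if dup.any():
        i = int(np.flatnonzero(dup.to_numpy())[0])
        key = tuple(df[k].iloc[i] for k in keys)
        raise DuplicateKeyError(f"{path}: duplicate key {key} for {keys} at {_row(i)}")


def frequency_class_to_int(cls: str) -> int:
    """Map a Roman frequency class I..V to its rank 1..5."""
    try:
        return FREQUENCY_CLASSES.index(cls) + 1
    except ValueError:
        raise SchemaError(
            f"unknown frequency class {cls!r}; expected one of {FREQUENCY_CLASSES}"
        ) from None


def read_floristic_table(path) -> pd.DataFrame:
    """Read a floristic table (community x species records).

    Columns: community_id, species, frequency_class (Roman I-V),
    domin (integer 1-10).  (community_id, species) must be unique.
    """
    df = _read_csv(path, FLORISTICS_COLUMNS)
    bad = ~df["frequency_class"].isin(FREQUENCY_CLASSES)
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        raise SchemaError(
            f"{path}: unknown frequency class {df['frequency_class'].iloc[i]!r} "
            f"at {_row(i)}; expected one of {FREQUENCY_CLASSES}"
        )
    df["domin"] = _to_numeric(df, "domin", path, kind="int")
    out_of_range = (df["domin"] < 1) | (df["domin"] > 10)
    if out_of_range.any():
        i = int(np.flatnonzero(out_of_range.to_numpy())[0])
        raise SchemaError(
            f"{path}: Domin score {df['domin'].iloc[i]} outside [1, 10] at {_row(i)}"
        )
    _check_unique(df, ["community_id", "species"], path)
    return df.reset_index(drop=True)


def read_correspondence(path) -> pd.DataFrame:
    """Read the community -> habitat correspondence table."""
    df = _read_csv(path, CORRESPONDENCE_COLUMNS)
    _check_unique(df, ["community_id", "habitat"], path)
    return df.reset_index(drop=True)


def read_areas(path) -> pd.DataFrame:
    """Read habitat areas (nonnegative, same units for all rows)."""
    df = _read_csv(path, AREAS_COLUMNS)
    df["area"] = _to_numeric(df, "area", path)
    neg = df["area"] < 0
    if neg.any():
        i = int(np.flatnonzero(neg.to_numpy())[0])
        raise SchemaError(f"{path}: negative area at {_row(i)}")
    _check_unique(df, ["habitat"], path)
    if not (df["area"] > 0).any():
        raise SchemaError(f"{path}: at least one habitat area must be positive")
    return df.reset_index(drop=True)


def read_occupancy(path) -> pd.DataFrame:
    """Read annual per-species occupancy scores.

    Occupancy must lie in [0, 1]; exact 0/1 values are tolerated here and
    clamped later by the index module's floor rule, but anything outside
    [0, 1] is rejected.  Years are sorted ascending within species.
    """
    df = _read_csv(path, OCCUPANCY_COLUMNS)
    df["year"] = _to_numeric(df, "year", path, kind="int")
    df["occupancy"] = _to_numeric(df, "occupancy", path)
    bad = (df["occupancy"] < 0) | (df["occupancy"] > 1)
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        raise SchemaError(
            f"{path}: occupancy {df['occupancy'].iloc[i]} outside [0, 1] at {_row(i)}"
        )
    _check_unique(df, ["species", "year"], path)
    return df.sort_values(["species", "year"], kind="stable").reset_index(drop=True)


def read_covers(path) -> pd.DataFrame:
    df = _read_csv(path, COVER_COLUMNS)
    df["cover"] = _to_numeric(df, "cover", path)
    _check_unique(df, ["species", "habitat"], path)
    return df.reset_index(drop=True)


def read_weights(path) -> pd.DataFrame:
    df = _read_csv(path, WEIGHTS_COLUMNS)
    df["weight"] = _to_numeric(df, "weight", path)
    neg = df["weight"] < 0
    if neg.any():
        i = int(np.flatnonzero(neg.to_numpy())[0])
        raise SchemaError(f"{path}: negative weight at {_row(i)}")
    _check_unique(df, ["species", "habitat", "method"], path)
    return df.reset_index(drop=True)


def read_index_series(path) -> pd.DataFrame:
    df = _read_csv(path, INDEX_COLUMNS)
    df["year"] = _to_numeric(df, "year", path, kind="int")
    for col in ("di", "gsd", "coverage"):
        df[col] = _to_numeric(df, col, path)
    df["n_species"] = _to_numeric(df, "n_species", path, kind="int")
    _check_unique(df, ["habitat", "method", "year"], path)
    return df.reset_index(drop=True)


def read_trends(path) -> pd.DataFrame:
    df = _read_csv(path, TRENDS_COLUMNS)
    df["start_year"] = _to_numeric(df, "start_year", path, kind="int")
    df["end_year"] = _to_numeric(df, "end_year", path, kind="int")
    df["trend"] = _to_numeric(df, "trend", path)
    _check_unique(df, ["species", "period"], path)
    return df.reset_index(drop=True)


def write_table(df: pd.DataFrame, path, columns: list[str] | None = None) -> None:
    """Write a table as CSV at 12 significant digits.

    The generic writer behind all ``write_*`` helpers; ``columns``
    restricts and orders the emitted columns.
    """
    if columns is not None:
        extra = [c for c in df.columns if c in columns]
        df = df[extra] if len(df) or extra else pd.DataFrame(columns=columns)
        missing = [c for c in columns if c not in df.columns]
        for c in missing:
            df = df.assign(**{c: pd.Series(dtype=float)})
        df = df[columns]
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_covers(df: pd.DataFrame, path) -> None:
    write_table(df, path, COVER_COLUMNS)


def write_weights(df: pd.DataFrame, path) -> None:
    write_table(df, path, WEIGHTS_COLUMNS)


def write_index_series(df: pd.DataFrame, path) -> None:
    write_table(df, path, INDEX_COLUMNS)


def write_trends(df: pd.DataFrame, path) -> None:
    write_table(df, path, TRENDS_COLUMNS)


def write_comparison(df: pd.DataFrame, path) -> None:
    write_table(df, path, COMPARISON_COLUMNS)
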