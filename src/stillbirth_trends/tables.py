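"""Stratified birth-count tables and rate computation.

The central container is :class:`BirthTable`, a validated long-format table
of aggregated stillbirth and live-birth counts per country, calendar year,
stratification axis (maternal age or multiplicity) and stratum.  National
registries report the two axes as separate marginal tables — age and
multiplicity are not cross-tabulated — so the axis is part of the key.

Rates throughout the package are stillbirths per 1000 *total* births
(stillbirths + live births), the convention of perinatal surveillance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import (
    LookupError_,
    SchemaError,
    UndefinedRateError,
    ValidationError,
)

#: Stratification axes recognised in input tables.
AXES = ("maternal_age", "multiplicity")

#: Label used for records whose stratum could not be determined upstream.
UNKNOWN = "unknown"

#: Canonical maternal-age bands (closed-open on completed years); configurable
#: at the generator/IO level — the analysis code treats strata as opaque labels.
DEFAULT_AGE_BANDS = ("<20", "20-24", "25-29", "30-34", "35-39", "40+")

#: Multiplicity strata.
MULTIPLICITY_STRATA = ("singleton", "multiple")

REQUIRED_COLUMNS = ("country", "year", "axis", "stratum", "stillbirths", "live_births")
KEY_COLUMNS = ("country", "year", "axis", "stratum")


@dataclass
class CountryMeta:
    """Per-country metadata flags.

    includes_top
        True when the national stillbirth counts cannot exclude terminations
        of pregnancy; interpretation caveat only, never a numerical adjustment.
    first_year
        First calendar year with usable data for this country.
    """

    includes_top: bool = False
    first_year: int | None = None


@dataclass
class BirthTable:
    """A validated long-format table of stratified birth counts.

    ``data`` columns: country, year, axis, stratum, stillbirths, live_births,
    suppressed_bound.  ``suppressed_bound`` is 0 for exact cells; a value
    k > 0 marks a disclosure-suppressed cell whose true stillbirth count lies
    in ``0..k-1`` (the stored count is a placeholder until imputation).
    Counts may be fractional after proportional redistribution of unknowns.
    """

    data: pd.DataFrame
    metadata: dict[str, CountryMeta] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = _normalise(self.data)
        validate_frame(self.data)

    # -- convenience accessors -------------------------------------------------

    @property
    def countries(self) -> list[str]:
        return sorted(self.data["country"].unique())

    def years(self, country: str) -> list[int]:
        sub = self.data[self.data["country"] == country]
        if sub.empty:
            raise LookupError_(f"country {country!r} not in table")
        return sorted(sub["year"].unique())

    def subset(self, country: str, year: int, axis: str) -> pd.DataFrame:
        _check_axis(axis)
        mask = (
            (self.data["country"] == country)
            & (self.data["year"] == year)
            & (self.data["axis"] == axis)
        )
        return self.data[mask]

    def has_unknown(self) -> bool:
        return bool((self.data["stratum"] == UNKNOWN).any())

    def has_suppressed(self) -> bool:
        return bool((self.data["suppressed_bound"] > 0).any())

    def replace_data(self, data: pd.DataFrame) -> "BirthTable":
        """New table with the same metadata and different records."""
        return BirthTable(data=data.reset_index(drop=True), metadata=dict(self.metadata))

    # -- IO ---------------------------------------------------------------------

    def write_csv(self, path: str | Path) -> None:
        out = self.data.copy()
        out.to_csv(path, index=False)


def _check_axis(axis: str) -> None:
    if axis not in AXES:
        raise ValidationError(f"axis must be one of {AXES}, got {axis!r}")


def _normalise(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy().reset_index(drop=True)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")
    if "suppressed_bound" not in df.columns:
        df["suppressed_bound"] = 0
    df["suppressed_bound"] = (
        pd.to_numeric(df["suppressed_bound"], errors="coerce").fillna(0).astype(int)
    )
    df["country"] = df["country"].astype(str)
    df["stratum"] = df["stratum"].astype(str)
    df["axis"] = df["axis"].astype(str)
    df["year"] = pd.to_numeric(df["year"], errors="raise").astype(int)
    for col in ("stillbirths", "live_births"):
        df[col] = pd.to_numeric(df[col], errors="raise").astype(float)
    return df[list(REQUIRED_COLUMNS) + ["suppressed_bound"]]


def validate_frame(df: pd.DataFrame) -> None:
    """Raise :class:`ValidationError` on negative counts, bad axes or duplicate keys."""
    bad_axis = ~df["axis"].isin(AXES)
    if bad_axis.any():
        raise ValidationError(
            f"unrecognised axis values: {sorted(df.loc[bad_axis, 'axis'].unique())}"
        )
    for col in ("stillbirths", "live_births"):
        neg = df[col] < 0
        if neg.any():
            row = df[neg].iloc[0]
            raise ValidationError(
                f"negative {col} ({row[col]}) at country={row['country']!r} "
                f"year={row['year']} axis={row['axis']!r} stratum={row['stratum']!r}"
            )
    dup = df.duplicated(subset=list(KEY_COLUMNS), keep=False)
    if dup.any():
        row = df[dup].iloc[0]
        raise ValidationError(
            f"duplicate (country, year, axis, stratum) key: "
            f"({row['country']!r}, {row['year']}, {row['axis']!r}, {row['stratum']!r})"
        )


def read_table(
    path: str | Path,
    delimiter: str = ",",
    column_map: Mapping[str, str] | None = None,
    metadata: Mapping[str, CountryMeta] | None = None,
) -> BirthTable:
    """Read a delimited text file into a validated :class:`BirthTable`.

    Parameters
    ----------
    path
        CSV file with header row; required columns ``country, year, axis,
        stratum, stillbirths, live_births`` and optional ``suppressed_bound``.
    delimiter
        Field delimiter, ``,`` by default.
    column_map
        Optional mapping from the file's column names to the canonical ones.
    metadata
        Optional per-country flags to attach.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"input file not found: {path}")
    df = pd.read_csv(path, sep=delimiter)
    if column_map:
        df = df.rename(columns=dict(column_map))
    return BirthTable(data=df, metadata=dict(metadata or {}))


def compute_rate(stillbirths: float, live_births: float) -> float:
    """Stillbirth rate per 1000 total births: 1000 * SB / (SB + LB)."""
    total = stillbirths + live_births
    if total <= 0:
        raise UndefinedRateError("rate undefined: zero total births")
    return 1000.0 * stillbirths / total


@dataclass
class RateSeries:
    """One country's annual national stillbirth rates.

    rates are per 1000 total births, aligned with strictly increasing years;
    totals carry the per-year total births (the rate denominators / 1000).
    """

    country: str
    years: np.ndarray
    rates: np.ndarray
    totals: np.ndarray

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.rates = np.asarray(self.rates, dtype=float)
        self.totals = np.asarray(self.totals, dtype=float)
        if not (len(self.years) == len(self.rates) == len(self.totals)):
            raise ValidationError("years, rates and totals must have equal length")
        if len(self.years) > 1 and not np.all(np.diff(self.years) > 0):
            raise ValidationError("years must be strictly increasing")
        if np.any((self.rates < 0) | (self.rates > 1000)):
            raise ValidationError("rates must lie in [0, 1000] per 1000 births")

    def __len__(self) -> int:
        return len(self.years)

    def value_at(self, year: int) -> float:
        idx = np.nonzero(self.years == year)[0]
        if idx.size == 0:
            raise LookupError_(f"year {year} not in series for {self.country}")
        return float(self.rates[idx[0]])


def rate_series(table: BirthTable, country: str, axis: str) -> RateSeries:
    """National annual rate series from summed stratum counts on one axis.

    Requires a repaired table (no 'unknown' strata) so that the stratum sum
    equals the national total.  Years are the country's native span; series
    starting after 2010 are legal.
    """
    _check_axis(axis)
    sub = table.data[
        (table.data["country"] == country) & (table.data["axis"] == axis)
    ]
    if sub.empty:
        raise LookupError_(f"no records for country={country!r} axis={axis!r}")
    if (sub["stratum"] == UNKNOWN).any():
        raise ValidationError(
            f"table not repaired: 'unknown' strata remain for {country!r}/{axis}"
        )
    grouped = sub.groupby("year")[["stillbirths", "live_births"]].sum().sort_index()
    totals = grouped["stillbirths"] + grouped["live_births"]
    if (totals <= 0).any():
        bad = int(totals[totals <= 0].index[0])
        raise UndefinedRateError(f"zero total births for {country!r} in {bad}")
    rates = 1000.0 * grouped["stillbirths"] / totals
    return RateSeries(
        country=country,
        years=grouped.index.to_numpy(),
        rates=rates.to_numpy(),
        totals=totals.to_numpy(),
    )


def axis_totals(table: BirthTable, country: str, year: int, axis: str) -> tuple[float, float]:
    """(stillbirths, live_births) summed over strata of one axis."""
    sub = table.subset(country, year, axis)
    if sub.empty:
        raise LookupError_(f"no records for ({country!r}, {year}, {axis!r})")
    return float(sub["stillbirths"].sum()), float(sub["live_births"].sum())


def check_axis_consistency(table: BirthTable, tol: float = 1e-6) -> pd.DataFrame:
    """Compare per (country, year) totals computed from each axis.

    Returns a frame of discrepancies exceeding ``tol`` (relative, on total
    births); empty frame means the two marginal tables are consistent.
    """
    rows = []
    df = table.data
    for (country, year), sub in df.groupby(["country", "year"]):
        axes_present = sub["axis"].unique()
        if len(axes_present) < 2:
            continue
        totals = {
            axis: sub[sub["axis"] == axis][["stillbirths", "live_births"]].sum().sum()
            for axis in axes_present
        }
        vals = list(totals.values())
        ref = max(vals)
        if ref > 0 and (max(vals) - min(vals)) / ref > tol:
            rows.append(
                {"country": country, "year": year, **{f"total_{a}": t for a, t in totals.items()}}
            )
    return pd.DataFrame(rows)


def validation_report(table: BirthTable) -> dict:
    """Machine-readable validation summary (JSON-serialisable)."""
    df = table.data
    inconsistent = check_axis_consistency(table)
    return {
        "n_records": int(len(df)),
        "n_countries": len(table.countries),
        "year_range": [int(df["year"].min()), int(df["year"].max())] if len(df) else None,
        "n_unknown_records": int((df["stratum"] == UNKNOWN).sum()),
        "n_suppressed_cells": int((df["suppressed_bound"] > 0).sum()),
        "axis_inconsistencies": inconsistent.to_dict(orient="records"),
    }


def concat_tables(tables: Iterable[BirthTable]) -> BirthTable:
    """Concatenate tables with disjoint keys into one."""
    tables = list(tables)
    data = pd.concat([t.data for t in tables], ignore_index=True)
    meta: dict[str, CountryMeta] = {}
    for t in tables:
        meta.update(t.metadata)
    return BirthTable(data=data, metadata=meta)
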