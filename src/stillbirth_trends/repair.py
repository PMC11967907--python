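"""Table repair: proportional redistribution of unknown strata and seeded
imputation of disclosure-suppressed cells.

Registries sometimes cannot assign a maternal-age band or multiplicity to
every birth.  Dropping those births would bias national rates downward in
exactly the countries with poorer data completeness, so unknown-stratum
counts are instead redistributed proportionally across the known strata,
separately for stillbirths and live births — the maximum-entropy choice
under a missing-at-random assumption.  Redistribution conserves the
(country, year, axis) grand totals and produces fractional counts.

Cells reported only as "< k" for disclosure control are imputed with an
integer drawn uniformly from {0, ..., k-1} by a seeded generator, making
repair fully reproducible.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ConfigurationError, UnresolvableMissingnessError
from .tables import UNKNOWN, BirthTable


def redistribute_unknown(table: BirthTable) -> BirthTable:
    """Allocate 'unknown'-stratum counts proportionally over known strata.

    For each (country, year, axis) and each outcome (stillbirths, live
    births) independently: every known stratum receives the unknown count
    times its share of the known total.  Totals are conserved to machine
    precision; known-stratum proportions are preserved exactly; the
    'unknown' records are removed.

    Raises
    ------
    UnresolvableMissingnessError
        If an unknown count is positive while every known stratum is zero.
    """
    df = table.data
    if not (df["stratum"] == UNKNOWN).any():
        return table.replace_data(df)

    out_groups: list[pd.DataFrame] = []
    for (country, year, axis), sub in df.groupby(["country", "year", "axis"], sort=False):
        unk = sub[sub["stratum"] == UNKNOWN]
        known = sub[sub["stratum"] != UNKNOWN].copy()
        if unk.empty:
            out_groups.append(sub)
            continue
        for col in ("stillbirths", "live_births"):
            u = float(unk[col].sum())
            if u == 0.0:
                continue
            known_total = float(known[col].sum())
            if known_total <= 0.0:
                raise UnresolvableMissingnessError(
                    f"unknown {col}={u} with zero known total at "
                    f"({country!r}, {year}, {axis!r})"
                )
            known[col] = known[col] * (1.0 + u / known_total)
        out_groups.append(known)

    repaired = pd.concat(out_groups, ignore_index=True)
    return table.replace_data(repaired)


def impute_suppressed(
    table: BirthTable, bound: int | None = None, seed: int | None = None
) -> BirthTable:
    """Replace disclosure-suppressed stillbirth cells with seeded uniform draws.

    A suppressed cell's true count lies in ``0..k-1`` where k is the
    disclosure bound, taken from the record's ``suppressed_bound`` column
    (or ``bound`` as a fallback for flagged cells without one).  The stored
    placeholder count is replaced by a draw from the seeded generator; the
    suppression flag is cleared.  Deterministic given ``seed``.
    """
    df = table.data.copy()
    mask = df["suppressed_bound"] > 0
    if not mask.any():
        return table.replace_data(df)
    if seed is None:
        raise ConfigurationError("impute_suppressed requires a seed for reproducibility")

    bounds = df.loc[mask, "suppressed_bound"].to_numpy()
    if bound is not None:
        bounds = np.where(bounds > 0, bounds, bound)
    if np.any(bounds <= 0):
        raise ConfigurationError("suppressed cell without a positive disclosure bound")

    rng = np.random.default_rng(seed)
    draws = rng.integers(low=0, high=bounds)  # uniform over {0, ..., k-1}
    df.loc[mask, "stillbirths"] = draws.astype(float)
    df.loc[mask, "suppressed_bound"] = 0
    return table.replace_data(df)


def repair(table: BirthTable, bound: int | None = None, seed: int | None = None) -> BirthTable:
    """Full repair: impute suppressed cells, then redistribute unknowns.

    Imputation runs first so that redistribution shares reflect the imputed
    counts.  Seed required only when suppressed cells are present.
    """
    if table.has_suppressed():
        table = impute_suppressed(table, bound=bound, seed=seed)
    return redistribute_unknown(table)
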