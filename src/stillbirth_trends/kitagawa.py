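"""Kitagawa two-population decomposition of crude stillbirth-rate differences.

For two populations A and B partitioned into the same strata i (maternal-age
bands or multiplicity), with C_i the share of total births in stratum i and
M_i the stratum stillbirth rate per 1000 total births, the crude-rate
difference

    delta = sum_i C_iB * M_iB  -  sum_i C_iA * M_iA

splits exactly into

    composition = sum_i (C_iB - C_iA) * (M_iB + M_iA) / 2
    rate        = sum_i (M_iB - M_iA) * (C_iB + C_iA) / 2

The composition component is the counterfactual rate change if only the
stratum shares differed (stratum rates held at the two-population mean);
the rate component is the change if only the stratum rates differed.  The
two components add to delta exactly, stratum by stratum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import LookupError_, UndefinedRateError, ValidationError
from .tables import BirthTable, _check_axis

#: Tolerance on share-sum validation.
SHARE_TOL = 1e-9


def summarize_population(
    table: BirthTable, country: str, year: int, axis: str
) -> pd.DataFrame:
    """Per-stratum shares and rates for one (country, year, axis).

    Returns a frame with columns ``stratum``, ``share`` (C_i, proportion of
    total births) and ``rate`` (M_i, stillbirths per 1000 total births in the
    stratum).  A stratum with zero births gets share 0 and rate 0.
    Requires a repaired table (no 'unknown' strata).
    """
    _check_axis(axis)
    sub = table.subset(country, year, axis)
    if sub.empty:
        raise LookupError_(f"no records for ({country!r}, {year}, {axis!r})")
    if (sub["stratum"] == "unknown").any():
        raise ValidationError("table not repaired: 'unknown' strata remain")
    births = (sub["stillbirths"] + sub["live_births"]).to_numpy(dtype=float)
    total = births.sum()
    if total <= 0:
        raise UndefinedRateError(f"zero total births for ({country!r}, {year}, {axis!r})")
    share = births / total
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(births > 0, 1000.0 * sub["stillbirths"].to_numpy() / births, 0.0)
    return pd.DataFrame(
        {"stratum": sub["stratum"].to_numpy(), "share": share, "rate": rate}
    ).sort_values("stratum", ignore_index=True)


@dataclass
class DecompositionResult:
    """Exact split of a crude-rate difference delta = B minus A (per 1000).

    per_stratum columns: stratum, composition, rate — the stratum-level
    contributions, summing to the respective components.
    """

    total_difference: float
    composition_component: float
    rate_component: float
    per_stratum: pd.DataFrame
    role_labels: dict = field(default_factory=dict)

    @property
    def crude_rate_a(self) -> float:
        return float(self._crude("a"))

    @property
    def crude_rate_b(self) -> float:
        return float(self._crude("b"))

    def _crude(self, side: str) -> float:
        return (self.per_stratum[f"share_{side}"] * self.per_stratum[f"rate_{side}"]).sum()

    def as_dict(self) -> dict:
        return {
            "delta": self.total_difference,
            "composition": self.composition_component,
            "rate_component": self.rate_component,
            **self.role_labels,
        }


def _validate_summary(pop: pd.DataFrame, name: str) -> pd.DataFrame:
    for col in ("stratum", "share", "rate"):
        if col not in pop.columns:
            raise ValidationError(f"population {name} lacks column {col!r}")
    if pop["stratum"].duplicated().any():
        raise ValidationError(f"population {name} has duplicate strata")
    if (pop["share"] < 0).any():
        raise ValidationError(f"population {name} has negative shares")
    if abs(pop["share"].sum() - 1.0) > 1e-6:
        raise ValidationError(
            f"population {name} shares sum to {pop['share'].sum():.9f}, not 1"
        )
    return pop.set_index("stratum")


def kitagawa_decompose(
    pop_a: pd.DataFrame, pop_b: pd.DataFrame, role_labels: dict | None = None
) -> DecompositionResult:
    """Decompose the crude-rate difference (B minus A) into composition and
    rate components with per-stratum contributions.

    Strata present on one side only enter with share 0 on the absent side
    and the rate copied from the present side, so they contribute through
    the composition channel only (avoids an undefined 0/0 rate while keeping
    the split exact).
    """
    a = _validate_summary(pop_a, "A")
    b = _validate_summary(pop_b, "B")
    strata = sorted(set(a.index) | set(b.index))

    ca = np.array([a["share"].get(s, 0.0) for s in strata])
    cb = np.array([b["share"].get(s, 0.0) for s in strata])
    ma = np.empty(len(strata))
    mb = np.empty(len(strata))
    for k, s in enumerate(strata):
        in_a, in_b = s in a.index, s in b.index
        ma[k] = a["rate"].get(s, b["rate"].get(s, 0.0)) if in_a or in_b else 0.0
        mb[k] = b["rate"].get(s, a["rate"].get(s, 0.0)) if in_a or in_b else 0.0

    comp_i = (cb - ca) * (mb + ma) / 2.0
    rate_i = (mb - ma) * (cb + ca) / 2.0
    delta = float(np.sum(cb * mb) - np.sum(ca * ma))

    per_stratum = pd.DataFrame(
        {
            "stratum": strata,
            "share_a": ca,
            "share_b": cb,
            "rate_a": ma,
            "rate_b": mb,
            "composition": comp_i,
            "rate": rate_i,
        }
    )
    return DecompositionResult(
        total_difference=delta,
        composition_component=float(comp_i.sum()),
        rate_component=float(rate_i.sum()),
        per_stratum=per_stratum,
        role_labels=dict(role_labels or {}),
    )


def decompose_over_time(
    table: BirthTable,
    country: str,
    axis: str,
    year_a: int | None = None,
    year_b: int = 2021,
) -> DecompositionResult:
    """Within-country decomposition between two years (default: first
    available year -> 2021).  Population A is the earlier year."""
    years = [y for y in table.years(country) if not table.subset(country, y, axis).empty]
    if not years:
        raise LookupError_(f"no {axis} records for {country!r}")
    if year_a is None:
        year_a = min(years)
    for y in (year_a, year_b):
        if y not in years:
            raise LookupError_(f"year {y} absent for ({country!r}, {axis!r})")
    pop_a = summarize_population(table, country, year_a, axis)
    pop_b = summarize_population(table, country, year_b, axis)
    return kitagawa_decompose(
        pop_a,
        pop_b,
        role_labels={
            "comparison": "over_time",
            "country": country,
            "axis": axis,
            "year_a": int(year_a),
            "year_b": int(year_b),
        },
    )


def pooled_reference(
    table: BirthTable, year: int, axis: str, countries: list[str] | None = None
) -> pd.DataFrame:
    """Multi-country reference population: stratum counts summed across
    countries before computing shares and rates (birth-weighted pooling,
    not the mean of national rates)."""
    _check_axis(axis)
    if countries is None:
        countries = table.countries
    frames = []
    for c in countries:
        sub = table.subset(c, year, axis)
        if sub.empty:
            raise LookupError_(f"country {c!r} lacks ({year}, {axis!r}) data")
        frames.append(sub)
    pooled = (
        pd.concat(frames)
        .groupby("stratum", as_index=False)[["stillbirths", "live_births"]]
        .sum()
    )
    births = pooled["stillbirths"] + pooled["live_births"]
    total = float(births.sum())
    if total <= 0:
        raise UndefinedRateError("pooled reference has zero total births")
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(births > 0, 1000.0 * pooled["stillbirths"] / births, 0.0)
    return pd.DataFrame(
        {"stratum": pooled["stratum"], "share": births / total, "rate": rate}
    ).sort_values("stratum", ignore_index=True)


def decompose_vs_reference(
    table: BirthTable,
    country: str,
    axis: str,
    year: int,
    countries: list[str] | None = None,
    exclude_self: bool = False,
) -> DecompositionResult:
    """Country vs pooled multi-country average in one year.

    Population A is the country, B the pooled reference (which includes the
    country itself unless ``exclude_self``).  Positive delta means the
    reference exceeds the country; ``role_labels['country_minus_reference']``
    carries the negation for 'higher/lower than average' reporting.
    """
    if countries is None:
        countries = table.countries
    ref_countries = [c for c in countries if not (exclude_self and c == country)]
    pop_a = summarize_population(table, country, year, axis)
    pop_b = pooled_reference(table, year, axis, ref_countries)
    result = kitagawa_decompose(
        pop_a,
        pop_b,
        role_labels={
            "comparison": "vs_reference",
            "country": country,
            "axis": axis,
            "year_a": int(year),
            "year_b": int(year),
        },
    )
    result.role_labels["country_minus_reference"] = -result.total_difference
    return result
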