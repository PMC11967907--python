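"""Synthetic stratified birth-registry generator with known ground truth.

The real multi-country registry extracts behind this kind of surveillance
are confidential, so every pipeline stage is exercised against a generator
that emulates their statistical structure:

* per-country annual totals from a few thousand to several hundred thousand
  births, linearly interpolated between a start and end value;
* a maternal-age distribution drifting toward ages 35+ over the study span;
* multiple-birth shares of roughly 2–6%, mostly declining;
* J-shaped age-specific stillbirth risk, with the advanced-age risk
  declining over time;
* a ~3x relative stillbirth risk for multiple births;
* optional positive age–multiplicity coupling (multiples more frequent at
  older ages);
* partially missing stratum labels, disclosure-suppressed small cells,
  country series with late start years, and optional multiplicative rate
  shocks in designated years (pandemic scenario).

Births are drawn per country-year from an age x multiplicity cross-table
(multinomial), stillbirths binomially per cell, and the cross-table is then
marginalised into the two separate axis tables that registries actually
release.  With ``sampling=False`` expected counts are emitted instead — the
infinite-population limit used by construction oracles.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .kitagawa import kitagawa_decompose
from .tables import (
    DEFAULT_AGE_BANDS,
    MULTIPLICITY_STRATA,
    UNKNOWN,
    BirthTable,
    CountryMeta,
)


@dataclass
class CountrySpec:
    """One synthetic country.

    Shares are start-of-span and end-of-span vectors, linearly interpolated
    in between.  ``covid_shock`` maps year -> multiplicative bump applied to
    every stratum's stillbirth probability in that year.
    """

    name: str
    births_start: float
    births_end: float
    age_shares_start: dict[str, float]
    age_shares_end: dict[str, float]
    multiple_share_start: float
    multiple_share_end: float
    first_year: int | None = None
    covid_shock: dict[int, float] = field(default_factory=dict)
    includes_top: bool = False


@dataclass
class SyntheticConfig:
    """Full generator configuration; the defaults define the study conditions."""

    countries: list[CountrySpec]
    years: tuple[int, int] = (2010, 2021)
    age_bands: tuple[str, ...] = DEFAULT_AGE_BANDS
    #: per-band stillbirth probability at span start and end (J-shape; the
    #: advanced-age bands improve the most over time)
    age_risk_start: dict[str, float] = field(default_factory=dict)
    age_risk_end: dict[str, float] = field(default_factory=dict)
    multiple_risk_ratio: float = 3.0
    #: >0 couples multiplicity to age (multiples more likely at older ages)
    age_multiplicity_coupling: float = 0.0
    missing_frac: float = 0.0
    suppress_below: int = 0
    sampling: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.age_risk_start:
            self.age_risk_start = dict(DEFAULT_AGE_RISK_START)
        if not self.age_risk_end:
            self.age_risk_end = dict(DEFAULT_AGE_RISK_END)
        self.validate()

    def validate(self) -> None:
        if self.multiple_risk_ratio <= 0:
            raise ConfigurationError("multiple_risk_ratio must be > 0")
        if not (0.0 <= self.missing_frac <= 1.0):
            raise ConfigurationError("missing_frac must lie in [0, 1]")
        for spec in self.countries:
            for shares, tag in (
                (spec.age_shares_start, "start"),
                (spec.age_shares_end, "end"),
            ):
                if set(shares) != set(self.age_bands):
                    raise ConfigurationError(
                        f"{spec.name}: age share bands ({tag}) must match config bands"
                    )
                tot = sum(shares.values())
                if abs(tot - 1.0) > 1e-9:
                    raise ConfigurationError(
                        f"{spec.name}: age shares ({tag}) sum to {tot}, not 1"
                    )
                if any(v < 0 for v in shares.values()):
                    raise ConfigurationError(f"{spec.name}: negative age share")
            for m in (spec.multiple_share_start, spec.multiple_share_end):
                if not (0.0 <= m <= 1.0):
                    raise ConfigurationError(f"{spec.name}: multiple share outside [0,1]")
        for band in self.age_bands:
            for risks in (self.age_risk_start, self.age_risk_end):
                if band not in risks:
                    raise ConfigurationError(f"missing risk for band {band!r}")
                if not (0.0 <= risks[band] <= 1.0):
                    raise ConfigurationError(f"risk for band {band!r} outside [0,1]")


#: Default per-band stillbirth probabilities (per birth, not per 1000):
#: J-shaped in age with elevated risk for teenagers and a steep rise after
#: 35; by span end the advanced-age bands have improved the most while the
#: youngest band worsens slightly.
DEFAULT_AGE_RISK_START = {
    "<20": 0.0042,
    "20-24": 0.0032,
    "25-29": 0.0028,
    "30-34": 0.0030,
    "35-39": 0.0045,
    "40+": 0.0075,
}
DEFAULT_AGE_RISK_END = {
    "<20": 0.0046,
    "20-24": 0.0031,
    "25-29": 0.0026,
    "30-34": 0.0027,
    "35-39": 0.0034,
    "40+": 0.0048,
}


@dataclass
class GroundTruth:
    """Exact design quantities for a generated table.

    expected_rates
        Frame (country, year, expected_rate) with the noise-free national
        rate per 1000 implied by the design.
    designed_decompositions
        Frame (country, axis, year_a, year_b, delta, composition,
        rate_component): the decomposition of the expected (infinite-n)
        populations between each country's first and last year.
    shock_years
        country -> {year: factor}.
    """

    expected_rates: pd.DataFrame
    designed_decompositions: pd.DataFrame
    shock_years: dict[str, dict[int, float]]
    config: SyntheticConfig

    def to_json_dict(self) -> dict:
        return {
            "expected_rates": self.expected_rates.to_dict(orient="records"),
            "designed_decompositions": self.designed_decompositions.to_dict(orient="records"),
            "shock_years": {c: {str(y): f for y, f in d.items()} for c, d in self.shock_years.items()},
            "config": _config_dict(self.config),
        }


def _config_dict(config: SyntheticConfig) -> dict:
    d = asdict(config)
    for spec in d["countries"]:
        spec["covid_shock"] = {str(k): v for k, v in spec["covid_shock"].items()}
    return d


def _interp(a: float, b: float, frac: float) -> float:
    return a + (b - a) * frac


def _cell_design(config: SyntheticConfig, spec: CountrySpec, year: int):
    """Expected cell structure for one country-year.

    Returns (cell_probs, cell_risks): arrays of shape (bands, 2) over the
    age x multiplicity cross-table — probability of a birth falling in the
    cell, and that cell's stillbirth probability.
    """
    y0, y1 = config.years
    frac = 0.0 if y1 == y0 else (year - y0) / (y1 - y0)
    bands = config.age_bands
    k = len(bands)

    age = np.array(
        [_interp(spec.age_shares_start[b], spec.age_shares_end[b], frac) for b in bands]
    )
    age = age / age.sum()
    m_overall = _interp(spec.multiple_share_start, spec.multiple_share_end, frac)

    # optional coupling: per-band multiple share tilts linearly with band index
    idx = np.arange(k, dtype=float)
    tilt = 1.0 + config.age_multiplicity_coupling * (idx - (k - 1) / 2.0)
    m_band = np.clip(m_overall * tilt, 0.0, 0.95)
    if m_band @ age > 0 and m_overall > 0:
        m_band = m_band * (m_overall / (m_band @ age))  # keep the overall share
        m_band = np.clip(m_band, 0.0, 0.95)

    cell_probs = np.column_stack([age * (1.0 - m_band), age * m_band])

    base = np.array(
        [_interp(config.age_risk_start[b], config.age_risk_end[b], frac) for b in bands]
    )
    shock = spec.covid_shock.get(year, 1.0)
    cell_risks = np.column_stack([base, np.minimum(base * config.multiple_risk_ratio, 1.0)])
    cell_risks = np.minimum(cell_risks * shock, 1.0)
    return cell_probs, cell_risks


def _expected_summaries(config: SyntheticConfig, spec: CountrySpec, year: int):
    """Noise-free stratum summaries (share, rate per 1000) for both axes."""
    probs, risks = _cell_design(config, spec, year)
    age_share = probs.sum(axis=1)
    mult_share = probs.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        age_rate = np.where(age_share > 0, 1000.0 * (probs * risks).sum(axis=1) / age_share, 0.0)
        mult_rate = np.where(mult_share > 0, 1000.0 * (probs * risks).sum(axis=0) / mult_share, 0.0)
    age_df = pd.DataFrame({"stratum": list(config.age_bands), "share": age_share, "rate": age_rate})
    mult_df = pd.DataFrame(
        {"stratum": list(MULTIPLICITY_STRATA), "share": mult_share, "rate": mult_rate}
    )
    expected_rate = float(1000.0 * (probs * risks).sum())
    return age_df, mult_df, expected_rate


def generate(config: SyntheticConfig) -> tuple[BirthTable, GroundTruth]:
    """Generate a stratified birth table plus its exact design quantities.

    Deterministic given ``config.seed``.  With ``sampling=False`` the table
    carries expected (fractional) counts — no sampling noise, no missingness
    or suppression randomness beyond what the seeded generator draws.
    """
    rng = np.random.default_rng(config.seed)
    y0, y1 = config.years
    bands = list(config.age_bands)
    records: list[dict] = []
    truth_rate_rows: list[dict] = []
    designed_rows: list[dict] = []
    metadata: dict[str, CountryMeta] = {}

    for spec in config.countries:
        start = spec.first_year if spec.first_year is not None else y0
        metadata[spec.name] = CountryMeta(includes_top=spec.includes_top, first_year=start)
        for year in range(start, y1 + 1):
            probs, risks = _cell_design(config, spec, year)
            n_total = _interp(spec.births_start, spec.births_end, (year - y0) / max(y1 - y0, 1))
            if config.sampling:
                n_total = int(round(n_total))
                births = rng.multinomial(n_total, probs.ravel()).reshape(probs.shape).astype(float)
                still = rng.binomial(births.astype(int), risks).astype(float)
            else:
                births = n_total * probs
                still = births * risks
            live = births - still

            # marginalise the cross-table into the two released axis tables
            for axis, labels, ax in (
                ("maternal_age", bands, 1),
                ("multiplicity", list(MULTIPLICITY_STRATA), 0),
            ):
                sb = still.sum(axis=ax)
                lb = live.sum(axis=ax)
                for lab, s_cnt, l_cnt in zip(labels, sb, lb):
                    records.append(
                        {
                            "country": spec.name,
                            "year": year,
                            "axis": axis,
                            "stratum": lab,
                            "stillbirths": s_cnt,
                            "live_births": l_cnt,
                            "suppressed_bound": 0,
                        }
                    )

            _, _, expected_rate = _expected_summaries(config, spec, year)
            truth_rate_rows.append(
                {"country": spec.name, "year": year, "expected_rate": expected_rate}
            )

        # designed decomposition between first and last available year
        age_a, mult_a, _ = _expected_summaries(config, spec, start)
        age_b, mult_b, _ = _expected_summaries(config, spec, y1)
        for axis, pa, pb in (("maternal_age", age_a, age_b), ("multiplicity", mult_a, mult_b)):
            res = kitagawa_decompose(pa, pb)
            designed_rows.append(
                {
                    "country": spec.name,
                    "axis": axis,
                    "year_a": start,
                    "year_b": y1,
                    "delta": res.total_difference,
                    "composition": res.composition_component,
                    "rate_component": res.rate_component,
                }
            )

    df = pd.DataFrame.from_records(records)
    df = _apply_missingness(df, config, rng)
    df = _apply_suppression(df, config, rng)
    table = BirthTable(data=df, metadata=metadata)
    truth = GroundTruth(
        expected_rates=pd.DataFrame(truth_rate_rows),
        designed_decompositions=pd.DataFrame(designed_rows),
        shock_years={s.name: dict(s.covid_shock) for s in config.countries if s.covid_shock},
        config=config,
    )
    return table, truth


def _apply_missingness(df: pd.DataFrame, config: SyntheticConfig, rng) -> pd.DataFrame:
    """Move a random fraction of each record's counts to an 'unknown' stratum
    per (country, year, axis); totals per axis are conserved."""
    if config.missing_frac <= 0:
        return df
    frames = [df]
    unknown_rows = []
    for col in ("stillbirths", "live_births"):
        counts = df[col].to_numpy()
        if config.sampling:
            moved = rng.binomial(counts.astype(int), config.missing_frac).astype(float)
        else:
            moved = counts * config.missing_frac
        df[col] = counts - moved
        df[f"_moved_{col}"] = moved
    moved = (
        df.groupby(["country", "year", "axis"], as_index=False)[
            ["_moved_stillbirths", "_moved_live_births"]
        ].sum()
    )
    df.drop(columns=["_moved_stillbirths", "_moved_live_births"], inplace=True)
    moved = moved[(moved["_moved_stillbirths"] > 0) | (moved["_moved_live_births"] > 0)]
    if moved.empty:
        return df
    unknown = moved.rename(
        columns={"_moved_stillbirths": "stillbirths", "_moved_live_births": "live_births"}
    )
    unknown["stratum"] = UNKNOWN
    unknown["suppressed_bound"] = 0
    return pd.concat([df, unknown[df.columns]], ignore_index=True)


def _apply_suppression(df: pd.DataFrame, config: SyntheticConfig, rng) -> pd.DataFrame:
    """Flag stillbirth cells below the disclosure bound: the count is
    replaced by a placeholder 0 and the bound recorded."""
    k = config.suppress_below
    if k <= 0:
        return df
    mask = (df["stratum"] != UNKNOWN) & (df["stillbirths"] > 0) & (df["stillbirths"] < k)
    df.loc[mask, "stillbirths"] = 0.0
    df.loc[mask, "suppressed_bound"] = k
    return df


# --------------------------------------------------------------------------
# Default preset: a realistic 24-country study world
# --------------------------------------------------------------------------


def _shares(v: list[float]) -> dict[str, float]:
    total = sum(v)
    return {b: x / total for b, x in zip(DEFAULT_AGE_BANDS, v)}

#: Younger start structure (Baltic-like), shifting modestly older.
_YOUNG_START = _shares([0.06, 0.24, 0.32, 0.24, 0.11, 0.03])
_YOUNG_END = _shares([0.03, 0.16, 0.30, 0.30, 0.16, 0.05])
#: Older start structure (southern-European-like), shifting strongly older.
_OLD_START = _shares([0.02, 0.12, 0.28, 0.33, 0.19, 0.06])
_OLD_END = _shares([0.01, 0.08, 0.22, 0.33, 0.26, 0.10])
#: Intermediate structure.
_MID_START = _shares([0.04, 0.18, 0.30, 0.29, 0.15, 0.04])
_MID_END = _shares([0.02, 0.12, 0.26, 0.32, 0.21, 0.07])


def default_config(seed: int = 0, covid_shock: dict[str, dict[int, float]] | None = None) -> SyntheticConfig:
    """Preset mimicking the observed European ranges: 24 countries with
    annual totals from 4e3 to 8e5 births, multiple-birth shares between
    2.4% and 5.4% (mostly declining), baseline national rates roughly 2–5.5
    per 1000, a few late series starts, mild missingness and suppression.
    """
    rng = np.random.default_rng(seed)
    covid_shock = covid_shock or {}
    countries: list[CountrySpec] = []
    sizes = np.exp(rng.uniform(np.log(4e3), np.log(8e5), size=24))
    templates = [(_YOUNG_START, _YOUNG_END), (_MID_START, _MID_END), (_OLD_START, _OLD_END)]
    late_starts = {"C21": 2013, "C22": 2013, "C23": 2014, "C24": 2015}
    for i in range(24):
        name = f"C{i + 1:02d}"
        start_shares, end_shares = templates[i % 3]
        m0 = float(rng.uniform(0.024, 0.054))
        m1 = float(np.clip(m0 * rng.uniform(0.7, 1.05), 0.02, 0.06))
        growth = rng.uniform(0.92, 1.10)
        countries.append(
            CountrySpec(
                name=name,
                births_start=float(sizes[i]),
                births_end=float(sizes[i] * growth),
                age_shares_start=dict(start_shares),
                age_shares_end=dict(end_shares),
                multiple_share_start=m0,
                multiple_share_end=m1,
                first_year=late_starts.get(name),
                covid_shock=dict(covid_shock.get(name, {})),
                includes_top=(i in (0, 7)),
            )
        )
    return SyntheticConfig(
        countries=countries,
        years=(2010, 2021),
        multiple_risk_ratio=3.0,
        missing_frac=0.02,
        suppress_below=3,
        sampling=True,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
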