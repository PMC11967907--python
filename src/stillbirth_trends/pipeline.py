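"""End-to-end orchestration: repair -> rates -> trends -> anomalies ->
decompositions, emitting machine-readable report tables.

The report bundle mirrors the standard surveillance outputs:

(a) per-country trend table — MK statistic with significance stars, OLS or
    broken-line slopes, breakpoint year, score-test p;
(b) composition table — stratum shares per country/year/axis;
(c) over-time decomposition table (first available year -> final year);
(d) vs-pooled-reference decomposition table in the final year;
(e) anomaly table — robust z for the designated years;
(f) a JSON run manifest echoing configuration and seed.

Failures are contained per country: a country whose series is too short for
one step is reported in the manifest and the run continues.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import synthetic
from .errors import StillbirthTrendsError
from .kitagawa import decompose_over_time, decompose_vs_reference
from .repair import repair
from .tables import AXES, BirthTable, read_table, rate_series, validation_report
from .trends import fit_segmented, mk_test, robust_anomaly, significance_stars

logger = logging.getLogger("stillbirth_trends")

EXIT_OK = 0
EXIT_VALIDATION = 2
EXIT_PARTIAL = 3


@dataclass
class RunConfig:
    """Pipeline configuration; CLI flags override config-file values."""

    input_path: str | None = None
    preset: str | None = None  # 'default' -> synthetic study world
    axes: tuple[str, ...] = AXES
    year_a: int | None = None  # None -> per-country first available year
    year_b: int = 2021
    alpha: float = 0.05
    min_segment: int = 3
    anomaly_years: tuple[int, ...] = (2020, 2021)
    anomaly_threshold: float = 2.0
    impute_bound: int | None = None
    out_dir: str = "results"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")


@dataclass
class ReportBundle:
    trend_table: pd.DataFrame
    composition_table: pd.DataFrame
    over_time_table: pd.DataFrame
    vs_reference_table: pd.DataFrame
    anomaly_table: pd.DataFrame
    manifest: dict = field(default_factory=dict)

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.trend_table.to_csv(out / "trends.csv", index=False)
        self.composition_table.to_csv(out / "composition.csv", index=False)
        self.over_time_table.to_csv(out / "decomposition_over_time.csv", index=False)
        self.vs_reference_table.to_csv(out / "decomposition_vs_reference.csv", index=False)
        self.anomaly_table.to_csv(out / "anomalies.csv", index=False)
        with open(out / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=2, sort_keys=True)


def load_input(config: RunConfig) -> BirthTable:
    if config.input_path:
        return read_table(config.input_path)
    if config.preset:
        table, _ = synthetic.generate(synthetic.default_config(seed=config.seed))
        return table
    raise StillbirthTrendsError("RunConfig needs input_path or preset")


def trend_table(
    table: BirthTable,
    axis: str = "maternal_age",
    alpha: float = 0.05,
    min_segment: int = 3,
    anomaly_years: tuple[int, ...] = (2020, 2021),
    threshold: float = 2.0,
    errors: list | None = None,
) -> pd.DataFrame:
    """Per-country trend battery on the national series of one axis."""
    rows = []
    for country in table.countries:
        try:
            series = rate_series(table, country, axis)
            mk = mk_test(series)
            fit = fit_segmented(series, alpha=alpha, min_segment=min_segment)
            anomalies = {a.year: a for a in robust_anomaly(series, anomaly_years, threshold)}
            direction = "stable"
            if mk.p < alpha:
                direction = "increasing" if mk.S > 0 else "decreasing"
            row = {
                "country": country,
                "mk_S": mk.S,
                "mk_z": mk.z,
                "mk_p": mk.p,
                "mk_stars": significance_stars(mk.p),
                "trend_class": f"{direction}/{fit.kind}",
                "slope1": fit.slopes[0],
                "slope2": fit.slopes[1] if fit.kind == "segmented" else None,
                "breakpoint_year": fit.breakpoint_year,
                "score_p": fit.score_test_p,
            }
            for y in anomaly_years:
                a = anomalies.get(y)
                row[f"z_{y}"] = a.robust_z if a else None
                row[f"flag_{y}"] = a.flagged if a else None
            rows.append(row)
        except StillbirthTrendsError as exc:
            if errors is not None:
                errors.append({"step": "trends", "country": country, "error": str(exc)})
            logger.warning("trends failed for %s: %s", country, exc)
    return pd.DataFrame(rows)


def composition_table(table: BirthTable) -> pd.DataFrame:
    """Stratum shares of total births per (country, year, axis)."""
    df = table.data.copy()
    df["births"] = df["stillbirths"] + df["live_births"]
    totals = df.groupby(["country", "year", "axis"])["births"].transform("sum")
    df["share"] = df["births"] / totals
    return df[["country", "year", "axis", "stratum", "births", "share"]].sort_values(
        ["country", "year", "axis", "stratum"], ignore_index=True
    )


def _decomposition_rows(result) -> list[dict]:
    base = result.as_dict()
    rows = [dict(base, stratum="(all)", stratum_composition=None, stratum_rate=None)]
    for _, r in result.per_stratum.iterrows():
        rows.append(
            dict(
                base,
                stratum=r["stratum"],
                stratum_composition=r["composition"],
                stratum_rate=r["rate"],
            )
        )
    return rows


def decomposition_tables(
    table: BirthTable,
    axes: tuple[str, ...] = AXES,
    year_a: int | None = None,
    year_b: int = 2021,
    errors: list | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Long-format over-time and vs-reference decomposition tables."""
    over_rows: list[dict] = []
    ref_rows: list[dict] = []
    for axis in axes:
        axis_countries = sorted(
            table.data.loc[table.data["axis"] == axis, "country"].unique()
        )
        for country in axis_countries:
            try:
                res = decompose_over_time(table, country, axis, year_a=year_a, year_b=year_b)
                over_rows.extend(_decomposition_rows(res))
            except StillbirthTrendsError as exc:
                if errors is not None:
                    errors.append(
                        {"step": "decompose_over_time", "country": country, "axis": axis,
                         "error": str(exc)}
                    )
                logger.warning("over-time decomposition failed for %s/%s: %s", country, axis, exc)
        ref_pool = [
            c for c in axis_countries if not table.subset(c, year_b, axis).empty
        ]
        for country in ref_pool:
            try:
                res = decompose_vs_reference(table, country, axis, year_b, countries=ref_pool)
                ref_rows.extend(_decomposition_rows(res))
            except StillbirthTrendsError as exc:
                if errors is not None:
                    errors.append(
                        {"step": "decompose_vs_reference", "country": country, "axis": axis,
                         "error": str(exc)}
                    )
                logger.warning("vs-reference decomposition failed for %s/%s: %s", country, axis, exc)
    return pd.DataFrame(over_rows), pd.DataFrame(ref_rows)


def run(config: RunConfig) -> tuple[ReportBundle, int]:
    """Execute the full pipeline; returns the bundle and an exit code
    (0 ok, 2 validation failure, 3 partial per-country failures)."""
    errors: list[dict] = []
    try:
        raw = load_input(config)
    except StillbirthTrendsError as exc:
        logger.error("input failed validation: %s", exc)
        raise

    report = validation_report(raw)
    table = repair(raw, bound=config.impute_bound, seed=config.seed)

    trend_frames = []
    for axis in config.axes:
        tf = trend_table(
            table,
            axis=axis,
            alpha=config.alpha,
            min_segment=config.min_segment,
            anomaly_years=config.anomaly_years,
            threshold=config.anomaly_threshold,
            errors=errors,
        )
        if not tf.empty:
            tf.insert(1, "axis", axis)
        trend_frames.append(tf)
    trends = pd.concat(trend_frames, ignore_index=True) if trend_frames else pd.DataFrame()

    over_time, vs_reference = decomposition_tables(
        table, axes=config.axes, year_a=config.year_a, year_b=config.year_b, errors=errors
    )
    anomaly_cols = ["country", "axis"] + [
        c for c in trends.columns if c.startswith(("z_", "flag_"))
    ]
    anomalies = trends[anomaly_cols].copy() if not trends.empty else pd.DataFrame()

    manifest = {
        "config": {
            "input_path": config.input_path,
            "preset": config.preset,
            "axes": list(config.axes),
            "year_a": config.year_a,
            "year_b": config.year_b,
            "alpha": config.alpha,
            "anomaly_years": list(config.anomaly_years),
            "anomaly_threshold": config.anomaly_threshold,
            "seed": config.seed,
        },
        "validation": report,
        "errors": errors,
        "n_countries": len(table.countries),
    }
    bundle = ReportBundle(
        trend_table=trends,
        composition_table=composition_table(table),
        over_time_table=over_time,
        vs_reference_table=vs_reference,
        anomaly_table=anomalies,
        manifest=manifest,
    )
    code = EXIT_PARTIAL if errors else EXIT_OK
    if len(table.countries) == 0:
        logger.warning("empty input: emitting empty tables")
    return bundle, code
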