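import numpy as np
import pandas as pd
import pytest

from stillbirth_trends import BirthTable, RateSeries


def make_records(country, year, axis, strata, stillbirths, live_births):
    return [
        {
            "country": country,
            "year": year,
            "axis": axis,
            "stratum": s,
            "stillbirths": sb,
            "live_births": lb,
        }
        for s, sb, lb in zip(strata, stillbirths, live_births)
    ]


@pytest.fixture
def two_country_table():
    """Two countries, one year, both axes, internally consistent totals."""
    rows = []
    for country, sb_age, lb_age in (
        ("AA", [2, 3], [998, 997]),
        ("BB", [5, 5], [1995, 1995]),
    ):
        rows += make_records(country, 2021, "maternal_age", ["25-29", "30-34"], sb_age, lb_age)
        total_sb, total_lb = sum(sb_age), sum(lb_age)
        rows += make_records(
            country, 2021, "multiplicity", ["singleton", "multiple"],
            [total_sb - 1, 1], [total_lb - 30, 30],
        )
    return BirthTable(data=pd.DataFrame(rows))


@pytest.fixture
def multi_year_table():
    """One country over 12 years with a gently rising age-axis rate."""
    rows = []
    for i, year in enumerate(range(2010, 2022)):
        sb = [10 + i, 20 + 2 * i]
        lb = [5000 - sb[0], 5000 - sb[1]]
        rows += make_records("CC", year, "maternal_age", ["25-29", "35-39"], sb, lb)
    return BirthTable(data=pd.DataFrame(rows))


def series_from(years, rates):
    years = np.asarray(years)
    return RateSeries("T", years, np.asarray(rates, float), np.full(len(years), 1000.0))


@pytest.fixture
def series_factory():
    return series_from
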