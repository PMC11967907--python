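"""Kitagawa decomposition: hand-checked examples and exact invariants."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from stillbirth_trends import (
    BirthTable,
    ValidationError,
    decompose_over_time,
    decompose_vs_reference,
    kitagawa_decompose,
    pooled_reference,
    summarize_population,
)


def pop(strata, shares, rates):
    return pd.DataFrame({"stratum": strata, "share": shares, "rate": rates})


def random_pop(rng, strata):
    shares = rng.dirichlet(np.ones(len(strata)))
    rates = rng.uniform(0, 12, len(strata))
    return pop(strata, shares, rates)


class TestKitagawaDecompose:
    def test_identical_populations_zero(self):
        p = pop(["a", "b"], [0.7, 0.3], [3.0, 9.0])
        res = kitagawa_decompose(p, p)
        assert res.total_difference == pytest.approx(0.0, abs=1e-12)
        assert res.composition_component == pytest.approx(0.0, abs=1e-12)
        assert res.rate_component == pytest.approx(0.0, abs=1e-12)

    def test_pure_composition_shift_hand_value(self):
        # shares 0.9/0.1 -> 0.8/0.2, rates (3, 9) frozen:
        # delta = (0.8*3+0.2*9) - (0.9*3+0.1*9) = 4.2 - 3.6 = 0.6, all composition
        a = pop(["a", "b"], [0.9, 0.1], [3.0, 9.0])
        b = pop(["a", "b"], [0.8, 0.2], [3.0, 9.0])
        res = kitagawa_decompose(a, b)
        assert res.total_difference == pytest.approx(0.6)
        assert res.composition_component == pytest.approx(0.6)
        assert res.rate_component == pytest.approx(0.0, abs=1e-12)

    def test_offsetting_rate_changes_per_stratum_contributions(self):
        # equal shares; rates (3,9) -> (4,8): delta = 0 but stratum rate
        # contributions are (+0.5, -0.5)
        a = pop(["a", "b"], [0.5, 0.5], [3.0, 9.0])
        b = pop(["a", "b"], [0.5, 0.5], [4.0, 8.0])
        res = kitagawa_decompose(a, b)
        assert res.total_difference == pytest.approx(0.0, abs=1e-12)
        assert res.composition_component == pytest.approx(0.0, abs=1e-12)
        contrib = res.per_stratum.set_index("stratum")["rate"]
        assert contrib["a"] == pytest.approx(0.5)
        assert contrib["b"] == pytest.approx(-0.5)

    def test_stratum_on_one_side_contributes_via_composition_only(self):
        a = pop(["a"], [1.0], [3.0])
        b = pop(["a", "b"], [0.9, 0.1], [3.0, 9.0])
        res = kitagawa_decompose(a, b)
        row = res.per_stratum.set_index("stratum").loc["b"]
        assert row["rate"] == pytest.approx(0.0, abs=1e-12)
        assert res.total_difference == pytest.approx(
            res.composition_component + res.rate_component, abs=1e-9
        )

    def test_shares_not_summing_to_one_rejected(self):
        bad = pop(["a", "b"], [0.6, 0.6], [3.0, 9.0])
        good = pop(["a", "b"], [0.5, 0.5], [3.0, 9.0])
        with pytest.raises(ValidationError):
            kitagawa_decompose(bad, good)

    @settings(max_examples=300, deadline=None)
    @given(seed=hst.integers(0, 2**31 - 1), k=hst.integers(2, 6))
    def test_additivity_and_antisymmetry(self, seed, k):
        rng = np.random.default_rng(seed)
        strata = [f"s{i}" for i in range(k)]
        a, b = random_pop(rng, strata), random_pop(rng, strata)
        fwd = kitagawa_decompose(a, b)
        rev = kitagawa_decompose(b, a)
        assert fwd.composition_component + fwd.rate_component == pytest.approx(
            fwd.total_difference, abs=1e-9
        )
        assert fwd.per_stratum["composition"].sum() == pytest.approx(
            fwd.composition_component, abs=1e-9
        )
        assert fwd.per_stratum["rate"].sum() == pytest.approx(fwd.rate_component, abs=1e-9)
        assert rev.total_difference == pytest.approx(-fwd.total_difference, abs=1e-12)
        assert rev.composition_component == pytest.approx(-fwd.composition_component, abs=1e-12)
        assert rev.rate_component == pytest.approx(-fwd.rate_component, abs=1e-12)

    @settings(max_examples=100, deadline=None)
    @given(seed=hst.integers(0, 2**31 - 1))
    def test_null_components(self, seed):
        rng = np.random.default_rng(seed)
        strata = ["a", "b", "c"]
        shares = rng.dirichlet(np.ones(3))
        rates1, rates2 = rng.uniform(0, 10, 3), rng.uniform(0, 10, 3)
        equal_shares = kitagawa_decompose(
            pop(strata, shares, rates1), pop(strata, shares, rates2)
        )
        assert equal_shares.composition_component == pytest.approx(0.0, abs=1e-12)
        shares2 = rng.dirichlet(np.ones(3))
        equal_rates = kitagawa_decompose(
            pop(strata, shares, rates1), pop(strata, shares2, rates1)
        )
        assert equal_rates.rate_component == pytest.approx(0.0, abs=1e-12)


class TestSummaries:
    def test_single_stratum_share_one(self, two_country_table):
        one = BirthTable(
            data=two_country_table.data[
                (two_country_table.data["axis"] == "multiplicity")
                & (two_country_table.data["stratum"] == "singleton")
            ]
        )
        s = summarize_population(one, "AA", 2021, "multiplicity")
        assert s["share"].tolist() == [1.0]

    def test_equal_strata_half_shares(self, two_country_table):
        s = summarize_population(two_country_table, "BB", 2021, "maternal_age")
        assert s["share"].tolist() == pytest.approx([0.5, 0.5])

    def test_shares_sum_to_one(self, two_country_table):
        for axis in ("maternal_age", "multiplicity"):
            s = summarize_population(two_country_table, "AA", 2021, axis)
            assert s["share"].sum() == pytest.approx(1.0, abs=1e-12)

    def test_scale_invariance_of_decomposition(self, two_country_table):
        res1 = decompose_vs_reference(two_country_table, "AA", "maternal_age", 2021)
        scaled = two_country_table.replace_data(
            two_country_table.data.assign(
                stillbirths=lambda d: d["stillbirths"] * 7,
                live_births=lambda d: d["live_births"] * 7,
            )
        )
        res2 = decompose_vs_reference(scaled, "AA", "maternal_age", 2021)
        assert res2.total_difference == pytest.approx(res1.total_difference, abs=1e-12)
        assert res2.composition_component == pytest.approx(res1.composition_component, abs=1e-12)


class TestPooledReference:
    def test_single_country_identity(self, two_country_table):
        own = summarize_population(two_country_table, "AA", 2021, "maternal_age")
        pooled = pooled_reference(two_country_table, 2021, "maternal_age", ["AA"])
        pd.testing.assert_frame_equal(own, pooled)

    def test_equal_sized_countries_average(self):
        rows = []
        for c, sb in (("X", 2), ("Y", 4)):
            rows.append(
                {"country": c, "year": 2021, "axis": "multiplicity", "stratum": "singleton",
                 "stillbirths": sb, "live_births": 1000 - sb}
            )
        pooled = pooled_reference(BirthTable(data=pd.DataFrame(rows)), 2021, "multiplicity")
        assert pooled["rate"].iloc[0] == pytest.approx(3.0)

    def test_birth_weighted_pooling_not_mean_of_rates(self):
        rows = []
        for c, sb, total in (("X", 2, 1000), ("Y", 12, 3000)):
            rows.append(
                {"country": c, "year": 2021, "axis": "multiplicity", "stratum": "singleton",
                 "stillbirths": sb, "live_births": total - sb}
            )
        pooled = pooled_reference(BirthTable(data=pd.DataFrame(rows)), 2021, "multiplicity")
        assert pooled["rate"].iloc[0] == pytest.approx(3.5)  # (2+12)/4000 * 1000


class TestHighLevelDecompositions:
    def test_same_year_over_time_is_zero(self, two_country_table):
        res = decompose_over_time(two_country_table, "AA", "maternal_age", 2021, 2021)
        assert res.total_difference == pytest.approx(0.0, abs=1e-12)

    def test_composition_only_world(self):
        rows = []
        # stratum rates frozen at 2 and 8 per 1000; only shares move
        for year, split in ((2010, (0.8, 0.2)), (2021, (0.6, 0.4))):
            for stratum, share, rate in zip(("young", "old"), split, (2.0, 8.0)):
                births = 10000 * share
                sb = births * rate / 1000
                rows.append(
                    {"country": "Z", "year": year, "axis": "maternal_age",
                     "stratum": stratum, "stillbirths": sb, "live_births": births - sb}
                )
        res = decompose_over_time(BirthTable(data=pd.DataFrame(rows)), "Z", "maternal_age")
        assert res.rate_component == pytest.approx(0.0, abs=1e-12)
        assert res.composition_component == pytest.approx(res.total_difference, abs=1e-12)
        assert res.total_difference == pytest.approx(1.2)  # (0.6*2+0.4*8)-(0.8*2+0.2*8)

    def test_constructed_components_recovered(self):
        # construction oracle: choose C and M for both years, build counts,
        # expect the decomposition to return the hand-computed components
        c_a, c_b = np.array([0.7, 0.3]), np.array([0.55, 0.45])
        m_a, m_b = np.array([3.0, 6.0]), np.array([2.5, 5.0])
        expected_comp = float(((c_b - c_a) * (m_b + m_a) / 2).sum())
        expected_rate = float(((m_b - m_a) * (c_b + c_a) / 2).sum())
        rows = []
        for year, shares, rates in ((2010, c_a, m_a), (2021, c_b, m_b)):
            for stratum, share, rate in zip(("a", "b"), shares, rates):
                births = 1e6 * share
                sb = births * rate / 1000
                rows.append(
                    {"country": "W", "year": year, "axis": "maternal_age",
                     "stratum": stratum, "stillbirths": sb, "live_births": births - sb}
                )
        res = decompose_over_time(BirthTable(data=pd.DataFrame(rows)), "W", "maternal_age")
        assert res.composition_component == pytest.approx(expected_comp, abs=1e-9)
        assert res.rate_component == pytest.approx(expected_rate, abs=1e-9)

    def test_country_equal_to_reference_is_zero(self, two_country_table):
        res = decompose_vs_reference(
            two_country_table, "AA", "maternal_age", 2021, countries=["AA"]
        )
        assert res.total_difference == pytest.approx(0.0, abs=1e-12)

    def test_sign_convention_country_minus_reference(self, two_country_table):
        res = decompose_vs_reference(two_country_table, "AA", "maternal_age", 2021)
        assert res.role_labels["country_minus_reference"] == pytest.approx(
            -res.total_difference
        )
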