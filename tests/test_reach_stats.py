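"""Stratum proportions, reach ratios and log-scale Wald intervals."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import reachra as rr
from reachra.core import AreaCategory, CATEGORY_ORDER

LM, SM, NM = CATEGORY_ORDER


def _classified(counts: dict[AreaCategory, int], year=2013) -> pd.DataFrame:
    rows = []
    for cat, k in counts.items():
        rows += [(f"u{len(rows) + i}", year, cat.value) for i in range(k)]
    return pd.DataFrame(rows, columns=["user_id", "year", "category"])


class TestStratumTables:
    def test_cohort_proportions_exclude_unclassified(self):
        df = _classified({LM: 5, SM: 3, NM: 2, AreaCategory.UNCLASSIFIED: 4})
        t = rr.cohort_proportions(df, 2013)
        assert t.n == 10
        assert t.proportion(LM) == pytest.approx(0.5)
        assert t.proportion(SM) == pytest.approx(0.3)
        assert t.proportion(NM) == pytest.approx(0.2)

    def test_all_unclassified_is_an_error(self):
        df = _classified({AreaCategory.UNCLASSIFIED: 3})
        with pytest.raises(rr.EmptyStratumError):
            rr.cohort_proportions(df, 2013)

    def test_reference_proportions_from_counts(self):
        ref = pd.DataFrame(
            {
                "year": 2013,
                "category": [LM.value, SM.value, NM.value],
                "smokers_thousands": [1, 1, 2],
            }
        )
        t = rr.reference_proportions(ref, 2013)
        assert t.proportion(LM) == pytest.approx(0.25)
        assert t.proportion(NM) == pytest.approx(0.5)

    def test_missing_category_is_typed(self):
        ref = pd.DataFrame(
            {"year": [2013, 2013], "category": [LM.value, SM.value], "smokers_thousands": [1, 1]}
        )
        with pytest.raises(rr.MissingCategoryError):
            rr.reference_proportions(ref, 2013)

    def test_large_metro_2016_share_of_us_smokers(self, reference_counts):
        # 25,259 thousand of the 51,333 thousand US smokers -> 49.2%
        t = rr.reference_proportions(reference_counts, 2016)
        assert round(100 * t.proportion(LM), 1) == 49.2

    def test_sampled_proportions_near_truth(self):
        # multinomial draw at the 2013 stratum probabilities stays within 3 SE
        probs = np.array([0.4886, 0.3316, 0.1798])
        n = 33484
        counts = np.random.default_rng(2013).multinomial(n, probs)
        t = rr.StratumTable.from_counts(
            2013, dict(zip(CATEGORY_ORDER, counts.astype(float)))
        )
        for cat, p in zip(CATEGORY_ORDER, probs):
            se = math.sqrt(p * (1 - p) / n)
            assert abs(t.proportion(cat) - p) < 3 * se


class TestReachRatio:
    @pytest.mark.parametrize(
        "p1,p2,expected_2dp",
        [
            (0.1798, 0.2023, 0.89),  # Nonmetro 2013
            (0.3670, 0.3199, 1.15),  # Small Metro 2016
            (0.5, 0.5, 1.0),
        ],
    )
    def test_point_estimates(self, p1, p2, expected_2dp):
        assert rr.round_half_even(rr.reach_ratio(p1, p2), 2) == expected_2dp

    def test_zero_reference_is_undefined(self):
        with pytest.raises(rr.UndefinedRatioError):
            rr.reach_ratio(0.1, 0.0)


class TestFixedReferenceInterval:
    @pytest.mark.parametrize(
        "p1,n1,p2,expected",
        [
            (0.1798, 33484, 0.2023, (0.87, 0.91)),  # Nonmetro 2013
            (0.2111, 8832, 0.1817, (1.12, 1.21)),  # Nonmetro 2017
            (0.1945, 1820, 0.1880, (0.94, 1.14)),  # Nonmetro 2016
        ],
    )
    def test_published_endpoints(self, p1, n1, p2, expected):
        lo, hi = rr.reach_ratio_ci(p1, n1, p2)
        assert (rr.round_half_even(lo), rr.round_half_even(hi)) == expected

    def test_interval_shrinks_to_point_with_n(self):
        lo, hi = rr.reach_ratio_ci(0.5, 10**9, 0.5)
        assert lo == pytest.approx(1.0, abs=1e-4)
        assert hi == pytest.approx(1.0, abs=1e-4)

    @pytest.mark.parametrize("p1", [0.0, 1.0])
    def test_degenerate_proportion_rejected(self, p1):
        with pytest.raises(rr.DegenerateProportionError):
            rr.reach_ratio_ci(p1, 100, 0.5)

    @given(
        p1=st.floats(0.01, 0.99),
        n1=st.integers(2, 10**6),
        p2=st.floats(0.01, 0.99),
    )
    def test_log_symmetry(self, p1, n1, p2):
        # on the log scale the interval is symmetric: lo * hi == ReRa^2
        lo, hi = rr.reach_ratio_ci(p1, n1, p2)
        assert lo * hi == pytest.approx(rr.reach_ratio(p1, p2) ** 2, rel=1e-9)
        assert lo <= rr.reach_ratio(p1, p2) <= hi

    @given(
        p1=st.floats(0.05, 0.95),
        p2=st.floats(0.05, 0.95),
        n1=st.integers(10, 10**5),
    )
    def test_width_strictly_decreasing_in_n(self, p1, p2, n1):
        lo1, hi1 = rr.reach_ratio_ci(p1, n1, p2)
        lo2, hi2 = rr.reach_ratio_ci(p1, 2 * n1, p2)
        assert hi2 - lo2 < hi1 - lo1


class TestTwoSampleInterval:
    @given(
        p1=st.floats(0.05, 0.95),
        n1=st.integers(10, 10**5),
        p2=st.floats(0.05, 0.95),
        n2=st.integers(10, 10**5),
    )
    def test_contains_fixed_reference_interval(self, p1, n1, p2, n2):
        flo, fhi = rr.reach_ratio_ci(p1, n1, p2)
        tlo, thi = rr.reach_ratio_ci_two_sample(p1, n1, p2, n2)
        assert tlo <= flo and thi >= fhi

    def test_converges_to_fixed_reference_as_n2_grows(self):
        flo, fhi = rr.reach_ratio_ci(0.3, 500, 0.25)
        tlo, thi = rr.reach_ratio_ci_two_sample(0.3, 500, 0.25, 10**12)
        assert tlo == pytest.approx(flo, rel=1e-5)
        assert thi == pytest.approx(fhi, rel=1e-5)

    def test_matches_parametric_bootstrap(self):
        """Closed form vs a 100,000-replicate bootstrap of two binomials."""
        rng = np.random.default_rng(12345)
        n = 100_000
        ratio = (rng.binomial(200, 0.55, n) / 200) / (rng.binomial(200, 0.50, n) / 200)
        boot_lo, boot_hi = np.quantile(ratio, [0.025, 0.975])
        lo, hi = rr.reach_ratio_ci_two_sample(0.55, 200, 0.50, 200)
        assert lo == pytest.approx(boot_lo, abs=0.02)
        assert hi == pytest.approx(boot_hi, abs=0.02)


class TestReachTable:
    def _tables(self):
        cohort = {
            2016: rr.StratumTable.from_counts(
                2016, {LM: 798.0, SM: 668.0, NM: 354.0}
            )
        }
        ref = {2016: rr.StratumTable.from_counts(2016, {LM: 492.0, SM: 320.0, NM: 188.0})}
        return cohort, ref

    def test_one_result_per_year_and_category(self):
        cohort, ref = self._tables()
        results = rr.reach_table(cohort, ref)
        assert [(r.year, r.category) for r in results] == [
            (2016, c) for c in CATEGORY_ORDER
        ]

    def test_significance_iff_interval_excludes_one(self):
        cohort, ref = self._tables()
        for r in rr.reach_table(cohort, ref):
            assert r.significant == (not (r.ci_low <= 1.0 <= r.ci_high))

    def test_identical_distributions_give_unit_ratios(self):
        t = rr.StratumTable.from_counts(2015, {LM: 50.0, SM: 30.0, NM: 20.0})
        results = rr.reach_table({2015: t}, {2015: t})
        assert all(r.rera == pytest.approx(1.0) for r in results)
        assert not any(r.significant for r in results)

    def test_year_mismatch_lists_missing_years(self):
        cohort, ref = self._tables()
        cohort[2017] = cohort[2016]
        with pytest.raises(rr.YearMismatchError) as exc:
            rr.reach_table(cohort, ref)
        assert exc.value.missing_in_reference == (2017,)

    @given(
        counts1=st.tuples(*[st.integers(1, 10**5)] * 3),
        counts2=st.tuples(*[st.integers(1, 10**5)] * 3),
    )
    @settings(max_examples=50)
    def test_weighted_mean_of_ratios_is_one(self, counts1, counts2):
        # sum over strata of p2 * ReRa telescopes back to sum of p1 = 1
        c = rr.StratumTable.from_counts(2013, dict(zip(CATEGORY_ORDER, map(float, counts1))))
        r = rr.StratumTable.from_counts(2013, dict(zip(CATEGORY_ORDER, map(float, counts2))))
        results = rr.reach_table({2013: c}, {2013: r})
        total = sum(res.rera * r.proportion(res.category) for res in results)
        assert total == pytest.approx(1.0, rel=1e-12)


class TestConfig:
    def test_alpha_bounds_enforced(self):
        with pytest.raises(rr.ReachraError):
            rr.AnalysisConfig(alpha=1.5)

    def test_z_derived_from_alpha_when_unset(self):
        cfg = rr.AnalysisConfig(alpha=0.05, z=None)
        assert cfg.critical_value == pytest.approx(1.959964, abs=1e-6)

    def test_two_sample_variant_widens_table_intervals(self):
        c = rr.StratumTable.from_counts(2013, {LM: 500.0, SM: 300.0, NM: 200.0})
        r = rr.StratumTable.from_counts(2013, {LM: 480.0, SM: 320.0, NM: 200.0})
        fixed = rr.reach_table({2013: c}, {2013: r})
        two = rr.reach_table(
            {2013: c}, {2013: r}, rr.AnalysisConfig(interval_variant="two_sample")
        )
        for f, t in zip(fixed, two):
            assert t.ci_low <= f.ci_low and t.ci_high >= f.ci_high
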