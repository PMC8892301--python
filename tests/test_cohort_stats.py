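import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from vestwear.cohort_stats import (
    build_cohort_table,
    fisher_exact_2x2,
    format_p,
    mann_whitney_u,
    route_test,
    spearman_rho,
    welch_t_test,
)


def enumerate_fisher(table):
    """Exact-rational enumeration of the probability-ordering two-sided p."""
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def comb(m, k):
        return Fraction(math.comb(m, k))

    denom = comb(n, c1)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    probs = {k: comb(r1, k) * comb(r2, c1 - k) / denom for k in range(lo, hi + 1)}
    p_obs = probs[a]
    return float(sum(p for p in probs.values() if p <= p_obs))


class TestFisherExact:
    def test_symmetric_table_is_one(self):
        assert fisher_exact_2x2([[5, 5], [5, 5]]) == pytest.approx(1.0)

    def test_zero_margin_convention(self):
        assert fisher_exact_2x2([[0, 0], [3, 4]]) == 1.0
        assert fisher_exact_2x2([[0, 3], [0, 4]]) == 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[-1, 2], [3, 4]])

    def test_non_integer_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[1.5, 2], [3, 4]])

    @given(
        a=st.integers(0, 12), b=st.integers(0, 12),
        c=st.integers(0, 12), d=st.integers(0, 12),
    )
    @settings(max_examples=300, derandomize=True, deadline=None)
    def test_matches_exact_enumeration_and_symmetries(self, a, b, c, d):
        table = [[a, b], [c, d]]
        p = fisher_exact_2x2(table)
        assert p == pytest.approx(enumerate_fisher(table), rel=1e-9)
        assert p == pytest.approx(fisher_exact_2x2([[c, d], [a, b]]), rel=1e-9)  # row swap
        assert p == pytest.approx(fisher_exact_2x2([[a, c], [b, d]]), rel=1e-9)  # transpose

    def test_matches_scipy_on_random_tables(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            t = rng.integers(0, 60, size=(2, 2))
            assert fisher_exact_2x2(t) == pytest.approx(
                sps.fisher_exact(t)[1], rel=1e-8, abs=1e-12
            )


class TestWelchT:
    def test_identical_samples(self):
        stat, p = welch_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_closed_form_oracle(self):
        a = np.array([19.8, 20.4, 19.6, 17.8, 18.5, 18.9, 18.3, 18.9, 19.5, 22.0])
        b = np.array([28.2, 26.6, 20.1, 23.3, 25.2, 22.1, 17.7, 27.6, 20.6, 13.7, 23.2, 17.5])
        ma, mb = a.mean(), b.mean()
        va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
        t = (ma - mb) / math.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
        p = 2 * sps.t.sf(abs(t), df)
        stat, pval = welch_t_test(a, b)
        assert stat == pytest.approx(t, abs=1e-10)
        assert pval == pytest.approx(p, abs=1e-10)

    def test_degenerate_variance_rejected(self):
        with pytest.raises(ValueError):
            welch_t_test([1.0, 1.0], [2.0, 2.0])

    def test_type_one_error_near_nominal(self):
        rng = np.random.default_rng(42)
        rejections = sum(
            welch_t_test(rng.normal(0, 1, 50), rng.normal(0, 1, 50))[1] < 0.05
            for _ in range(1000)
        )
        ci = 1.96 * math.sqrt(0.05 * 0.95 / 1000)
        assert abs(rejections / 1000 - 0.05) < ci + 1e-12


class TestMannWhitney:
    def test_fully_separated_small_samples_exact(self):
        stat, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert stat in (0.0, 9.0)
        assert p == pytest.approx(0.1)  # 2 of the 20 equally likely orderings

    def test_sample_against_itself(self):
        x = [1.0, 2.5, 3.1, 4.7, 5.2, 8.8, 9.9, 11.0]
        _, p = mann_whitney_u(x, x)
        assert p > 0.9

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])

    def test_type_one_error_near_nominal(self):
        rng = np.random.default_rng(7)
        rejections = sum(
            mann_whitney_u(rng.exponential(1, 40), rng.exponential(1, 40))[1] < 0.05
            for _ in range(1000)
        )
        ci = 1.96 * math.sqrt(0.05 * 0.95 / 1000)
        assert abs(rejections / 1000 - 0.05) < ci + 1e-12


class TestSpearman:
    def test_perfect_monotone(self):
        r = spearman_rho([1, 2, 3, 4], [10, 20, 25, 70])
        assert r.rho == pytest.approx(1.0)
        x = np.arange(10.0)
        assert spearman_rho(x, -x).rho == pytest.approx(-1.0)

    def test_constant_vector_undefined(self):
        r = spearman_rho([1.0, 1.0, 1.0, 1.0], [1, 2, 3, 4])
        assert math.isnan(r.rho)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=30)
        y = x + rng.normal(size=30)
        base = spearman_rho(x, y)
        warped = spearman_rho(np.exp(x), y**3)
        assert warped.rho == pytest.approx(base.rho)
        assert warped.p_value == pytest.approx(base.p_value)

    def test_nan_pairs_dropped(self):
        x = [1.0, 2.0, np.nan, 4.0, 5.0]
        y = [2.0, 3.0, 9.0, 5.0, 6.0]
        assert spearman_rho(x, y).n == 4


class TestRouting:
    def test_normal_samples_get_welch(self):
        rng = np.random.default_rng(0)
        cmp = route_test("v", rng.normal(10, 2, 40), rng.normal(11, 2, 40))
        assert cmp.test == "welch_t"
        assert "(" in cmp.group_a_stat  # mean (SD)

    def test_skewed_samples_get_mann_whitney(self):
        rng = np.random.default_rng(0)
        cmp = route_test("v", rng.lognormal(0, 1.5, 60), rng.lognormal(0, 1.5, 60))
        assert cmp.test == "mann_whitney"
        assert "-" in cmp.group_a_stat  # median (IQR)

    def test_binary_variable_gets_fisher(self):
        cmp = route_test("v", [True] * 5 + [False] * 10, [True] * 9 + [False] * 2,
                         kind="categorical")
        assert cmp.test == "fisher"
        assert cmp.p_value == pytest.approx(fisher_exact_2x2([[5, 10], [9, 2]]))

    def test_tiny_group_falls_back_to_mann_whitney(self):
        cmp = route_test("v", [1.0, 2.0], [3.0, 4.0, 5.0, 6.0])
        assert cmp.test == "mann_whitney"


class TestFormatP:
    @pytest.mark.parametrize(
        "p,expected",
        [
            (0.0004, "<.001"),
            (0.995, ">.99"),
            (0.5, ".50"),
            (0.045, ".045"),
            (0.003, ".003"),
            (0.02, ".02"),
            (0.26, ".26"),
            (1.0, ">.99"),
            (0.001, ".001"),
        ],
    )
    def test_journal_convention(self, p, expected):
        assert format_p(p) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            format_p(1.2)
        with pytest.raises(ValueError):
            format_p(-0.1)

    def test_guards_round_trip(self):
        # "<.001" only below .001, ">.99" only above .99
        assert format_p(0.00099) == "<.001"
        assert format_p(0.0011) != "<.001"
        assert format_p(0.9899) != ">.99"


class TestCohortTable:
    def _identical_cohort(self, n_a=5, n_b=6):
        rows = []
        for i in range(n_a + n_b):
            rows.append(
                {
                    "participant_id": f"P{i:02d}",
                    "group": "AECOPD" if i < n_a else "Stable",
                    "age": 65.0, "sex": "male", "bmi": 26.0,
                    "chest_circumference_in": 38.0, "waist_circumference_cm": 95.0,
                    "fev1_pct_pred": 50.0, "mrc_grade": 3, "oversized_vest": False,
                }
            )
        meta = pd.DataFrame(rows)
        parts = pd.DataFrame(
            {
                "participant_id": meta["participant_id"],
                "days_worn": 40, "pct_protocol_worn": 100 * 40 / 42,
                "weekly_category": ">5", "longest_consecutive_days": 40,
                "missing_day_occasions": 1, "any_battery_depletion": False,
                "mean_daily_wear_hours": 12.0, "hr_signal_quality": 90.0,
                "rr_signal_quality": 93.0, "hr_data_quality": 81.0,
                "rr_data_quality": 85.0, "st_data_quality": 96.0,
                "mean_hr": 84.0, "mean_rr": 20.0, "mean_st": 34.2,
                "stationary_hours_per_day": 10.5, "ambulatory_pct": 12.0,
                "ambulatory_hours_per_day": 1.5,
            }
        )
        return parts, meta

    def test_identical_participants_give_p_one(self):
        parts, meta = self._identical_cohort()
        table = build_cohort_table(parts, meta)
        cont = table[table["test"] != "fisher"]
        assert cont["p_value"].to_numpy() == pytest.approx(1.0)
        assert (table["p_value"] <= 1.0).all() and (table["p_value"] >= 0.0).all()

    def test_row_inventory_complete(self):
        parts, meta = self._identical_cohort()
        table = build_cohort_table(parts, meta)
        variables = set(table["variable"])
        for expected in (
            "Male", "BMI (kg/m2)", "MRC grade 5", "Duration worn >5 weeks",
            "Wear time (hours)", "HR signal quality (%)", "ST data quality (%)",
            "Physical activity (% of wear time)", "Battery depletion during wear",
        ):
            assert expected in variables
        assert len(table) == len(variables)  # no duplicate rows

    def test_empty_group_rejected(self):
        parts, meta = self._identical_cohort(n_a=1, n_b=6)
        with pytest.raises(ValueError):
            build_cohort_table(parts, meta)

    def test_null_cohort_p_values_roughly_uniform(self):
        rng = np.random.default_rng(5)
        ps = []
        for _ in range(200):
            ps.append(route_test("v", rng.normal(0, 1, 35), rng.normal(0, 1, 49)).p_value)
        frac = np.mean(np.asarray(ps) < 0.05)
        assert 0.01 <= frac <= 0.10
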