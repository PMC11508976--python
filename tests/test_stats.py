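"""Rank-sum and contingency tests, rib count tables, group comparisons."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from ribmap import (
    contingency_2x2,
    mann_whitney,
    position_comparison,
    rib_count_table,
    upper_rib_association,
)

from conftest import make_cohort


def enumeration_oracle(a, b):
    """Brute-force two-sided Mann-Whitney p: enumerate every split of the
    pooled values into groups of the observed sizes."""
    pooled = np.concatenate([a, b])
    n_a = len(a)
    ranks = sps.rankdata(pooled)
    mu = n_a * len(b) / 2.0
    u_obs = ranks[:n_a].sum() - n_a * (n_a + 1) / 2.0
    hits = total = 0
    for combo in itertools.combinations(range(len(pooled)), n_a):
        u = ranks[list(combo)].sum() - n_a * (n_a + 1) / 2.0
        total += 1
        if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
            hits += 1
    return u_obs, hits / total


class TestMannWhitney:
    def test_extreme_small_sample(self):
        u, p = mann_whitney([1, 2], [3, 4])
        assert u == 0.0
        assert p == pytest.approx(2 / 6)

    def test_identical_samples_give_central_u_and_p_one(self):
        x = [3.0, 1.0, 4.0, 1.0, 5.0]
        u, p = mann_whitney(x, x)
        assert u == pytest.approx(25 / 2)
        assert p == 1.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])

    @pytest.mark.parametrize("data,n_a", [
        ((1.0, 5.0, 2.0, 8.0, 3.0, 9.0), 2),
        ((1.0, 5.0, 2.0, 8.0, 3.0, 9.0, 4.0), 3),
        ((2.0, 2.0, 3.0, 3.0, 3.0, 7.0, 9.0, 9.0), 4),  # heavy ties
        ((0.0, 0.0, 0.0, 1.0, 2.0, 2.0), 3),
    ])
    def test_exact_p_matches_enumeration_for_all_splits(self, data, n_a):
        for combo in itertools.combinations(range(len(data)), n_a):
            a = [data[i] for i in combo]
            b = [data[i] for i in range(len(data)) if i not in combo]
            u, p = mann_whitney(a, b)
            u_ref, p_ref = enumeration_oracle(a, b)
            assert u == pytest.approx(u_ref)
            assert p == pytest.approx(p_ref)

    def test_complementarity_of_u_statistics(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(size=30), rng.normal(size=40)
        u_a, _ = mann_whitney(a, b)
        u_b, _ = mann_whitney(b, a)
        assert u_a + u_b == pytest.approx(30 * 40)

    def test_asymptotic_p_matches_scipy_without_continuity_correction(self):
        rng = np.random.default_rng(9)
        a, b = rng.normal(size=40), rng.normal(0.5, 1, size=55)
        u, p = mann_whitney(a, b)
        ref = sps.mannwhitneyu(a, b, alternative="two-sided",
                               method="asymptotic", use_continuity=False)
        assert u == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_type_i_error_rate_under_null(self):
        # equal distributions, n=100 vs 100: rejection rate near nominal 5%
        rng = np.random.default_rng(123)
        rejections = 0
        n_rep = 1000
        for _ in range(n_rep):
            a = rng.normal(size=100)
            b = rng.normal(size=100)
            _, p = mann_whitney(a, b)
            rejections += p < 0.05
        assert 0.03 <= rejections / n_rep <= 0.07


class TestContingency2x2:
    def test_chi_square_matches_closed_form(self):
        # n(ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d)) for the clavicle/upper-rib table
        res = contingency_2x2([[24, 2], [53, 23]], method="chi_square")
        a, b, c, d = 24, 2, 53, 23
        n = a + b + c + d
        expected = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        assert res.statistic == pytest.approx(expected, abs=1e-9)
        assert res.statistic == pytest.approx(5.334, abs=5e-4)

    def test_independence_gives_zero_statistic(self):
        res = contingency_2x2([[10, 10], [10, 10]], method="chi_square")
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_auto_routes_small_tables_to_fisher(self):
        res = contingency_2x2([[1, 0], [0, 1]])
        assert res.method == "fisher"
        assert res.p_value == pytest.approx(1.0)

    def test_fisher_matches_hypergeometric_enumeration(self):
        table = np.array([[3, 7], [8, 2]])
        res = contingency_2x2(table, method="fisher")
        # oracle: sum hypergeometric probabilities of all tables with the same
        # margins whose probability does not exceed the observed one
        n1, n2 = table.sum(axis=1)
        k = table[:, 0].sum()
        n = table.sum()
        p_obs = sps.hypergeom.pmf(table[0, 0], n, n1, k)
        p_total = sum(
            p for x in range(max(0, k - n2), min(k, n1) + 1)
            if (p := sps.hypergeom.pmf(x, n, n1, k)) <= p_obs * (1 + 1e-9)
        )
        assert res.p_value == pytest.approx(p_total, rel=1e-9)

    def test_yates_correction_available(self):
        plain = contingency_2x2([[24, 2], [53, 23]], method="chi_square")
        yates = contingency_2x2([[24, 2], [53, 23]], method="chi_square_yates")
        assert yates.statistic < plain.statistic
        assert yates.method == "chi_square_yates"

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            contingency_2x2([[0, 0], [5, 5]])


class TestRibCountTable:
    def test_reconstructed_table_reproduces_published_totals(self, rib_count_cohort):
        table = rib_count_table(rib_count_cohort)
        assert table.grand_total == 923
        assert round(table.percent_per_rib[4], 2) == 14.08  # rib 5
        assert round(table.left_share, 2) == 52.00
        assert round(table.right_share, 2) == 48.00

    def test_single_record(self):
        table = rib_count_table(make_cohort([("A", 1, "left", 10.0)]))
        assert table.left[0] == 1 and table.right[0] == 0
        assert table.percent_per_rib[0] == 100.0

    def test_rounded_percents_sum_to_100(self, rib_count_cohort):
        table = rib_count_table(rib_count_cohort)
        assert np.round(table.percent_per_rib, 2).sum() == pytest.approx(100.0, abs=0.05)

    def test_invariant_under_record_shuffling(self, rib_count_cohort):
        import copy, random
        shuffled = copy.deepcopy(rib_count_cohort)
        random.Random(0).shuffle(shuffled.patients)
        for p in shuffled.patients:
            random.Random(1).shuffle(p.fractures)
        base = rib_count_table(rib_count_cohort)
        after = rib_count_table(shuffled)
        np.testing.assert_array_equal(base.left, after.left)
        np.testing.assert_array_equal(base.right, after.right)

    def test_empty_cohort_flags_undefined_percents(self):
        table = rib_count_table(make_cohort([], flags={"A": {}}))
        assert table.grand_total == 0
        assert np.isnan(table.percent_per_rib).all()


class TestPositionComparison:
    def test_separated_groups_recover_group_means(self):
        cohort = make_cohort(
            [("A", 5, "left", 90.0), ("A", 6, "left", 90.0), ("B", 5, "right", 10.0)],
            flags={"A": {"sternum": True}, "B": {}},
        )
        res = position_comparison(cohort, "sternum")
        assert res.mean_yes == 90.0
        assert res.mean_no == 10.0
        assert res.shift == 80.0

    def test_group_with_zero_records_rejected(self):
        cohort = make_cohort([("A", 5, "left", 50.0)], flags={"A": {}})
        with pytest.raises(ValueError, match="zero records"):
            position_comparison(cohort, "scapula")

    def test_patient_level_unit(self):
        cohort = make_cohort(
            [("A", 5, "left", 80.0), ("A", 6, "left", 100.0), ("B", 5, "right", 10.0)],
            flags={"A": {"sternum": True}, "B": {}},
        )
        res = position_comparison(cohort, "sternum", unit="patient")
        assert res.n_yes == 1 and res.mean_yes == 90.0

    def test_unknown_flag_rejected(self):
        with pytest.raises(ValueError):
            position_comparison(make_cohort([("A", 5, "left", 50.0)]), "femur")


class TestUpperRibAssociation:
    def test_perfectly_separated_cohort(self):
        cohort = make_cohort(
            [("A", 2, "left", 30.0), ("B", 8, "left", 30.0)],
            flags={"A": {"clavicle": True}, "B": {}},
        )
        res = upper_rib_association(cohort, "clavicle")
        assert res.rates == (1.0, 0.0)

    def test_full_rib_range_saturates(self):
        cohort = make_cohort(
            [("A", 2, "left", 30.0), ("B", 8, "left", 30.0)],
            flags={"A": {"clavicle": True}, "B": {}},
        )
        res = upper_rib_association(cohort, "clavicle", rib_range=range(1, 13))
        assert res.rates == (1.0, 1.0)
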