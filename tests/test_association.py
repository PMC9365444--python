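"""Rank statistics: approximations vs exact enumeration, structural identities."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

import hospiseg as hs
from hospiseg.association import (
    NUMERIC_CHARACTERISTICS,
    characteristic_correlations,
    composition_correlation_matrix,
    group_comparisons,
    rank_sum_test,
    spearman,
)
from hospiseg.characteristics import derive_characteristics
from conftest import analytic_table


def exact_spearman_p(x, y):
    """Two-sided permutation p-value by full enumeration (no ties)."""
    from scipy.stats import spearmanr

    obs = abs(spearmanr(x, y).statistic)
    count = 0
    total = 0
    for perm in itertools.permutations(y):
        total += 1
        if abs(spearmanr(x, perm).statistic) >= obs - 1e-12:
            count += 1
    return count / total


def exact_rank_sum_p(a, b):
    """Two-sided exact p by enumerating all assignments of ranks to group a."""
    pooled = np.concatenate([a, b])
    ranks = pd.Series(pooled).rank().to_numpy()
    n_a = len(a)
    w_obs = ranks[:n_a].sum()
    mu = n_a * (len(pooled) + 1) / 2.0
    dev = abs(w_obs - mu)
    count = 0
    total = 0
    for idx in itertools.combinations(range(len(pooled)), n_a):
        total += 1
        if abs(ranks[list(idx)].sum() - mu) >= dev - 1e-12:
            count += 1
    return count / total


class TestSpearman:
    def test_perfect_monotone(self):
        assert spearman([1, 2, 3, 4], [10, 20, 30, 40]).rho == 1.0
        assert spearman([1, 2, 3, 4], [40, 30, 20, 10]).rho == -1.0

    def test_pairwise_deletion(self):
        r = spearman([1, 2, 3, 4, 5], [5, np.nan, 3, 2, 1])
        assert r.n_pairs == 4
        assert r.rho == -1.0

    def test_constant_vector_undefined(self):
        r = spearman([1, 1, 1, 1], [1, 2, 3, 4])
        assert not r.defined
        assert math.isnan(r.p_value)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            spearman([1, 2], [3, 4])

    def test_monotone_transform_invariance(self, rng):
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        base = spearman(x, y)
        warped = spearman(np.exp(x), y**3)
        assert warped.rho == pytest.approx(base.rho, abs=1e-12)
        assert warped.p_value == pytest.approx(base.p_value, abs=1e-12)

    def test_t_approximation_close_to_exact_permutation(self, rng):
        """At n=6 (720 permutations) the t-approximate p stays within
        0.05 of the exact permutation p."""
        for _ in range(10):
            x = rng.normal(size=6)
            y = rng.normal(size=6)
            approx = spearman(x, y).p_value
            exact = exact_spearman_p(x, y)
            assert abs(approx - exact) < 0.05


class TestRankSum:
    def test_extreme_configuration_minimal_rank_sum(self):
        r = rank_sum_test([1, 2], [3, 4])
        assert r.statistic == 3.0  # minimum possible for n_a = 2

    def test_identical_samples_null_p(self):
        r = rank_sum_test([5, 5, 5], [5, 5, 5])
        assert r.p_value == pytest.approx(1.0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            rank_sum_test([], [1.0])

    def test_label_swap_leaves_p_unchanged(self, rng):
        a = rng.normal(size=9)
        b = rng.normal(size=13)
        assert rank_sum_test(a, b).p_value == pytest.approx(
            rank_sum_test(b, a).p_value, abs=1e-12
        )

    def test_statistic_bounds_random_instances(self, rng):
        for _ in range(300):
            n_a = int(rng.integers(1, 12))
            n_b = int(rng.integers(1, 12))
            a = rng.integers(0, 6, size=n_a).astype(float)  # heavy ties
            b = rng.integers(0, 6, size=n_b).astype(float)
            r = rank_sum_test(a, b)
            lo = n_a * (n_a + 1) / 2.0
            assert lo <= r.statistic <= lo + n_a * n_b

    def test_p_value_agrees_with_enumeration(self, rng):
        """At n_a = n_b = 4 (70 assignments) the reported p stays within
        0.03 of the independent exact enumeration p."""
        for _ in range(10):
            a = rng.normal(size=4)
            b = rng.normal(size=4)
            assert abs(rank_sum_test(a, b).p_value - exact_rank_sum_p(a, b)) < 0.03


class TestCompositionMatrix:
    def test_nhw_minority_exactly_minus_one(self, default_analytic):
        results = composition_correlation_matrix(default_analytic)
        r = next(c for c in results if {c.var_x, c.var_y} == {"nhw", "minority"})
        assert r.rho == -1.0

    def test_hand_computed_three_hospitals(self):
        # shares chosen so NHB ranks (1,2,3) vs Hispanic ranks (3,2,1)
        df = pd.DataFrame(
            {
                "hospital_id": ["a", "b", "c"],
                "share_nhw": [0.50, 0.40, 0.30],
                "share_nhb": [0.10, 0.20, 0.30],
                "share_hispanic": [0.30, 0.25, 0.20],
                "share_api_aian": [0.05, 0.10, 0.15],
                "share_minority": [0.50, 0.60, 0.70],
            }
        )
        results = composition_correlation_matrix(df)
        by_pair = {frozenset((c.var_x, c.var_y)): c.rho for c in results}
        assert by_pair[frozenset(("nhb", "hispanic"))] == pytest.approx(-1.0)
        assert by_pair[frozenset(("nhb", "api_aian"))] == pytest.approx(1.0)
        assert by_pair[frozenset(("nhw", "minority"))] == pytest.approx(-1.0)

    def test_coupled_groups_recovered(self, default_analytic):
        # NHB and Hispanic both track county minority mix, so they rank together
        results = composition_correlation_matrix(default_analytic)
        r = next(c for c in results if {c.var_x, c.var_y} == {"nhb", "hispanic"})
        assert r.rho > 0


@pytest.fixture(scope="module")
def chars84(region84):
    an = analytic_table(region84).merge(region84.ratings, on="hospital_id", how="left")
    return an, derive_characteristics(region84.structural, an)


class TestCharacteristicCorrelations:
    def test_strong_dual_link_recovered(self, chars84):
        an, chars = chars84
        results = characteristic_correlations(an, chars)
        r = next(c for c in results if (c.var_x, c.var_y) == ("minority", "dual_pct"))
        assert r.rho > 0.8

    def test_rating_rank_antisymmetry(self, chars84):
        an, chars = chars84
        results = characteristic_correlations(an, chars)
        r_nhw = next(c for c in results if (c.var_x, c.var_y) == ("nhw", "star_rating"))
        r_min = next(c for c in results if (c.var_x, c.var_y) == ("minority", "star_rating"))
        assert r_nhw.rho == pytest.approx(-r_min.rho, abs=1e-12)
        assert r_nhw.n_pairs == r_min.n_pairs < len(an)  # pairwise-complete n

    def test_independent_characteristic_uncorrelated(self, chars84):
        # structural capacity is generated independently of composition
        an, chars = chars84
        results = characteristic_correlations(an, chars)
        r = next(c for c in results if (c.var_x, c.var_y) == ("minority", "icu_pct"))
        assert abs(r.rho) < 0.35


class TestGroupComparisons:
    def test_safety_net_minority_link_significant(self, region84):
        an = analytic_table(region84).merge(region84.ratings, on="hospital_id", how="left")
        chars = derive_characteristics(region84.structural, an)
        results = group_comparisons(an, chars, by="safety_net")
        r = next(x for x in results if x.variable == "minority_share")
        assert r.p_value < 0.01
        assert len(results) == 5 + len(NUMERIC_CHARACTERISTICS)

    def test_empty_stratum_is_an_error(self, region84):
        an = analytic_table(region84).merge(region84.ratings, on="hospital_id", how="left")
        chars = derive_characteristics(region84.structural, an)
        chars = chars.assign(ownership="nonprofit")
        with pytest.raises(ValueError, match="nonfederal_government"):
            group_comparisons(an, chars, by="ownership")

    def test_unknown_stratifier_rejected(self, default_analytic):
        with pytest.raises(ValueError, match="unknown stratifier"):
            group_comparisons(default_analytic, default_analytic, by="size")
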