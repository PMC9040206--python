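import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from riskstrat import (cohens_kappa, incremental_by_age, paired_signed_rank,
                       rank_correlation, venn_counts)


def vectors_from_2x2(both, a_only, b_only, neither):
    a = np.array([True] * both + [True] * a_only + [False] * b_only
                 + [False] * neither)
    b = np.array([True] * both + [False] * a_only + [True] * b_only
                 + [False] * neither)
    return a, b


def signed_rank_enumeration(d):
    """Exact two-sided Wilcoxon p by enumerating all 2^n sign patterns."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    ranks = stats.rankdata(np.abs(d))
    n = len(d)
    w_obs = ranks[d > 0].sum()
    dist = np.array([np.sum(ranks[list(signs)])
                     for signs in itertools.product([False, True], repeat=n)])
    mean = ranks.sum() / 2
    p = np.mean(np.abs(dist - mean) >= abs(w_obs - mean) - 1e-12)
    return w_obs, p


class TestCohensKappa:
    def test_perfect_agreement(self):
        a = np.array([True, False, True, False, True])
        res = cohens_kappa(a, a)
        assert res.kappa == pytest.approx(1.0)

    def test_hand_arithmetic_2x2(self):
        # both+=20, a-only=5, b-only=10, neither=65: p_o=.85, p_e=.60
        a, b = vectors_from_2x2(20, 5, 10, 65)
        res = cohens_kappa(a, b)
        assert res.kappa == pytest.approx(0.625, abs=1e-12)
        assert res.p_value < 1e-6

    def test_independent_raters_near_zero(self):
        rng = np.random.default_rng(11)
        a = rng.random(100_000) < 0.3
        b = rng.random(100_000) < 0.3
        res = cohens_kappa(a, b)
        # SE of kappa under independence ~ 1/sqrt(n) scale
        assert res.kappa == pytest.approx(0.0, abs=3 / np.sqrt(100_000) * 1.5)

    def test_symmetry(self):
        a, b = vectors_from_2x2(12, 7, 3, 40)
        assert cohens_kappa(a, b).kappa == pytest.approx(cohens_kappa(b, a).kappa)

    def test_degenerate_constant_identical(self):
        a = np.zeros(10, dtype=bool)
        res = cohens_kappa(a, a)
        assert res.status == "degenerate"
        assert res.kappa is None


class TestRankCorrelation:
    def test_monotone_function_gives_one(self):
        x = np.array([1.0, 2.0, 5.0, 9.0])
        assert rank_correlation(x, np.exp(x)).rho == pytest.approx(1.0)

    def test_antimonotone_gives_minus_one(self):
        x = np.array([1.0, 2.0, 5.0, 9.0])
        assert rank_correlation(x, -x).rho == pytest.approx(-1.0)

    def test_four_point_hand_value(self):
        # 1 - 6*sum(d^2)/(n(n^2-1)) with d^2 = (0,1,1,0) -> 0.8
        res = rank_correlation([1, 2, 3, 4], [1, 3, 2, 4])
        assert res.rho == pytest.approx(0.8, abs=1e-12)

    def test_constant_input_degenerate(self):
        assert rank_correlation([1, 1, 1], [1, 2, 3]).status == "degenerate"


class TestPairedSignedRank:
    def test_identical_vectors_degenerate(self):
        x = np.arange(6.0)
        assert paired_signed_rank(x, x).status == "degenerate"

    def test_six_positive_differences_exact(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        res = paired_signed_rank(x + np.array([0.1, 0.2, 0.3, 0.4, 0.5, 0.6]), x)
        assert res.method == "exact"
        assert res.p_value == pytest.approx(2 / 64)

    def test_symmetric_differences_central(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = x + np.array([0.5, -0.5, 1.5, -1.5])
        res = paired_signed_rank(x, y)
        assert res.p_value > 0.5

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_exact_p_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 13))
        d = rng.normal(0.3, 1.0, size=n)
        res = paired_signed_rank(d, np.zeros(n))
        w, p = signed_rank_enumeration(d)
        assert res.method == "exact"
        assert res.statistic == pytest.approx(w)
        assert res.p_value == pytest.approx(p, abs=1e-12)

    def test_large_sample_uses_approximation(self):
        rng = np.random.default_rng(5)
        res = paired_signed_rank(rng.normal(0.2, 1, 200), np.zeros(200))
        assert res.method == "approx"
        assert 0 < res.p_value < 1


class TestVennCounts:
    def test_disjoint_criteria(self):
        a = np.array([True] * 3 + [False] * 7)
        b = np.array([False] * 3 + [True] * 4 + [False] * 3)
        s = venn_counts({"a": a, "b": b})
        assert s.region_counts == {"10": 3, "01": 4, "11": 0, "00": 3}
        assert s.union == 7

    def test_nested_criterion(self):
        outer = np.array([True, True, True, False])
        inner = np.array([True, True, False, False])
        s = venn_counts({"outer": outer, "inner": inner})
        assert s.region_counts["01"] == 0  # inner-only region empty

    def test_random_flags_against_brute_force(self):
        rng = np.random.default_rng(8)
        flags = {k: rng.random(1000) < p
                 for k, p in zip("wxyz", (0.1, 0.3, 0.5, 0.05))}
        s = venn_counts(flags)
        assert sum(s.region_counts.values()) == 1000
        for name, arr in flags.items():
            assert s.marginals[name] == arr.sum()
        # brute-force recount of every pattern
        mat = np.column_stack(list(flags.values()))
        for pattern, count in s.region_counts.items():
            target = np.array([c == "1" for c in pattern])
            assert count == np.sum((mat == target).all(axis=1))
        assert s.union == np.sum(mat.any(axis=1))


class TestIncrementalByAge:
    @pytest.fixture
    def eight_individuals(self):
        flags = {
            "fh": np.array([1, 0, 0, 0, 1, 0, 0, 0], dtype=bool),
            "gail": np.array([1, 1, 0, 0, 0, 0, 0, 0], dtype=bool),
            "prs": np.array([0, 0, 1, 0, 0, 1, 1, 0], dtype=bool),
        }
        ages = np.array([32, 33, 31, 34, 51, 52, 53, 54], dtype=float)
        return flags, ages

    def test_hand_enumerated_proportions(self, eight_individuals):
        flags, ages = eight_individuals
        table = incremental_by_age(flags, ages, ["fh", "gail", "prs"])
        bin30 = table[table["age_group"] == "30-34"].iloc[0]
        assert bin30["+fh"] == pytest.approx(1 / 4)
        assert bin30["+gail"] == pytest.approx(2 / 4)
        assert bin30["+prs"] == pytest.approx(3 / 4)
        bin50 = table[table["age_group"] == "50-54"].iloc[0]
        assert bin50["+fh"] == pytest.approx(1 / 4)
        assert bin50["+gail"] == pytest.approx(1 / 4)
        assert bin50["+prs"] == pytest.approx(3 / 4)

    def test_single_prefix_equals_marginal(self, eight_individuals):
        flags, ages = eight_individuals
        table = incremental_by_age(flags, ages, ["prs"])
        bin30 = table[table["age_group"] == "30-34"].iloc[0]
        assert bin30["+prs"] == pytest.approx(1 / 4)

    def test_subset_criterion_absorbed(self, eight_individuals):
        flags, ages = eight_individuals
        flags = dict(flags)
        flags["sub"] = flags["fh"] & flags["gail"]
        with_sub = incremental_by_age(flags, ages, ["fh", "gail", "sub"])
        without = incremental_by_age(flags, ages, ["fh", "gail"])
        np.testing.assert_allclose(with_sub["+sub"], with_sub["+gail"])
        np.testing.assert_allclose(with_sub["+gail"], without["+gail"])

    def test_proportions_non_decreasing_along_sequence(self):
        rng = np.random.default_rng(4)
        flags = {k: rng.random(500) < 0.2 for k in "abcd"}
        ages = rng.uniform(30, 75, 500)
        table = incremental_by_age(flags, ages, list("abcd"))
        cols = [c for c in table.columns if c.startswith("+")]
        vals = table[cols].to_numpy(float)
        assert np.all(np.diff(vals, axis=1) >= -1e-12)

    def test_age_75_closed_into_last_bin_and_overflow_warned(self, caplog):
        flags = {"a": np.array([True, False, True])}
        ages = np.array([75.0, 29.0, 40.0])
        with caplog.at_level("WARNING", logger="riskstrat"):
            table = incremental_by_age(flags, ages, ["a"])
        assert table[table["age_group"] == "70-74"].iloc[0]["n"] == 1
        assert table[table["age_group"] == "outside"].iloc[0]["n"] == 1
        assert "outside" in caplog.text
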