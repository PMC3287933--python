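"""Score tests, Hotelling T^2, Fisher-z G-E contrast, permutation engine."""

import itertools

import numpy as np
import pytest
from scipy import stats
from scipy.special import expit

from snpset.assoc_tests import (
    SeparationError,
    _ge_perm_stats,
    _hotelling_perm_stats,
    ge_correlation_permutation_test,
    ge_correlation_test,
    hotelling_permutation_test,
    hotelling_t2,
    logistic_score_test,
    permutation_pvalue,
    permuted_label_matrix,
)
from snpset.data_model import ValidationError


def _table_to_data(a, b, c, d):
    """2x2 status x carrier table -> (y, z)."""
    y = np.array([1] * (a + b) + [0] * (c + d), dtype=float)
    z = np.array([1] * a + [0] * b + [1] * c + [0] * d, dtype=float)
    return y, z


def _pearson_x2(a, b, c, d):
    n = a + b + c + d
    return n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))


class TestLogisticScoreTest:
    def test_matches_pearson_chi_square_on_2x2_table(self):
        y, z = _table_to_data(10, 20, 20, 10)
        res = logistic_score_test(y, np.ones((60, 1)), z)
        assert res.statistic == pytest.approx(_pearson_x2(10, 20, 20, 10), abs=1e-8)
        assert res.statistic == pytest.approx(6.6667, abs=1e-4)
        assert res.df == 1

    def test_constant_column_dropped_with_reduced_df(self, rng):
        n = 80
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        z = rng.binomial(2, 0.3, n).astype(float)
        y = rng.binomial(1, 0.4, n).astype(float)
        Z = np.column_stack([z, np.full(n, 1.0)])
        res = logistic_score_test(y, X, Z)
        ref = logistic_score_test(y, X, z)
        assert res.df == 1 and res.notes["dropped_columns"] == 1
        assert res.statistic == pytest.approx(ref.statistic, abs=1e-10)

    def test_all_degenerate_columns_error(self, rng):
        n = 30
        with pytest.raises(ValidationError, match="no testable genetic signal"):
            logistic_score_test(
                np.repeat([0.0, 1.0], 15), np.ones((n, 1)), np.ones((n, 1))
            )

    def test_finite_difference_likelihood_oracle(self, rng):
        for _ in range(5):
            res, oracle = _random_score_problem(rng)
            assert res.statistic == pytest.approx(oracle, abs=1e-6)

    def test_invariant_to_affine_rescaling_of_genetic_columns(self, rng):
        n = 120
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        Z = rng.binomial(2, 0.2, size=(n, 3)).astype(float)
        s = rng.binomial(1, 0.4, n).astype(float)
        y = rng.binomial(1, 0.35, n).astype(float)
        r1 = logistic_score_test(y, X, Z, s)
        r2 = logistic_score_test(y, X, Z * np.array([2.0, 0.5, 7.0]), s)
        assert r1.statistic == pytest.approx(r2.statistic, abs=1e-8)
        assert r1.df == r2.df


def _random_score_problem(rng):
    from oracles import random_score_problem

    return random_score_problem(rng, logistic_score_test)


class TestHotellingT2:
    def test_identical_means_give_zero(self):
        A = np.array([[1.0, 2.0], [3.0, 0.0], [2.0, 4.0]])
        B = A + 0.0
        res = hotelling_t2(np.vstack([A, -A + 2 * A.mean(0)]), np.vstack([B, -B + 2 * B.mean(0)]))
        assert res.statistic == pytest.approx(0.0, abs=1e-20)

    def test_d1_equals_squared_pooled_t(self, rng):
        for _ in range(20):
            A = rng.normal(size=(rng.integers(4, 15), 1))
            B = rng.normal(size=(rng.integers(4, 15), 1)) + rng.normal()
            t = stats.ttest_ind(A[:, 0], B[:, 0]).statistic
            assert hotelling_t2(A, B).statistic == pytest.approx(t**2, abs=1e-10)

    def test_constant_coordinate_equals_reduced_dimension(self, rng):
        A = rng.normal(size=(10, 2))
        B = rng.normal(size=(8, 2)) + 0.5
        A2 = np.column_stack([A, np.full(10, 3.0)])
        B2 = np.column_stack([B, np.full(8, 3.0)])
        full = hotelling_t2(A2, B2)
        reduced = hotelling_t2(A, B)
        assert full.statistic == pytest.approx(reduced.statistic, abs=1e-8)
        assert "rank" in full.notes

    def test_invariant_to_nonsingular_linear_transform(self, rng):
        A = rng.normal(size=(12, 3))
        B = rng.normal(size=(14, 3)) + 0.3
        T = rng.normal(size=(3, 3)) + np.eye(3)
        r1 = hotelling_t2(A, B).statistic
        r2 = hotelling_t2(A @ T, B @ T).statistic
        assert r1 == pytest.approx(r2, abs=1e-8 * max(1.0, r1))


class TestGeCorrelationTest:
    def test_statistic_matches_independent_formula(self, rng):
        n = 60
        g = rng.normal(size=n)
        e = rng.binomial(1, 0.4, n).astype(float)
        status = (rng.random(n) < 0.5).astype(int)
        res = ge_correlation_test(g, e, status)
        r_a = np.corrcoef(g[status == 1], e[status == 1])[0, 1]
        r_u = np.corrcoef(g[status == 0], e[status == 0])[0, 1]
        n_a, n_u = (status == 1).sum(), (status == 0).sum()
        expected = (np.arctanh(r_a) - np.arctanh(r_u)) / np.sqrt(
            1 / (n_a - 3) + 1 / (n_u - 3)
        )
        assert res.statistic == pytest.approx(expected, abs=1e-12)
        assert res.p_value == pytest.approx(2 * stats.norm.sf(abs(expected)), abs=1e-12)

    def test_equal_group_correlations_give_zero_statistic(self):
        g = np.array([0.0, 1.0, 2.0, 3.0, 1.5] * 2)
        e = np.array([0.0, 1.0, 0.0, 1.0, 1.0] * 2)
        status = np.array([1] * 5 + [0] * 5)
        res = ge_correlation_test(g, e, status)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_label_swap_negates_statistic(self, rng):
        n = 50
        g = rng.normal(size=n)
        e = rng.binomial(1, 0.5, n).astype(float)
        status = (rng.random(n) < 0.4).astype(int)
        r1 = ge_correlation_test(g, e, status)
        r2 = ge_correlation_test(g, e, 1 - status)
        assert r1.statistic == pytest.approx(-r2.statistic, abs=1e-12)
        assert r1.p_value == pytest.approx(r2.p_value, abs=1e-12)

    def test_small_group_and_constant_inputs_rejected(self):
        status = np.array([1, 1, 1, 0, 0, 0, 0])
        with pytest.raises(ValidationError):
            ge_correlation_test(np.arange(7.0), np.arange(7.0) % 2, status)


class TestPermutationEngine:
    def test_extreme_observed_statistic(self, rng):
        status = np.array([1, 1, 1, 0, 0, 0])
        x = status.astype(float)  # observed labels maximize the overlap statistic

        def stat(lab):
            return float(lab @ x)

        res = permutation_pvalue(stat, status, B=99, rng=rng)
        assert res.p_value <= (1 + 10) / 100  # only exact ties can match

    def test_constant_statistic_gives_p_one(self, rng):
        res = permutation_pvalue(lambda lab: 1.0, np.array([1, 0, 1, 0]), B=50, rng=rng)
        assert res.p_value == 1.0

    def test_matches_exhaustive_enumeration(self, rng):
        x = rng.normal(size=6)  # continuous: only exact complement ties
        status = np.array([1, 1, 1, 0, 0, 0])

        def stat(lab):
            lab = np.asarray(lab, dtype=bool)
            return abs(x[lab].mean() - x[~lab].mean())

        obs = stat(status)
        exact_ge = sum(
            stat(np.isin(np.arange(6), combo)) >= obs - 1e-12
            for combo in itertools.combinations(range(6), 3)
        )
        exact_p = exact_ge / 20
        res = permutation_pvalue(stat, status, B=2000, rng=rng)
        assert res.p_value == pytest.approx(exact_p, abs=0.02)

    def test_reproducible_under_seed(self):
        x = np.arange(10.0)
        status = np.array([1] * 4 + [0] * 6)

        def stat(lab):
            lab = np.asarray(lab, dtype=bool)
            return abs(x[lab].mean() - x[~lab].mean())

        p1 = permutation_pvalue(stat, status, B=200, seed=5).p_value
        p2 = permutation_pvalue(stat, status, B=200, seed=5).p_value
        assert p1 == p2


class TestVectorizedPermutationPaths:
    def test_hotelling_fast_path_matches_direct_statistic(self, rng):
        M = rng.normal(size=(40, 3))
        for _ in range(10):
            status = np.zeros(40)
            status[rng.choice(40, 15, replace=False)] = 1
            direct = hotelling_t2(M[status == 1], M[status == 0]).statistic
            fast = _hotelling_perm_stats(M, status[:, None])[0]
            assert fast == pytest.approx(direct, abs=1e-8 * max(1, direct))

    def test_ge_fast_path_matches_direct_statistic(self, rng):
        g = rng.normal(size=50)
        e = rng.binomial(1, 0.4, 50).astype(float)
        for _ in range(10):
            status = np.zeros(50)
            status[rng.choice(50, 20, replace=False)] = 1
            direct = abs(ge_correlation_test(g, e, status.astype(int)).statistic)
            fast = _ge_perm_stats(g, e, status[:, None])[0]
            assert fast == pytest.approx(direct, abs=1e-10)

    def test_label_matrix_preserves_group_totals(self, rng):
        status = np.array([1] * 7 + [0] * 13)
        labels = permuted_label_matrix(status, 50, rng)
        assert labels.shape == (20, 50)
        np.testing.assert_array_equal(labels.sum(axis=0), 7)

    def test_fast_tests_reproducible_and_valid(self, rng):
        M = rng.normal(size=(60, 2))
        status = (rng.random(60) < 0.4).astype(float)
        r1 = hotelling_permutation_test(M, status, B=300, seed=3)
        r2 = hotelling_permutation_test(M, status, B=300, seed=3)
        assert r1.p_value == r2.p_value
        g = rng.normal(size=60)
        e = rng.binomial(1, 0.5, 60).astype(float)
        r3 = ge_correlation_permutation_test(g, e, status, B=300, seed=4)
        assert 0 < r3.p_value <= 1


class TestScoreTestCalibration:
    def test_null_rejection_rate_near_nominal(self, rng):
        """Type-I error of the score test at alpha = 0.05 on null simulations."""
        n, reps, alpha = 400, 2000, 0.05
        rej = 0
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        Z = rng.binomial(2, np.array([0.2, 0.05, 0.3]), size=(n, 3)).astype(float)
        s = rng.binomial(1, 0.3, n).astype(float)
        mu = expit(-0.5 + 0.3 * X[:, 1])
        for _ in range(reps):
            y = rng.binomial(1, mu).astype(float)
            rej += logistic_score_test(y, X, Z, s).p_value < alpha
        # 99% binomial band around 0.05 for 2000 replicates
        se = np.sqrt(alpha * (1 - alpha) / reps)
        assert abs(rej / reps - alpha) < 2.58 * se + 1e-9
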