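"""Oracle and property tests for the five association measures."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from consortium_net import (
    AbundanceTable,
    bray_curtis,
    gblm_scores,
    mutual_information,
    pearson,
    score_matrix,
    spearman,
)
from consortium_net.measures import _boost_path, default_mi_bins


def _rel_table(values, taxa=None):
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    return AbundanceTable(
        sample_ids=[f"s{i}" for i in range(n)],
        taxon_ids=taxa or [f"t{j}" for j in range(p)],
        values=values / values.sum(axis=1, keepdims=True),
        generations=["G1"] * n,
        replicates=list(range(1, n + 1)),
        mode="relative",
    )


class TestBrayCurtis:
    def test_identity_is_zero(self, rng):
        x = rng.random(10) + 0.1
        assert bray_curtis(x, x) == pytest.approx(0.0)

    def test_disjoint_supports_is_one(self):
        assert bray_curtis(np.array([1, 0, 2.0]), np.array([0, 3, 0.0])) == 1.0

    def test_hand_formula(self):
        # 1 - 2*sum(min)/(sum x + sum y) = 1 - 2*2/5
        assert bray_curtis(np.array([2, 1.0]), np.array([1, 1.0])) == pytest.approx(0.2)

    def test_matches_direct_formula_on_random_vectors(self, rng):
        for _ in range(50):
            x, y = rng.random(12), rng.random(12)
            expected = 1 - 2 * np.minimum(x, y).sum() / (x.sum() + y.sum())
            assert bray_curtis(x, y) == pytest.approx(expected)
            assert 0 <= bray_curtis(x, y) <= 1

    def test_both_zero_rejected(self):
        with pytest.raises(ValueError):
            bray_curtis(np.zeros(3), np.zeros(3))


class TestCorrelations:
    def test_affine_relationship(self, rng):
        x = rng.random(15)
        y = 2 * x + 1
        assert pearson(x, y) == pytest.approx(1.0)
        assert spearman(x, y) == pytest.approx(1.0)

    def test_monotone_nonlinear(self):
        x = np.linspace(0, 5, 20)
        y = np.exp(x)
        assert spearman(x, y) == pytest.approx(1.0)
        assert pearson(x, y) < 1.0

    def test_spearman_rank_oracle(self):
        # brute-force rank formula on a tie-free permutation
        assert spearman(np.array([1, 2, 3, 4.0]), np.array([2, 1, 4, 3.0])) == pytest.approx(0.6)

    def test_constant_vector_signals_undefined(self, rng):
        assert np.isnan(pearson(np.ones(5), rng.random(5)))
        assert np.isnan(spearman(np.ones(5), rng.random(5)))

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(st.lists(st.integers(0, 5), min_size=4, max_size=25),
           st.lists(st.integers(0, 5), min_size=4, max_size=25))
    def test_spearman_equals_pearson_on_midranks(self, xs, ys):
        n = min(len(xs), len(ys))
        x = np.asarray(xs[:n], dtype=float)
        y = np.asarray(ys[:n], dtype=float)
        rx, ry = stats.rankdata(x), stats.rankdata(y)
        if np.ptp(rx) == 0 or np.ptp(ry) == 0:
            assert np.isnan(spearman(x, y))
        else:
            assert spearman(x, y) == pytest.approx(np.corrcoef(rx, ry)[0, 1], abs=1e-12)


class TestMutualInformation:
    def test_perfect_dependence_is_log_bins(self):
        x = np.arange(24, dtype=float)  # tie-free, divisible by 2,3,4
        for bins in (2, 3, 4):
            assert mutual_information(x, x, bins=bins) == pytest.approx(np.log(bins))

    def test_constant_vector_gives_zero(self, rng):
        assert mutual_information(rng.random(30), np.full(30, 2.0)) == 0.0

    def test_independent_near_zero(self, rng):
        x = rng.random(1000)
        y = rng.permutation(x)
        assert mutual_information(x, y, bins=4) < 0.02

    def test_symmetry(self, rng):
        for _ in range(20):
            x, y = rng.random(40), rng.random(40)
            assert mutual_information(x, y) == pytest.approx(mutual_information(y, x))

    def test_default_bins(self):
        assert default_mi_bins(12) == 3
        assert default_mi_bins(40) == 6
        assert default_mi_bins(200) == 8  # capped


class TestGBLM:
    def test_single_true_predictor_converges_to_ols(self, rng):
        n = 60
        X = rng.random((n, 4)) + 0.05
        X[:, 3] = X[:, 0]  # target duplicates predictor 0 exactly
        table = _rel_table(X, taxa=["a", "b", "c", "target"])
        coefs = gblm_scores(table, "target", shrinkage=0.1, iterations=3000)
        # closure keeps proportional columns proportional, so OLS slope is 1
        assert coefs["a"] == pytest.approx(1.0, abs=1e-3)
        assert coefs["b"] == pytest.approx(0.0, abs=1e-3)
        assert coefs["c"] == pytest.approx(0.0, abs=1e-3)

    def test_zero_iterations_gives_zero_coefficients(self, rng):
        table = _rel_table(rng.random((10, 4)) + 0.1)
        coefs = gblm_scores(table, "t0", iterations=0)
        assert all(v == 0.0 for v in coefs.values())

    def test_null_coefficients_stay_small(self):
        # independent predictors (no closure): boosting must not
        # hallucinate large coefficients
        hits = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            table = AbundanceTable(
                sample_ids=[f"s{i}" for i in range(200)],
                taxon_ids=[f"t{j}" for j in range(6)],
                values=r.random((200, 6)) + 0.05,
                generations=["G1"] * 200,
                replicates=list(range(1, 201)),
                mode="counts",
            )
            coefs = gblm_scores(table, "t0", iterations=100)
            # OLS oracle: standardized null coefficients ~ N(0, 1/sqrt(n));
            # joint 97.5% bound for the max of 5 is 0.071 * 2.80 ~ 0.20
            if max(abs(v) for v in coefs.values()) < 0.20:
                hits += 1
        assert hits >= 19

    def test_unit_shrinkage_single_predictor_is_ols(self, rng):
        x = rng.random(50)
        y = 0.7 * x + rng.normal(0, 0.1, 50)
        coef = _boost_path(x[:, None], y, shrinkage=1.0, iterations=200)
        xs = (x - x.mean()) / x.std()
        ys = (y - y.mean()) / y.std()
        ols = float(xs @ ys) / 50
        assert coef[0] == pytest.approx(ols, abs=1e-6)


class TestScoreMatrix:
    def test_two_taxa_closure_forces_negative_one(self, rng):
        x = rng.random(12) * 0.8 + 0.1
        table = _rel_table(np.column_stack([x, 1 - x]))
        M = score_matrix(table, "pearson")
        assert M[0, 1] == pytest.approx(-1.0)

    @pytest.mark.parametrize("measure", ["bray_curtis", "pearson", "spearman", "mi", "gblm"])
    def test_symmetric(self, measure, rng):
        table = _rel_table(rng.gamma(2, 1, (15, 6)))
        M = score_matrix(table, measure)
        np.testing.assert_allclose(M, M.T, atol=1e-12)

    @pytest.mark.parametrize("measure,fn", [
        ("bray_curtis", bray_curtis),
        ("pearson", pearson),
        ("spearman", spearman),
    ])
    def test_matches_per_pair_loop(self, measure, fn, rng):
        table = _rel_table(rng.gamma(2, 1, (20, 5)))
        M = score_matrix(table, measure)
        for i in range(5):
            for j in range(i + 1, 5):
                expected = fn(table.values[:, i], table.values[:, j])
                assert M[i, j] == pytest.approx(expected, abs=1e-12)

    def test_mi_matches_per_pair_loop(self, rng):
        table = _rel_table(rng.gamma(2, 1, (20, 5)))
        M = score_matrix(table, "mi", mi_bins=3)
        for i in range(5):
            for j in range(i + 1, 5):
                expected = mutual_information(table.values[:, i], table.values[:, j], bins=3)
                assert M[i, j] == pytest.approx(expected, abs=1e-12)

    def test_diagonal_self_values(self, rng):
        table = _rel_table(rng.gamma(2, 1, (20, 4)))
        assert np.allclose(np.diag(score_matrix(table, "bray_curtis")), 0.0)
        assert np.allclose(np.diag(score_matrix(table, "pearson")), 1.0)
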