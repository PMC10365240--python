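"""Unit and property tests for connectivity-network construction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from smfcnet import (
    binarize_symmetric_support,
    build_fcn_stack,
    dyadic_grid,
    hard_threshold_stack,
    network_density,
    normalize_series,
    pearson_matrix,
    penalty_weights,
    solve_wsr,
    sparsity_guided_fcn,
)
from smfcnet.fcn import _wsr_objective


def lasso_cd_oracle(X, target_col, C_col, lam, tol=1e-10, max_iter=20000):
    """Brute-force coordinate-descent solution of one weighted lasso column.

    Minimizes 0.5*||x_i - D w||^2 + lam * sum_j C_j |w_j| with D = X whose
    column ``target_col`` is zeroed. Independent of the ADMM path.
    """
    D = X.copy()
    D[:, target_col] = 0.0
    x = X[:, target_col]
    N = X.shape[1]
    w = np.zeros(N)
    sq = np.einsum("ij,ij->j", D, D)
    for _ in range(max_iter):
        w_old = w.copy()
        for j in range(N):
            if sq[j] == 0:
                continue
            r = x - D @ w + D[:, j] * w[j]
            rho_j = D[:, j] @ r
            w[j] = np.sign(rho_j) * max(abs(rho_j) - lam * C_col[j], 0.0) / sq[j]
        if np.max(np.abs(w - w_old)) < tol:
            break
    return w


class TestNormalize:
    def test_centering_and_unit_norm(self):
        ts = normalize_series(np.array([[1.0], [2.0], [3.0]]))
        np.testing.assert_allclose(ts.values[:, 0], np.array([-1, 0, 1]) / np.sqrt(2))
        assert ts.values[:, 0] @ ts.values[:, 0] == pytest.approx(1.0)

    def test_dot_products_are_correlations(self):
        ts = normalize_series(np.array([[1.0, 1.0, 1.0], [2.0, 2.0, 3.0], [3.0, 3.0, 2.0]]))
        x = ts.values
        assert x[:, 0] @ x[:, 1] == pytest.approx(1.0)   # identical columns
        assert x[:, 0] @ x[:, 2] == pytest.approx(0.5)   # hand-computed Pearson

    def test_constant_column_rejected_with_index(self):
        raw = np.ones((10, 3))
        raw[:, 0] = np.arange(10)
        raw[:, 2] = np.arange(10) ** 2
        with pytest.raises(ValueError, match=r"\[1\]"):
            normalize_series(raw)

    @pytest.mark.parametrize("raw", [np.ones((1, 2)), np.full((4, 2), np.nan)])
    def test_degenerate_inputs_rejected(self, raw):
        with pytest.raises(ValueError):
            normalize_series(raw)


class TestPearson:
    def test_matches_textbook_correlation(self, rng):
        raw = rng.standard_normal((25, 5))
        P = pearson_matrix(normalize_series(raw))
        np.testing.assert_allclose(P, np.corrcoef(raw.T), atol=1e-12)

    def test_antiparallel_pair(self):
        ts = normalize_series(np.array([[1.0, 3.0], [2.0, 2.0], [3.0, 1.0]]))
        assert pearson_matrix(ts)[0, 1] == pytest.approx(-1.0)

    def test_range_symmetry_diagonal(self, random_ts):
        P = pearson_matrix(random_ts)
        assert np.all(P >= -1) and np.all(P <= 1)
        np.testing.assert_array_equal(P, P.T)
        np.testing.assert_allclose(np.diag(P), 1.0)


class TestPenaltyWeights:
    @pytest.mark.parametrize("p, expected", [
        (0.0, 1.0),
        (1.0, np.exp(-5.0)),
        (0.5, np.exp(-1.25)),
    ])
    def test_pointwise_values(self, p, expected):
        assert penalty_weights(np.array([[p]]), 0.2)[0, 0] == pytest.approx(expected)

    def test_stronger_correlation_means_smaller_penalty(self):
        P = np.array([[0.1, 0.9]])
        C = penalty_weights(P, 0.2)
        assert C[0, 1] < C[0, 0]
        assert np.all((C > 0) & (C <= 1))

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            penalty_weights(np.zeros((2, 2)), 0.0)


class TestWSR:
    def test_large_lambda_gives_empty_solution(self, random_ts):
        P = pearson_matrix(random_ts)
        C = penalty_weights(P)
        off = ~np.eye(P.shape[0], dtype=bool)
        lam_max = np.max(np.abs(P[off]) / C[off])
        res = solve_wsr(random_ts, C, lam_max * 1.01)
        np.testing.assert_array_equal(res.W, 0.0)

    def test_matches_coordinate_descent_oracle_unweighted(self, rng):
        raw = rng.standard_normal((30, 6))
        ts = normalize_series(raw)
        C = np.ones((6, 6))
        for lam in (0.05, 0.2):
            res = solve_wsr(ts, C, lam)
            for i in range(6):
                w = lasso_cd_oracle(ts.values, i, C[:, i], lam)
                np.testing.assert_allclose(res.W[:, i], w, atol=1e-5)

    def test_two_roi_closed_form(self, rng):
        raw = rng.standard_normal((40, 2))
        ts = normalize_series(raw)
        P = pearson_matrix(ts)
        C = penalty_weights(P)
        lam = 0.1
        res = solve_wsr(ts, C, lam)
        r = ts.values[:, 1] @ ts.values[:, 0]
        expected = np.sign(r) * max(abs(r) - lam * C[1, 0], 0.0)  # unit-norm dictionary
        assert res.W[1, 0] == pytest.approx(expected, abs=1e-6)
        assert res.W[0, 1] == pytest.approx(expected, abs=1e-6)

    def test_objective_no_worse_than_zero_solution(self, random_ts):
        P = pearson_matrix(random_ts)
        C = penalty_weights(P)
        obj0 = 0.5 * np.linalg.norm(random_ts.values) ** 2
        for lam in dyadic_grid(-3, 2):
            res = solve_wsr(random_ts, C, lam)
            assert res.objective <= obj0 + 1e-9
            assert np.all(np.diag(res.W) == 0)

    def test_strong_correlation_survives_larger_lambda(self, rng):
        # x0 built from x1 (strongly) and x2 (weakly): the weighted penalty
        # lets the strong predictor persist to larger sparsity levels
        z = rng.standard_normal((200, 3))
        raw = np.column_stack([
            0.9 * z[:, 1] + 0.3 * z[:, 2] + 0.1 * z[:, 0], z[:, 1], z[:, 2]])
        ts = normalize_series(raw)
        C = penalty_weights(pearson_matrix(ts))
        died1 = died2 = None
        for lam in dyadic_grid(-6, 3):
            W = solve_wsr(ts, C, lam).W
            if died1 is None and abs(W[1, 0]) <= 1e-5:
                died1 = lam
            if died2 is None and abs(W[2, 0]) <= 1e-5:
                died2 = lam
        assert died2 is not None and (died1 is None or died1 > died2)

    def test_invalid_inputs_rejected(self, random_ts):
        C = np.ones((6, 6))
        with pytest.raises(ValueError):
            solve_wsr(random_ts, C, -1.0)
        with pytest.raises(ValueError):
            solve_wsr(random_ts, 0.0 * C, 1.0)


class TestBinarize:
    def test_or_symmetrization(self):
        W = np.array([[0.0, 0.3], [-0.2, 0.0]])
        np.testing.assert_array_equal(binarize_symmetric_support(W),
                                      [[0, 1], [1, 0]])
        W = np.array([[0.0, 0.3], [0.0, 0.0]])
        np.testing.assert_array_equal(binarize_symmetric_support(W),
                                      [[0, 1], [1, 0]])
        np.testing.assert_array_equal(binarize_symmetric_support(np.zeros((3, 3))),
                                      np.zeros((3, 3)))

    @settings(derandomize=True, max_examples=30)
    @given(st.integers(0, 2**32 - 1), st.integers(2, 8))
    def test_symmetric_binary_idempotent(self, seed, n):
        W = np.random.default_rng(seed).standard_normal((n, n)) * \
            (np.random.default_rng(seed + 1).random((n, n)) < 0.5)
        G = binarize_symmetric_support(W)
        np.testing.assert_array_equal(G, G.T)
        assert set(np.unique(G)) <= {0, 1}
        assert np.all(np.diag(G) == 0)
        np.testing.assert_array_equal(binarize_symmetric_support(G, 0.5), G)


class TestMasking:
    def test_limits(self, random_ts):
        P = pearson_matrix(random_ts)
        np.testing.assert_array_equal(sparsity_guided_fcn(P, np.zeros_like(P)), 0.0)
        G = 1 - np.eye(P.shape[0])
        M = sparsity_guided_fcn(P, G)
        np.testing.assert_array_equal(np.diag(M), 0.0)
        np.testing.assert_array_equal(M[G == 1], P[G == 1])

    def test_entrywise_against_double_loop(self, rng):
        P = rng.uniform(-1, 1, (5, 5))
        G = (rng.random((5, 5)) < 0.4).astype(int)
        M = sparsity_guided_fcn(P, G)
        for i in range(5):
            for j in range(5):
                assert M[i, j] == (P[i, j] if G[i, j] else 0.0)

    def test_retained_entries_bit_exact(self, random_ts):
        stack = build_fcn_stack(random_ts, dyadic_grid(-4, 0))
        P = pearson_matrix(random_ts)
        for M in stack.M:
            nz = M != 0
            np.testing.assert_array_equal(M[nz], P[nz])

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            sparsity_guided_fcn(np.eye(3), np.zeros((2, 2)))


class TestStack:
    def test_default_grid_yields_ten_networks(self, random_ts):
        stack = build_fcn_stack(random_ts)
        assert stack.d == 10
        np.testing.assert_allclose(stack.lam_grid, 2.0 ** np.arange(-4, 6))

    def test_density_monotone_in_lambda(self, rng):
        for _ in range(3):
            ts = normalize_series(rng.standard_normal((40, 8)))
            dens = build_fcn_stack(ts).densities()
            assert np.all(np.diff(dens) <= 1e-12)

    def test_largest_lambda_empty(self, random_ts):
        stack = build_fcn_stack(random_ts, dyadic_grid(-1, 8))
        assert network_density(stack.M[-1]) == 0.0

    def test_non_increasing_grid_rejected(self, random_ts):
        with pytest.raises(ValueError):
            build_fcn_stack(random_ts, np.array([1.0, 1.0]))


class TestHardThreshold:
    def test_survivor_count_at_99_percent(self, rng):
        raw = rng.standard_normal((140, 120))
        P = pearson_matrix(normalize_series(raw))
        stack = hard_threshold_stack(P, [99])
        n_kept = np.count_nonzero(np.triu(stack.M[0], 1))
        assert n_kept == 71  # floor(0.01 * 7140)

    def test_zero_percent_keeps_everything(self, random_ts):
        P = pearson_matrix(random_ts)
        M = hard_threshold_stack(P, [0]).M[0]
        off = ~np.eye(P.shape[0], dtype=bool)
        np.testing.assert_array_equal(M[off], P[off])
        np.testing.assert_array_equal(np.diag(M), 0.0)

    def test_survivors_dominate_discarded(self, rng):
        P = pearson_matrix(normalize_series(rng.standard_normal((60, 12))))
        M = hard_threshold_stack(P, [40]).M[0]
        off = np.triu(~np.eye(12, dtype=bool))
        kept = np.abs(P[(M != 0) & off])
        cut = np.abs(P[(M == 0) & off])
        assert kept.min() >= cut.max()

    def test_symmetry_and_out_of_range_percents(self, random_ts):
        P = pearson_matrix(random_ts)
        stack = hard_threshold_stack(P, [10, 50, 90])
        for M in stack.M:
            np.testing.assert_array_equal(M, M.T)
        with pytest.raises(ValueError):
            hard_threshold_stack(P, [100])
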