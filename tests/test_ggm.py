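"""Nonparanormal transform, graphical lasso, EBIC selection and the full
network estimator."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from odornet.datasets import NODES, PcorNetwork
from odornet.exceptions import ValidationError
from odornet.ggm import (
    ModelFit,
    count_edges,
    ebic_score,
    estimate_network,
    graphical_lasso,
    lambda_grid,
    npn_transform,
    precision_to_pcor,
)
from odornet.synthetic import build_covariance_from_pcor


def _random_correlation(p, seed):
    rng = np.random.default_rng(seed)
    A = rng.standard_normal((4 * p, p))
    return np.corrcoef(A, rowvar=False)


class TestNpnTransform:
    def test_three_point_example(self):
        # ranks of (5, 1, 9) are (2, 1, 3); u = (.5, .25, .75);
        # quantiles (0, -0.6745, 0.6745); unit-SD rescale -> (0, -1, 1)
        out = npn_transform(np.array([[5.0], [1.0], [9.0]]))
        assert out[:, 0] == pytest.approx([0.0, -1.0, 1.0], abs=1e-9)

    def test_every_column_unit_sample_sd(self):
        rng = np.random.default_rng(1)
        X = rng.exponential(size=(50, 4))
        out = npn_transform(X)
        assert out.std(axis=0, ddof=1) == pytest.approx(np.ones(4))

    def test_monotone_rank_preserving(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(10_000)
        out = npn_transform(x[:, None])[:, 0]
        from scipy.stats import spearmanr

        assert spearmanr(x, out).statistic == pytest.approx(1.0)

    def test_constant_column_rejected_by_name(self):
        X = np.column_stack([np.arange(5.0), np.full(5, 2.0)])
        with pytest.raises(ValidationError, match="A"):
            npn_transform(X, column_names=("V", "A"))

    def test_ties_averaged(self):
        out = npn_transform(np.array([[1.0], [1.0], [2.0], [3.0]]))
        assert out[0, 0] == out[1, 0]


class TestGraphicalLasso:
    def test_identity_input_identity_output(self):
        for lam in (0.0, 0.1, 0.5):
            fit = graphical_lasso(np.eye(4), lam)
            assert np.allclose(fit.theta, np.eye(4), atol=1e-8)

    def test_unpenalized_equals_inverse(self):
        S = _random_correlation(6, seed=3)
        fit = graphical_lasso(S, 0.0, tol=1e-9, max_iter=2000)
        assert np.abs(fit.theta - np.linalg.inv(S)).max() < 1e-6

    def test_bivariate_closed_form(self):
        # p=2: the working covariance off-diagonal is soft-thresholded,
        # w12 = s12 - lam, so the implied partial correlation is 0.3
        S = np.array([[1.0, 0.5], [0.5, 1.0]])
        fit0 = graphical_lasso(S, 0.0, tol=1e-10, max_iter=2000)
        assert np.allclose(fit0.theta, np.array([[4 / 3, -2 / 3], [-2 / 3, 4 / 3]]),
                           atol=1e-8)
        fit = graphical_lasso(S, 0.2, tol=1e-10, max_iter=2000)
        pcor = precision_to_pcor(fit.theta).weights[0, 1]
        assert pcor == pytest.approx(0.3, abs=1e-8)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    @pytest.mark.parametrize("lam", [0.05, 0.2])
    def test_kkt_conditions(self, seed, lam):
        S = _random_correlation(7, seed=seed)
        fit = graphical_lasso(S, lam, tol=1e-9, max_iter=2000)
        W = np.linalg.inv(fit.theta)
        for i in range(7):
            for j in range(7):
                if i == j:
                    assert W[i, i] == pytest.approx(S[i, i], abs=1e-6)
                elif abs(fit.theta[i, j]) > 1e-10:
                    grad = W[i, j] - S[i, j] - lam * np.sign(fit.theta[i, j])
                    assert abs(grad) < 1e-5
                else:
                    assert abs(W[i, j] - S[i, j]) <= lam + 1e-6

    def test_matches_sklearn(self):
        from sklearn.covariance import graphical_lasso as sk_glasso

        S = _random_correlation(6, seed=11)
        for lam in (0.05, 0.15):
            _, prec = sk_glasso(S, alpha=lam, tol=1e-10, max_iter=2000)
            fit = graphical_lasso(S, lam, tol=1e-10, max_iter=2000)
            assert np.abs(prec - fit.theta).max() < 1e-3

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValidationError):
            graphical_lasso(np.eye(3), -0.1)


class TestLambdaGrid:
    def test_lambda_max_is_largest_off_diagonal(self):
        S = np.array([[1.0, 0.5], [0.5, 1.0]])
        grid = lambda_grid(S, n_lambda=10)
        assert grid[0] == pytest.approx(0.5)
        assert grid[-1] == pytest.approx(0.005)

    def test_default_length_1000(self):
        grid = lambda_grid(_random_correlation(5, seed=0))
        assert len(grid) == 1000
        assert np.all(np.diff(grid) < 0)

    def test_graph_empty_at_lambda_max(self):
        S = _random_correlation(7, seed=4)
        grid = lambda_grid(S, n_lambda=5)
        fit = graphical_lasso(S, grid[0], tol=1e-9, max_iter=2000)
        assert count_edges(fit.theta) == 0

    def test_degenerate_all_zero_off_diagonals(self):
        with pytest.warns(UserWarning):
            grid = lambda_grid(np.eye(4))
        assert list(grid) == [0.0]


class TestPrecisionToPcor:
    def test_identity_gives_empty_network(self):
        net = precision_to_pcor(np.eye(7))
        assert np.all(net.weights == 0)

    def test_two_node_formula(self):
        theta = np.array([[1.0, -0.3], [-0.3, 1.0]])
        net = precision_to_pcor(theta)
        assert net.weights[0, 1] == pytest.approx(0.3)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_conditional_correlation_oracle(self, seed):
        """Brute force: pcor(i,j | rest) from inversion of the correlation
        submatrix of Sigma = Theta^-1."""
        rng = np.random.default_rng(seed)
        A = rng.standard_normal((30, 5))
        sigma = np.cov(A, rowvar=False) + np.eye(5)
        theta = np.linalg.inv(sigma)
        net = precision_to_pcor(theta, nodes=tuple("abcde"))
        for i in range(5):
            for j in range(i + 1, 5):
                rest = [k for k in range(5) if k not in (i, j)]
                s = sigma[np.ix_([i, j] + rest, [i, j] + rest)]
                s11 = s[:2, :2]
                s12 = s[:2, 2:]
                s22 = s[2:, 2:]
                cond = s11 - s12 @ np.linalg.inv(s22) @ s12.T
                expected = cond[0, 1] / np.sqrt(cond[0, 0] * cond[1, 1])
                assert net.weights[i, j] == pytest.approx(expected, abs=1e-10)


class TestEbic:
    def _fit(self, theta, lam, n, gamma, S):
        sign, logdet = np.linalg.slogdet(theta)
        ll = 0.5 * n * (logdet - np.trace(S @ theta))
        e = count_edges(theta)
        p = theta.shape[0]
        return ModelFit(theta=theta, lambda_=lam, gamma=gamma, n=n, p=p,
                        loglik=ll, n_edges=e,
                        ebic=-2 * ll + e * np.log(n) + 4 * gamma * e * np.log(p))

    def test_empty_graph_is_minus_two_loglik(self):
        S = np.eye(3)
        fit = self._fit(np.eye(3), 0.5, 100, 0.5, S)
        assert ebic_score(fit) == pytest.approx(-2 * fit.loglik)

    def test_gamma_zero_reduces_to_bic(self):
        S = np.array([[1.0, 0.5], [0.5, 1.0]])
        theta = np.linalg.inv(S)
        fit = self._fit(theta, 0.0, 100, 0.0, S)
        assert ebic_score(fit) == pytest.approx(-2 * fit.loglik + 1 * np.log(100))

    def test_hand_evaluated_difference(self):
        """p=2, n=100: EBIC(empty at S=I) vs EBIC(saturated at s12=0.5)."""
        n, gamma = 100, 0.5
        S = np.array([[1.0, 0.5], [0.5, 1.0]])
        sat = self._fit(np.linalg.inv(S), 0.0, n, gamma, S)
        empty = self._fit(np.eye(2), 1.0, n, gamma, S)
        # saturated: logdet(inv S) = -log(0.75), trace = 2
        ll_sat = 0.5 * n * (-np.log(0.75) - 2.0)
        ll_empty = 0.5 * n * (0.0 - 2.0)
        expected_diff = ((-2 * ll_sat + np.log(n) + 4 * gamma * np.log(2))
                         - (-2 * ll_empty))
        assert ebic_score(sat) - ebic_score(empty) == pytest.approx(expected_diff)


class TestEstimateNetwork:
    def test_orthogonal_columns_give_empty_network(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((200, 4))
        q, _ = np.linalg.qr(X)
        net, fit = estimate_network(q, n_lambda=50)
        assert fit.n_edges == 0
        assert np.all(net.weights == 0)

    @pytest.mark.parametrize("seed", [6, 7, 8])
    def test_chain_support_and_weights_recovered(self, chain4, seed):
        sigma = build_covariance_from_pcor(chain4)
        rng = np.random.default_rng(seed)
        X = rng.multivariate_normal(np.zeros(4), sigma, size=2000)
        net, fit = estimate_network(X, n_lambda=100)
        expected = {frozenset(p) for p in (("x0", "x1"), ("x1", "x2"), ("x2", "x3"))}
        got = {frozenset(e[:2]) for e in net.edges()}
        assert expected <= got  # every true link recovered
        for a, b, w in net.edges():
            if frozenset((a, b)) in expected:
                assert abs(w - 0.4) < 0.05
            else:  # occasional spurious extras stay at shrinkage level
                assert abs(w) < 0.05

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((150, 5)) @ _chol_corr(5, 0.4)
        net1, _ = estimate_network(X, n_lambda=60)
        net2, _ = estimate_network(X[rng.permutation(150)], n_lambda=60)
        assert np.abs(net1.weights - net2.weights).max() < 1e-10

    def test_deterministic_for_fixed_input(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((100, 4))
        w1 = estimate_network(X, n_lambda=40)[0].weights
        w2 = estimate_network(X, n_lambda=40)[0].weights
        assert np.array_equal(w1, w2)

    def test_output_invariants(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((120, 6))
        net, _ = estimate_network(X, n_lambda=40)
        assert np.array_equal(net.weights, net.weights.T)
        assert np.abs(net.weights).max() < 1.0

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_edge_count_monotone_along_path(self, seed):
        from odornet._glasso import ebic_path

        S = _random_correlation(7, seed=seed)
        lambdas = lambda_grid(S, n_lambda=60)
        _, _, _, edges, _ = ebic_path(S, lambdas, 100, 0.5, 1e-6, 500, 1e-8)
        assert np.all(np.diff(edges) >= 0)  # descending lambda: edges grow

    def test_needs_more_rows_than_columns(self):
        with pytest.raises(ValidationError):
            estimate_network(np.random.default_rng(0).standard_normal((5, 7)))


def _chol_corr(p, rho):
    S = np.full((p, p), rho)
    np.fill_diagonal(S, 1.0)
    return np.linalg.cholesky(S).T
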