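"""Sparse Gaussian graphical model estimation.

The estimation chain is: nonparanormal (rank-Gaussianizing) transform ->
Pearson correlation matrix -> graphical lasso along a descending log-spaced
penalty path -> extended-BIC model selection -> partial-correlation network.

The nonparanormal dialect is the shrunken empirical CDF: per column, ranks
with ties averaged, u = rank / (n + 1), value = standard-normal quantile of
u, then rescaled to unit sample SD. The EBIC of a fit with E nonzero
upper-triangle edges is ``-2 loglik + E log n + 4 gamma E log p`` with
``loglik = (n/2)(log det Theta - tr(S Theta))``; the selection hyperparameter
``gamma = 0.5`` favors sparse models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import ndtri
from scipy.stats import rankdata

from . import _glasso
from .datasets import EDGE_TOL, NODES, PcorNetwork
from .exceptions import ConvergenceError, EstimationError, ValidationError
from .preprocessing import StandardizedMatrix

__all__ = [
    "npn_transform", "graphical_lasso", "lambda_grid", "precision_to_pcor",
    "ebic_score", "estimate_network", "ModelFit", "PrecisionFit",
]


# ---------------------------------------------------------------------------
# nonparanormal transform
# ---------------------------------------------------------------------------

def npn_transform(X: np.ndarray, column_names=None) -> np.ndarray:
    """Rank-Gaussianize each column and rescale it to unit sample SD.

    The transform is monotone (rank-preserving) per column; a constant
    column has no rank information and raises a :class:`ValidationError`
    naming the column.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 3:
        raise ValidationError("npn transform needs an n x p matrix with n >= 3")
    if np.isnan(X).any():
        raise ValidationError("npn transform does not accept missing values")
    n, p = X.shape
    out = np.empty_like(X)
    for j in range(p):
        col = X[:, j]
        if np.all(col == col[0]):
            name = column_names[j] if column_names is not None else f"column {j}"
            raise ValidationError(f"constant column cannot be transformed: {name}")
        ranks = rankdata(col, method="average")
        q = ndtri(ranks / (n + 1.0))
        out[:, j] = q / q.std(ddof=1)
    return out


# ---------------------------------------------------------------------------
# graphical lasso
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PrecisionFit:
    """A single regularized precision-matrix estimate."""

    theta: np.ndarray
    lambda_: float
    n_iter: int
    residual: float


def _check_correlation(S: np.ndarray) -> np.ndarray:
    S = np.asarray(S, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValidationError("S must be a square matrix")
    if not np.allclose(S, S.T, atol=1e-12):
        raise ValidationError("S must be symmetric")
    if not np.allclose(np.diag(S), 1.0, atol=1e-8):
        raise ValidationError("S must have a unit diagonal")
    return (S + S.T) / 2.0


def graphical_lasso(S: np.ndarray, lambda_: float, tol: float = 1e-7,
                    max_iter: int = 500) -> PrecisionFit:
    """L1-penalized precision estimate for a correlation matrix S.

    Maximizes ``log det Theta - tr(S Theta) - lambda * sum_{i!=j} |Theta_ij|``
    (diagonal unpenalized) by block coordinate descent. Raises
    :class:`ConvergenceError`, carrying the residual, if the working
    covariance has not settled within ``max_iter`` sweeps.
    """
    S = _check_correlation(S)
    if lambda_ < 0:
        raise ValidationError("lambda must be nonnegative")
    W = S.copy()
    B = np.zeros_like(S)
    theta, n_iter, resid = _glasso.glasso_solve(S, lambda_, tol, max_iter, W, B)
    if resid >= tol and n_iter >= max_iter:
        raise ConvergenceError(
            f"graphical lasso did not converge in {max_iter} sweeps "
            f"(residual {resid:.3g}, tol {tol:.3g})")
    if not np.all(np.linalg.eigvalsh(theta) > 0):
        raise EstimationError("estimated precision matrix is not positive definite")
    return PrecisionFit(theta=theta, lambda_=float(lambda_), n_iter=n_iter, residual=resid)


def lambda_grid(S: np.ndarray, n_lambda: int = 1000, min_ratio: float = 0.01) -> np.ndarray:
    """Descending log-spaced penalty grid from lambda_max (= largest
    off-diagonal |s_ij|, the smallest penalty giving an empty graph) down to
    ``lambda_max * min_ratio``."""
    S = _check_correlation(S)
    off = np.abs(S[np.triu_indices(S.shape[0], k=1)])
    lam_max = float(off.max()) if off.size else 0.0
    if lam_max <= 0:
        import warnings

        warnings.warn("all off-diagonal correlations are zero; degenerate grid [0]")
        return np.array([0.0])
    return np.geomspace(lam_max, lam_max * min_ratio, n_lambda)


def precision_to_pcor(theta: np.ndarray, nodes=NODES) -> PcorNetwork:
    """Partial-correlation network from a positive-definite precision matrix:
    ``rho_ij = -theta_ij / sqrt(theta_ii * theta_jj)``, zero diagonal."""
    theta = np.asarray(theta, dtype=float)
    if not np.all(np.linalg.eigvalsh((theta + theta.T) / 2) > 0):
        raise EstimationError("precision matrix is not positive definite")
    d = np.sqrt(np.diag(theta))
    pcor = -theta / np.outer(d, d)
    np.fill_diagonal(pcor, 0.0)
    pcor = (pcor + pcor.T) / 2.0
    return PcorNetwork(tuple(nodes[: theta.shape[0]]), pcor)


# ---------------------------------------------------------------------------
# EBIC selection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelFit:
    """One penalized fit with its EBIC bookkeeping."""

    theta: np.ndarray
    lambda_: float
    gamma: float
    n: int
    p: int
    loglik: float
    n_edges: int
    ebic: float


def ebic_score(fit: ModelFit) -> float:
    """Extended BIC of a fit: ``-2 loglik + E log n + 4 gamma E log p``."""
    return (-2.0 * fit.loglik + fit.n_edges * np.log(fit.n)
            + 4.0 * fit.gamma * fit.n_edges * np.log(fit.p))


def count_edges(theta: np.ndarray, tol: float = EDGE_TOL) -> int:
    iu = np.triu_indices(theta.shape[0], k=1)
    return int(np.sum(np.abs(theta[iu]) > tol))


def _fit_path(S: np.ndarray, n: int, gamma: float, n_lambda: int,
              min_ratio: float, tol: float, max_iter: int):
    """Fit the penalty path and return (best index, lambdas, path arrays)."""
    lambdas = lambda_grid(S, n_lambda=n_lambda, min_ratio=min_ratio)
    thetas, ebics, logliks, edges, resids = _glasso.ebic_path(
        S, lambdas, n, gamma, tol, max_iter, EDGE_TOL)
    if np.max(resids) >= tol:
        bad = int(np.argmax(resids))
        raise ConvergenceError(
            f"graphical lasso did not converge at lambda={lambdas[bad]:.4g} "
            f"(residual {resids[bad]:.3g})")
    best = int(np.argmin(ebics))
    return best, lambdas, thetas, ebics, logliks, edges


def _matrix_from(X) -> tuple[np.ndarray, tuple[str, ...]]:
    if isinstance(X, StandardizedMatrix):
        return X.values, NODES
    if isinstance(X, pd.DataFrame):
        cols = tuple(X.columns)
        return X.to_numpy(dtype=float), cols
    X = np.asarray(X, dtype=float)
    return X, tuple(f"x{i}" for i in range(X.shape[1]))


def estimate_pcor_matrix(X: np.ndarray, gamma: float = 0.5, n_lambda: int = 1000,
                         min_ratio: float = 0.01, tol: float = 1e-5,
                         max_iter: int = 200) -> np.ndarray:
    """Fast path used by the resampling loops: raw matrix in, selected
    partial-correlation weight matrix out. Same chain as
    :func:`estimate_network`, without the dataclass packaging."""
    Z = npn_transform(X)
    S = np.corrcoef(Z, rowvar=False)
    best, _, thetas, _, _, _ = _fit_path(S, X.shape[0], gamma, n_lambda,
                                         min_ratio, tol, max_iter)
    theta = thetas[best]
    d = np.sqrt(np.diag(theta))
    pcor = -theta / np.outer(d, d)
    np.fill_diagonal(pcor, 0.0)
    return (pcor + pcor.T) / 2.0


def estimate_network(X, gamma: float = 0.5, n_lambda: int = 1000,
                     min_ratio: float = 0.01, tol: float = 1e-5,
                     max_iter: int = 200) -> tuple[PcorNetwork, ModelFit]:
    """Estimate the EBIC-selected sparse partial-correlation network.

    ``X`` may be a :class:`StandardizedMatrix`, a DataFrame with named
    columns, or a plain n x p array with n > p rows. Deterministic for fixed
    input.
    """
    mat, nodes = _matrix_from(X)
    n, p = mat.shape
    if n <= p:
        raise ValidationError(f"need more rows than variables (n={n}, p={p})")
    Z = npn_transform(mat, column_names=nodes)
    S = np.corrcoef(Z, rowvar=False)
    best, lambdas, thetas, ebics, logliks, edges = _fit_path(
        S, n, gamma, n_lambda, min_ratio, tol, max_iter)
    fit = ModelFit(theta=thetas[best], lambda_=float(lambdas[best]), gamma=gamma,
                   n=n, p=p, loglik=float(logliks[best]), n_edges=int(edges[best]),
                   ebic=float(ebics[best]))
    network = precision_to_pcor(fit.theta, nodes=nodes)
    return network, fit
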