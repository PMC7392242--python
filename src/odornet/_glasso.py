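"""Numba kernels for the graphical lasso and its EBIC path.

The solver is the block coordinate-descent algorithm: one lasso regression
per column of the working covariance W, with the diagonal unpenalized
(W_ii = S_ii). The path kernel sweeps a descending penalty grid with warm
starts and scores every fit with the extended BIC, which is what makes the
permutation/bootstrap Monte-Carlo loops elsewhere in the package affordable.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _lasso_column(S, W, B, j, lam, inner_tol, inner_max):
    """Coordinate descent for column j's lasso; updates B[:, j] in place."""
    p = S.shape[0]
    for _ in range(inner_max):
        bmax = 0.0
        for k in range(p):
            if k == j:
                continue
            r = S[k, j]
            for l in range(p):
                if l != j and l != k:
                    r -= W[k, l] * B[l, j]
            old = B[k, j]
            if r > lam:
                b = (r - lam) / W[k, k]
            elif r < -lam:
                b = (r + lam) / W[k, k]
            else:
                b = 0.0
            B[k, j] = b
            d = abs(b - old)
            if d > bmax:
                bmax = d
        if bmax < inner_tol:
            break


@njit(cache=True)
def glasso_solve(S, lam, tol, max_iter, W, B):
    """Run the outer coordinate loop until the working covariance settles.

    W and B carry warm starts in and the solution out. Returns
    (theta, n_iter, residual) where residual is the largest off-diagonal
    change in W during the final sweep.
    """
    p = S.shape[0]
    inner_tol = tol * 0.1
    resid = 0.0
    n_iter = 0
    for it in range(max_iter):
        n_iter = it + 1
        resid = 0.0
        for j in range(p):
            _lasso_column(S, W, B, j, lam, inner_tol, 200)
            for k in range(p):
                if k == j:
                    continue
                w = 0.0
                for l in range(p):
                    if l != j:
                        w += W[k, l] * B[l, j]
                d = abs(w - W[k, j])
                if d > resid:
                    resid = d
                W[k, j] = w
                W[j, k] = w
        if resid < tol:
            break

    theta = np.zeros((p, p))
    for j in range(p):
        dot = 0.0
        for k in range(p):
            if k != j:
                dot += W[k, j] * B[k, j]
        tjj = 1.0 / (W[j, j] - dot)
        theta[j, j] = tjj
        for k in range(p):
            if k != j:
                theta[k, j] = -B[k, j] * tjj
    # symmetrize; keep exact zeros where both directions are zero
    for i in range(p):
        for j in range(i + 1, p):
            v = 0.5 * (theta[i, j] + theta[j, i])
            theta[i, j] = v
            theta[j, i] = v
    return theta, n_iter, resid


@njit(cache=True)
def ebic_path(S, lambdas, n, gamma, tol, max_iter, edge_tol):
    """Fit the full descending-penalty path and score each fit with EBIC.

    Returns (thetas, ebics, logliks, edge_counts, residuals).
    """
    p = S.shape[0]
    m = lambdas.shape[0]
    thetas = np.zeros((m, p, p))
    ebics = np.empty(m)
    logliks = np.empty(m)
    edges = np.zeros(m, dtype=np.int64)
    resids = np.empty(m)
    W = S.copy()
    B = np.zeros((p, p))
    logn = np.log(n)
    logp = np.log(p)
    for i in range(m):
        theta, _, resid = glasso_solve(S, lambdas[i], tol, max_iter, W, B)
        thetas[i] = theta
        resids[i] = resid
        e = 0
        for a in range(p):
            for b in range(a + 1, p):
                if abs(theta[a, b]) > edge_tol:
                    e += 1
        edges[i] = e
        sign, logdet = np.linalg.slogdet(theta)
        tr = 0.0
        for a in range(p):
            for b in range(p):
                tr += S[a, b] * theta[b, a]
        ll = 0.5 * n * (logdet - tr)
        logliks[i] = ll
        ebics[i] = -2.0 * ll + e * logn + 4.0 * gamma * e * logp
    return thetas, ebics, logliks, edges, resids
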