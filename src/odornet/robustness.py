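"""Bootstrap accuracy and case-dropping stability of estimated networks.

Edge-weight accuracy: nonparametric bootstrap (rows resampled with
replacement, network re-estimated per replicate with identical settings),
reporting per-edge empirical percentile confidence intervals.

Centrality stability: case-dropping bootstrap — at each drop proportion the
network is re-estimated on a random subset and its centralities correlated
with the full-data centralities. The CS-coefficient is the largest drop
proportion at which at least ``prob`` of replicates still correlate at or
above ``cor_threshold`` with the original, required to hold at every smaller
proportion as well (prefix rule), so a non-monotone curve cannot inflate it.
The default grid tops out at 0.75, which is therefore the maximum reportable
CS.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .datasets import NODES, PcorNetwork
from .exceptions import EstimationError, NumericalError
from .ggm import estimate_pcor_matrix
from .metrics import betweenness, closeness, strength
from .preprocessing import StandardizedMatrix

logger = logging.getLogger(__name__)

DEFAULT_DROP_GRID = tuple(np.round(np.arange(0.05, 0.80, 0.05), 2))
DEFAULT_INDICES = ("strength", "closeness", "betweenness")


def _as_matrix(X, nodes=None) -> tuple[np.ndarray, tuple[str, ...]]:
    if isinstance(X, StandardizedMatrix):
        return X.values, NODES
    X = np.asarray(X, dtype=float)
    if nodes is None:
        nodes = NODES if X.shape[1] == len(NODES) \
            else tuple(f"x{i}" for i in range(X.shape[1]))
    return X, tuple(nodes)


def _centralities(weights: np.ndarray, indices) -> dict[str, np.ndarray]:
    p = weights.shape[0]
    net = PcorNetwork(tuple(f"x{i}" for i in range(p)), weights)
    out = {}
    if "strength" in indices:
        out["strength"] = strength(net).to_numpy()
    if "closeness" in indices:
        out["closeness"] = closeness(net).to_numpy()
    if "betweenness" in indices:
        out["betweenness"] = betweenness(net).to_numpy()
    return out


# ---------------------------------------------------------------------------
# edge-weight bootstrap
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BootstrapResult:
    """Per-edge point estimates, bootstrap means and percentile CIs."""

    nodes: tuple[str, ...]
    pairs: tuple[tuple[str, str], ...]
    point: np.ndarray        # observed edge weights, upper-triangle order
    boot_mean: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    samples: np.ndarray      # (B_effective, n_pairs) replicate edge weights
    B: int
    level: float
    seed: int | None
    n_failed: int

    def interval(self, a: str, b: str) -> tuple[float, float]:
        k = self.pairs.index((a, b) if (a, b) in self.pairs else (b, a))
        return float(self.lower[k]), float(self.upper[k])


def bootstrap_edge_cis(X, B: int = 1000, level: float = 0.95,
                       seed: int | None = None, nodes=None,
                       **estimation_kwargs) -> BootstrapResult:
    """Bootstrap the edge weights of the EBIC-selected network.

    Rows are resampled with replacement (same n) and the network re-estimated
    per replicate with the identical estimation settings. Replicates whose
    estimation fails are skipped and logged; more than 5% failures aborts.
    Deterministic given ``seed``.
    """
    mat, nodes = _as_matrix(X, nodes)
    n, p = mat.shape
    iu = np.triu_indices(p, k=1)
    pairs = tuple((nodes[i], nodes[j]) for i, j in zip(*iu))

    point = estimate_pcor_matrix(mat, **estimation_kwargs)[iu]
    rng = np.random.default_rng(seed)
    samples = []
    n_failed = 0
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        try:
            w = estimate_pcor_matrix(mat[idx], **estimation_kwargs)
        except NumericalError as exc:
            n_failed += 1
            logger.warning("bootstrap replicate failed: %s", exc)
            continue
        samples.append(w[iu])
    if n_failed > 0.05 * B:
        raise EstimationError(f"{n_failed}/{B} bootstrap replicates failed")
    arr = np.asarray(samples)
    alpha = (1.0 - level) / 2.0
    lower = np.percentile(arr, 100 * alpha, axis=0)
    upper = np.percentile(arr, 100 * (1 - alpha), axis=0)
    return BootstrapResult(nodes=nodes, pairs=pairs, point=point,
                           boot_mean=arr.mean(axis=0), lower=lower, upper=upper,
                           samples=arr, B=B, level=level, seed=seed, n_failed=n_failed)


# ---------------------------------------------------------------------------
# case-dropping stability
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StabilityResult:
    """Subsample-vs-full centrality correlations per drop proportion."""

    drop_grid: tuple[float, ...]
    correlations: dict[str, np.ndarray] = field(default_factory=dict)
    # correlations[index] has shape (len(drop_grid), B); NaN = degenerate replicate
    B: int = 0
    seed: int | None = None


def case_dropping_stability(X, drop_grid=DEFAULT_DROP_GRID, B: int = 1000,
                            indices=DEFAULT_INDICES, seed: int | None = None,
                            **estimation_kwargs) -> StabilityResult:
    """Correlate full-data centralities with centralities re-estimated from
    progressively smaller case subsets.

    For each drop proportion and replicate: subsample rows without
    replacement, re-estimate the network with identical settings, recompute
    the centralities and correlate them (Pearson, across nodes) with the
    full-data values. Degenerate replicates (zero-variance centrality
    vector, or failed estimation) are recorded as NaN.
    """
    mat, _ = _as_matrix(X)
    n, p = mat.shape
    drop_grid = tuple(float(d) for d in drop_grid)
    smallest = int(round(n * (1.0 - max(drop_grid))))
    if smallest <= p:
        raise EstimationError(
            f"smallest retained subsample ({smallest} rows) must exceed p={p}")

    full = _centralities(estimate_pcor_matrix(mat, **estimation_kwargs), indices)
    rng = np.random.default_rng(seed)
    cors = {ix: np.full((len(drop_grid), B), np.nan) for ix in indices}
    for gi, drop in enumerate(drop_grid):
        m = int(round(n * (1.0 - drop)))
        for b in range(B):
            idx = rng.choice(n, size=m, replace=False)
            try:
                w = estimate_pcor_matrix(mat[idx], **estimation_kwargs)
            except NumericalError as exc:
                logger.warning("stability replicate failed (drop %.2f): %s", drop, exc)
                continue
            cents = _centralities(w, indices)
            for ix in indices:
                a, c = full[ix], cents[ix]
                if a.std() == 0 or c.std() == 0:
                    continue  # stays NaN
                cors[ix][gi, b] = np.corrcoef(a, c)[0, 1]
    return StabilityResult(drop_grid=drop_grid, correlations=cors, B=B, seed=seed)


def cs_coefficient(result: StabilityResult, cor_threshold: float = 0.7,
                   prob: float = 0.95) -> dict[str, float]:
    """Correlation-stability coefficient per centrality index.

    CS is the largest drop proportion in the grid at which the fraction of
    replicates correlating >= ``cor_threshold`` with the full data is at
    least ``prob``, with the criterion also holding at every smaller
    proportion. NaN replicates count as failures. CS = 0 when the criterion
    already fails at the smallest proportion.
    """
    out = {}
    order = np.argsort(result.drop_grid)
    for ix, mat in result.correlations.items():
        cs = 0.0
        for gi in order:
            ok = np.mean(np.nan_to_num(mat[gi], nan=-np.inf) >= cor_threshold)
            if ok >= prob:
                cs = result.drop_grid[gi]
            else:
                break
        out[ix] = cs
    return out
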