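"""Between-network comparison: permutation Network Comparison Test and
classification of an estimated network against the signed hypothesis model.

The NCT permutes group labels of the pooled rows (preserving group sizes),
re-estimates both networks per permutation with identical settings, and
compares the observed statistics to their permutation distributions:

* M — largest absolute difference between corresponding edge weights
  (structure invariance),
* S — absolute difference in global strength (strength invariance).

P-values use the add-one rule ``(count + 1) / (iterations + 1)`` so they are
never exactly zero. The study design is paired (the same observers rate both
odor sets); the cited test is an independent-groups test, so the unpaired
mode is the default and a participant-level swap mode is provided for the
paired design.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .datasets import EDGE_TOL, PcorNetwork
from .exceptions import EstimationError, NumericalError, ValidationError
from .ggm import estimate_pcor_matrix
from .preprocessing import StandardizedMatrix
from .datasets import HypothesisModel

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# network comparison test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NCTResult:
    """Observed statistics and permutation p-values of the comparison test."""

    m_observed: float
    s_observed: float
    p_m: float
    p_s: float
    iterations: int
    paired: bool
    seed: int | None
    n_redrawn: int


def _stats(w1: np.ndarray, w2: np.ndarray) -> tuple[float, float]:
    iu = np.triu_indices(w1.shape[0], k=1)
    m = float(np.max(np.abs(w1[iu] - w2[iu])))
    s = float(abs(np.abs(w1[iu]).sum() - np.abs(w2[iu]).sum()))
    return m, s


def _rows(X) -> tuple[np.ndarray, np.ndarray | None]:
    if isinstance(X, StandardizedMatrix):
        return X.values, X.participant_ids
    return np.asarray(X, dtype=float), None


def nct(X1, X2, iterations: int = 10000, paired: bool = False,
        seed: int | None = None, max_redraw_fraction: float = 0.02,
        **estimation_kwargs) -> NCTResult:
    """Permutation test of structure (M) and global-strength (S) invariance.

    Unpaired mode pools the rows of both groups (canonically sorted, so the
    test is symmetric in its arguments for equal group sizes) and permutes
    group labels preserving group sizes. Paired mode requires participant
    metadata on both inputs and swaps each participant's rows between the
    two groups with probability 1/2. Permutations whose re-estimation fails
    are redrawn and logged; more than ``max_redraw_fraction`` of redraws
    aborts. Deterministic given ``seed``.
    """
    A, ids_a = _rows(X1)
    B, ids_b = _rows(X2)
    if A.shape[1] != B.shape[1]:
        raise ValidationError("both matrices must have the same columns")
    w1 = estimate_pcor_matrix(A, **estimation_kwargs)
    w2 = estimate_pcor_matrix(B, **estimation_kwargs)
    m_obs, s_obs = _stats(w1, w2)

    rng = np.random.default_rng(seed)
    n1 = A.shape[0]
    if paired:
        if ids_a is None or ids_b is None:
            raise ValidationError("paired mode needs StandardizedMatrix inputs "
                                  "with participant metadata")
        shared = np.intersect1d(np.unique(ids_a), np.unique(ids_b))
        if len(shared) < 2:
            raise ValidationError("paired mode needs shared participants")
    else:
        pool = np.vstack([A, B])
        pool = pool[np.lexsort(pool.T[::-1])]  # canonical row order

    count_m = 0
    count_s = 0
    n_redrawn = 0
    max_redraws = max(1, int(np.ceil(max_redraw_fraction * iterations)))
    done = 0
    while done < iterations:
        try:
            if paired:
                swap = rng.random(len(shared)) < 0.5
                swapped = set(shared[swap])
                in_a = np.array([pid in swapped for pid in ids_a])
                in_b = np.array([pid in swapped for pid in ids_b])
                g1 = np.vstack([A[~in_a], B[in_b]])
                g2 = np.vstack([B[~in_b], A[in_a]])
            else:
                perm = rng.permutation(pool.shape[0])
                g1, g2 = pool[perm[:n1]], pool[perm[n1:]]
            p1 = estimate_pcor_matrix(g1, **estimation_kwargs)
            p2 = estimate_pcor_matrix(g2, **estimation_kwargs)
        except NumericalError as exc:
            n_redrawn += 1
            logger.warning("NCT permutation redrawn: %s", exc)
            if n_redrawn > max_redraws:
                raise EstimationError(
                    f"more than {max_redraw_fraction:.0%} of NCT permutations failed")
            continue
        m_perm, s_perm = _stats(p1, p2)
        count_m += m_perm >= m_obs
        count_s += s_perm >= s_obs
        done += 1

    return NCTResult(m_observed=m_obs, s_observed=s_obs,
                     p_m=(count_m + 1) / (iterations + 1),
                     p_s=(count_s + 1) / (iterations + 1),
                     iterations=iterations, paired=paired, seed=seed,
                     n_redrawn=n_redrawn)


# ---------------------------------------------------------------------------
# hypothesis-model comparison
# ---------------------------------------------------------------------------

#: classification vocabulary for one node pair
STATUSES = ("present-sign-match", "present-sign-flip",
            "absent-though-hypothesized", "novel-edge", "correctly-absent")


@dataclass(frozen=True)
class HypothesisComparison:
    """Exhaustive classification of the 21 node pairs against the model."""

    odor_set: str
    by_pair: dict[frozenset, str]
    by_label: dict[str, str]

    def counts(self) -> dict[str, int]:
        out = {s: 0 for s in STATUSES}
        for status in self.by_pair.values():
            out[status] += 1
        return out


def compare_to_hypothesis(network: PcorNetwork, model: HypothesisModel,
                          odor_set: str) -> HypothesisComparison:
    """Classify every node pair of an estimated network against the signed
    hypothesis model for one odor valence set.

    A pair is hypothesized when the model lists a relation with a sign for
    that set; an edge is present when its weight exceeds the zero tolerance.
    Deterministic and exhaustive over all node pairs.
    """
    if odor_set not in ("pleasant", "unpleasant"):
        raise ValidationError(f"unknown odor set {odor_set!r}")
    by_pair = {}
    by_label = {}
    nodes = network.nodes
    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            a, b = nodes[i], nodes[j]
            weight = network.weights[i, j]
            present = abs(weight) > EDGE_TOL
            rel = model.relation_for_pair(a, b)
            sign = rel.sign_for(odor_set) if rel is not None else None
            if sign is None:
                status = "novel-edge" if present else "correctly-absent"
            elif not present:
                status = "absent-though-hypothesized"
            elif (weight > 0) == (sign == "+"):
                status = "present-sign-match"
            else:
                status = "present-sign-flip"
            by_pair[frozenset((a, b))] = status
            if rel is not None:
                by_label[rel.label] = status
    return HypothesisComparison(odor_set=odor_set, by_pair=by_pair, by_label=by_label)
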