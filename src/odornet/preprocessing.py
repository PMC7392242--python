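"""Outlier screening, valence-set splitting, within-individual z-scoring,
and the two descriptive checks (quadratic valence-arousal fit, intensity
homogeneity).

Standardization removes between-individual variance while keeping the
within-individual ordering of odors: each of the four rating variables is
z-scored per participant within an odor valence set. The participant-level
variables (BV, BA, T) pass through raw — they carry only between-individual
variance and are Gaussianized later by the nonparanormal transform.
All sample SDs use the n-1 denominator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datasets import NODES, validate_participants, validate_ratings
from .exceptions import ClassificationError, ValidationError

logger = logging.getLogger(__name__)

_RATING_VARS = ("valence", "arousal", "intensity", "familiarity")
_NODE_FOR_VAR = {"valence": "V", "arousal": "A", "intensity": "I", "familiarity": "F",
                 "baseline_valence": "BV", "baseline_arousal": "BA", "threshold": "T"}


# ---------------------------------------------------------------------------
# outlier screening
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OutlierReport:
    """Participants whose standardized ratings exceed the z threshold.

    ``evidence`` lists every offending (participant, odor, variable, z)
    combination. Exclusion is a separate, explicit step
    (:func:`exclude_participants`); flagging never drops data silently.
    """

    flagged: tuple[int, ...]
    evidence: pd.DataFrame
    z_threshold: float


def flag_outlier_participants(ratings: pd.DataFrame,
                              z_threshold: float = 2.0) -> OutlierReport:
    """Flag participants with any per-odor standardized rating beyond the
    threshold.

    Each rating variable is z-scored per odor across participants (n-1 SD).
    An odor/variable cell with zero cross-participant variance contributes
    z = 0 (logged as a warning).
    """
    validate_ratings(ratings)
    counts = ratings.groupby("odor_id")["participant_id"].nunique()
    if (counts < 3).any():
        raise ValidationError("each odor needs ratings from at least 3 participants")

    evidence_rows = []
    for var in _RATING_VARS:
        grp = ratings.groupby("odor_id")[var]
        mean = grp.transform("mean")
        sd = grp.transform(lambda s: s.std(ddof=1))
        zero_var = sd <= 0
        if zero_var.any():
            odors = sorted(ratings.loc[zero_var, "odor_id"].unique())
            logger.warning("zero cross-participant variance for %s, odors %s; z set to 0",
                           var, odors)
        z = np.where(zero_var, 0.0, (ratings[var] - mean) / sd.where(~zero_var, 1.0))
        over = np.abs(z) > z_threshold
        for i in np.flatnonzero(over):
            row = ratings.iloc[i]
            evidence_rows.append((int(row["participant_id"]), int(row["odor_id"]),
                                  var, float(z[i])))
    evidence = pd.DataFrame(evidence_rows,
                            columns=["participant_id", "odor_id", "variable", "z"])
    flagged = tuple(sorted(int(x) for x in evidence["participant_id"].unique()))
    return OutlierReport(flagged=flagged, evidence=evidence, z_threshold=z_threshold)


def exclude_participants(ratings: pd.DataFrame, participants: pd.DataFrame,
                         participant_ids) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop the given participants from both tables (explicit, logged)."""
    ids = set(participant_ids)
    if ids:
        logger.info("excluding %d participants: %s", len(ids), sorted(ids))
    return (ratings[~ratings["participant_id"].isin(ids)].reset_index(drop=True),
            participants[~participants["participant_id"].isin(ids)].reset_index(drop=True))


# ---------------------------------------------------------------------------
# valence-set split
# ---------------------------------------------------------------------------

def split_by_valence(ratings: pd.DataFrame) -> tuple[list[int], list[int]]:
    """Partition odors by the sign of their cross-participant mean valence.

    Returns (unpleasant_ids, pleasant_ids). A mean of exactly zero cannot be
    classified (the rule is defined only for strictly negative/positive
    means) and raises :class:`ClassificationError`.
    """
    means = ratings.groupby("odor_id")["valence"].mean()
    tied = means.index[means == 0.0].tolist()
    if tied:
        raise ClassificationError(
            f"odors with mean valence exactly 0 cannot be classified: {tied}")
    unpleasant = sorted(int(i) for i in means.index[means < 0])
    pleasant = sorted(int(i) for i in means.index[means > 0])
    return unpleasant, pleasant


# ---------------------------------------------------------------------------
# within-individual standardization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StandardizedMatrix:
    """Pooled n x 7 analysis matrix for one odor valence set.

    Columns follow the canonical node order (V, A, I, F, BV, BA, T). The
    four rating columns have mean 0 / SD 1 within each participant (or all
    zeros for a zero-variance participant); BV, BA, T repeat the
    participant's raw values on every row.
    """

    data: pd.DataFrame        # columns = NODES
    meta: pd.DataFrame        # participant_id, odor_id per row
    odor_set: str             # "pleasant" | "unpleasant"

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def participant_ids(self) -> np.ndarray:
        return self.meta["participant_id"].to_numpy()

    def __len__(self) -> int:
        return len(self.data)


def standardize_within_individual(ratings: pd.DataFrame, participants: pd.DataFrame,
                                  odor_set, set_name: str = "unspecified"
                                  ) -> StandardizedMatrix:
    """Z-score the rating variables per participant over the odors in one set.

    Participants with fewer than 2 rows in the set are excluded with a
    warning (a single row has no within-individual variance). Zero-variance
    participant/variable cells standardize to all zeros.
    """
    validate_ratings(ratings)
    validate_participants(participants)
    odor_set = sorted(set(odor_set))
    sub = ratings[ratings["odor_id"].isin(odor_set)]
    sub = sub.sort_values(["participant_id", "odor_id"], kind="mergesort")
    counts = sub.groupby("participant_id")["odor_id"].size()
    too_few = counts.index[counts < 2].tolist()
    if too_few:
        logger.warning("excluding participants with <2 odors in set %s: %s",
                       set_name, too_few)
        sub = sub[~sub["participant_id"].isin(too_few)]
    if len(sub) == 0:
        raise ValidationError(f"no rows left for odor set {set_name!r}")

    cols = {}
    for var in _RATING_VARS:
        grp = sub.groupby("participant_id")[var]
        mean = grp.transform("mean")
        sd = grp.transform(lambda s: s.std(ddof=1))
        z = (sub[var] - mean) / sd.where(sd > 0, 1.0)
        cols[_NODE_FOR_VAR[var]] = np.where(sd > 0, z, 0.0)

    part = participants.set_index("participant_id")
    missing = set(sub["participant_id"].unique()) - set(part.index)
    if missing:
        raise ValidationError(f"participants missing from participant table: {sorted(missing)}")
    for var in ("baseline_valence", "baseline_arousal", "threshold"):
        cols[_NODE_FOR_VAR[var]] = part.loc[sub["participant_id"], var].to_numpy()

    data = pd.DataFrame({n: cols[n] for n in NODES}).reset_index(drop=True)
    meta = sub[["participant_id", "odor_id"]].reset_index(drop=True)
    return StandardizedMatrix(data=data, meta=meta, odor_set=set_name)


# ---------------------------------------------------------------------------
# descriptive checks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QuadraticFit:
    """Least-squares quadratic fit of mean arousal on mean valence."""

    beta2: float
    beta1: float
    beta0: float
    r_squared: float

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return self.beta2 * x**2 + self.beta1 * x + self.beta0


def fit_quadratic_va(valence_means, arousal_means) -> QuadraticFit:
    """Ordinary least squares of per-odor mean arousal on mean valence
    (quadratic in valence); returns coefficients and R^2 = 1 - SSres/SStot."""
    x = np.asarray(valence_means, dtype=float)
    y = np.asarray(arousal_means, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("valence and arousal means must be 1-d and equal length")
    if len(np.unique(x)) < 3:
        raise ValidationError("need at least 3 distinct valence values")
    beta2, beta1, beta0 = np.polyfit(x, y, 2)
    resid = y - (beta2 * x**2 + beta1 * x + beta0)
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return QuadraticFit(float(beta2), float(beta1), float(beta0), r2)


def intensity_homogeneity(intensity_means) -> float:
    """Largest relative deviation (%) of a per-odor mean intensity from the
    grand mean across odors."""
    x = np.asarray(intensity_means, dtype=float)
    if len(x) < 2:
        raise ValidationError("need at least 2 intensity means")
    grand = x.mean()
    if grand == 0:
        raise ValidationError("grand mean intensity is zero")
    return float(100.0 * np.max(np.abs(x - grand)) / grand)
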