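"""Synthetic study generator and staircase threshold simulation.

The generator emulates the observational design the analysis assumes: each of
``n_participants`` observers contributes one row per odor, with the four
rating variables (V, A, I, F) varying per row and the three participant-level
variables (BV, BA, T) constant within participant. The joint dependence
structure is controlled by a target partial-correlation network per odor
valence set: the implied precision matrix (unit diagonal, off-diagonal
``-rho``) is inverted to a covariance, the participant-level block is sampled
once per participant, and the rating block is sampled per row from the
conditional Gaussian given the participant's values. Latent scores are then
mapped affinely onto the per-odor means/SDs of the odor profiles and clipped
to the scale ranges.

``simulate_staircase`` reproduces the adaptive triple-forced-choice threshold
test: a single staircase over 16 dilution levels (1 strongest .. 16 weakest)
that steps toward weaker concentrations after two successive correct
detections and toward stronger concentrations after a miss, terminating after
seven reversals; the threshold is the mean of the last four reversal levels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datasets import (
    NODES,
    SCALE_RANGES,
    OdorProfile,
    PcorNetwork,
    load_odor_profiles,
    load_reference_networks,
    validate_participants,
    validate_ratings,
)
from .exceptions import ConstructionError, ValidationError

_RATING_VARS = ("valence", "arousal", "intensity", "familiarity")  # node order V, A, I, F
_PARTICIPANT_VARS = ("baseline_valence", "baseline_arousal", "threshold")  # BV, BA, T


# ---------------------------------------------------------------------------
# covariance construction
# ---------------------------------------------------------------------------

def build_covariance_from_pcor(network: PcorNetwork,
                               unit_precision_diagonal: bool = True) -> np.ndarray:
    """Covariance matrix whose partial correlations equal the target network.

    The precision matrix is taken as ``Theta = I - W`` (unit diagonal,
    off-diagonal ``-rho_ij``); the returned covariance is its inverse. The
    construction is exact: recomputing partial correlations from the result
    reproduces the network to numerical precision.
    """
    if not unit_precision_diagonal:
        raise ValidationError("only the unit-precision-diagonal construction is defined")
    w = network.weights
    theta = np.eye(len(network.nodes)) - w
    eigvals = np.linalg.eigvalsh(theta)
    if eigvals[0] <= 0:
        raise ConstructionError(
            f"implied precision matrix is not positive definite "
            f"(smallest eigenvalue {eigvals[0]:.6g})")
    sigma = np.linalg.inv(theta)
    return (sigma + sigma.T) / 2.0


def partial_correlations_from_covariance(sigma: np.ndarray) -> np.ndarray:
    """Partial correlation matrix (zero diagonal) implied by a covariance."""
    theta = np.linalg.inv(sigma)
    d = np.sqrt(np.diag(theta))
    pcor = -theta / np.outer(d, d)
    np.fill_diagonal(pcor, 0.0)
    return (pcor + pcor.T) / 2.0


# ---------------------------------------------------------------------------
# study simulation
# ---------------------------------------------------------------------------

def uniform_profiles(n_odors: int = 40, n_unpleasant: int = 16) -> list[OdorProfile]:
    """Homogeneous odor profiles for calibration runs.

    All odors within a valence set share one mean/SD per variable (valence
    mean -1 for the first ``n_unpleasant`` odors, +1 for the rest), so pooled
    correlations reflect only the target network, not between-odor mean
    structure.
    """
    profiles = []
    for k in range(1, n_odors + 1):
        vmean = -1.0 if k <= n_unpleasant else 1.0
        profiles.append(OdorProfile(
            odor_id=k, label=f"synthetic-{k}", code="synthetic",
            valence_mean=vmean, valence_sd=1.2,
            arousal_mean=0.0, arousal_sd=1.2,
            familiarity_mean=50.0, familiarity_sd=12.0,
            intensity_mean=50.0, intensity_sd=12.0))
    return profiles


@dataclass
class GeneratorConfig:
    """Study conditions for :func:`simulate_study`.

    Defaults reproduce the reference study: 52 participants rating the 40
    packaged odors whose per-odor means/SDs match the published table, with
    the two published networks as dependence targets. ``participant_scales``
    gives the population mean/SD used to map the latent participant variables
    onto their scales; the study reports no population values for these, so
    neutral baselines and a mid-range threshold typical of normosmic young
    adults are used.
    """

    n_participants: int = 52
    profiles: Sequence[OdorProfile] | None = None
    targets: Mapping[str, PcorNetwork] | None = None
    seed: int = 0
    hierarchical: bool = True
    exact_participant_covariance: bool = False
    participant_scales: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"baseline_valence": (0.8, 1.2),
                                 "baseline_arousal": (0.0, 1.2),
                                 "threshold": (8.5, 2.5)})

    def resolve(self) -> tuple[list[OdorProfile], dict[str, PcorNetwork]]:
        profiles = list(self.profiles) if self.profiles is not None else load_odor_profiles()
        if self.targets is None:
            uoea, poea = load_reference_networks()
            targets = {"unpleasant": uoea, "pleasant": poea}
        else:
            targets = dict(self.targets)
        for name in ("unpleasant", "pleasant"):
            if name not in targets:
                raise ValidationError(f"targets must include the {name!r} network")
            if targets[name].nodes != NODES:
                raise ValidationError(f"target {name!r} must use node order {NODES}")
        return profiles, targets


def _clip(x: np.ndarray, var: str) -> np.ndarray:
    lo, hi = SCALE_RANGES[var]
    return np.clip(x, lo, hi)


def simulate_study(cfg: GeneratorConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a (ratings, participants) table pair under the target networks.

    Deterministic given ``cfg.seed``: identical configs produce bit-identical
    tables. Odors with negative profile valence mean follow the unpleasant
    target network, the rest the pleasant one. With ``hierarchical=False``
    the rating block is drawn from its marginal instead of the conditional
    given the participant values (rows become independent of BV/BA/T), which
    isolates the within-block structure for calibration tests.
    """
    if cfg.n_participants < 2:
        raise ValidationError("need at least 2 participants")
    profiles, targets = cfg.resolve()
    rng = np.random.default_rng(cfg.seed)

    sigma = {name: build_covariance_from_pcor(net) for name, net in targets.items()}
    # participant-level block (BV, BA, T) comes from the unpleasant target;
    # the packaged targets agree on this block.
    p_idx = np.array([4, 5, 6])
    o_idx = np.array([0, 1, 2, 3])
    sig_u = sigma["unpleasant"]
    sig_pp = sig_u[np.ix_(p_idx, p_idx)]
    chol_pp = np.linalg.cholesky(sig_pp)
    z_part = rng.standard_normal((cfg.n_participants, 3)) @ chol_pp.T
    if cfg.exact_participant_covariance:
        # whiten the realized draws and re-color, so the sample covariance of
        # the participant latents equals the target block exactly; the
        # participant block carries only n_participants of information, and
        # this removes its sampling noise for calibration runs
        if cfg.n_participants <= 3:
            raise ValidationError("exact participant covariance needs > 3 participants")
        z_c = z_part - z_part.mean(axis=0)
        emp = np.cov(z_c, rowvar=False, ddof=1)
        z_white = z_c @ np.linalg.inv(np.linalg.cholesky(emp)).T
        z_part = z_white @ chol_pp.T

    participant_ids = np.arange(1, cfg.n_participants + 1)
    part_rows = {"participant_id": participant_ids}
    for k, var in enumerate(_PARTICIPANT_VARS):
        mean, sd = cfg.participant_scales[var]
        latent = z_part[:, k] / np.sqrt(sig_pp[k, k])
        part_rows[var] = _clip(mean + sd * latent, var)
    participants = pd.DataFrame(part_rows)

    sets = {"unpleasant": [p for p in profiles if p.valence_mean < 0],
            "pleasant": [p for p in profiles if p.valence_mean > 0]}
    tied = [p.odor_id for p in profiles if p.valence_mean == 0]
    if tied:
        raise ValidationError(f"profiles with valence mean exactly 0 cannot be assigned: {tied}")

    frames = []
    for name in ("unpleasant", "pleasant"):
        set_profiles = sets[name]
        if not set_profiles:
            continue
        sig = sigma[name]
        sig_oo = sig[np.ix_(o_idx, o_idx)]
        n_odors = len(set_profiles)
        n_rows = cfg.n_participants * n_odors
        if cfg.hierarchical:
            coef = sig[np.ix_(o_idx, p_idx)] @ np.linalg.inv(sig[np.ix_(p_idx, p_idx)])
            cond_cov = sig_oo - coef @ sig[np.ix_(p_idx, o_idx)]
            cond_mean = z_part @ coef.T  # (n_participants, 4)
            chol_c = np.linalg.cholesky(cond_cov)
            eps = rng.standard_normal((n_rows, 4)) @ chol_c.T
            latent = np.repeat(cond_mean, n_odors, axis=0) + eps
        else:
            chol_o = np.linalg.cholesky(sig_oo)
            latent = rng.standard_normal((n_rows, 4)) @ chol_o.T
        latent = latent / np.sqrt(np.diag(sig_oo))  # unit marginal SD

        rows = {"participant_id": np.repeat(participant_ids, n_odors),
                "odor_id": np.tile([p.odor_id for p in set_profiles], cfg.n_participants)}
        for k, var in enumerate(_RATING_VARS):
            means = np.tile([getattr(p, f"{var}_mean") for p in set_profiles],
                            cfg.n_participants)
            sds = np.tile([getattr(p, f"{var}_sd") for p in set_profiles],
                          cfg.n_participants)
            rows[var] = _clip(means + sds * latent[:, k], var)
        frames.append(pd.DataFrame(rows))

    ratings = (pd.concat(frames, ignore_index=True)
               .sort_values(["participant_id", "odor_id"], kind="mergesort")
               .reset_index(drop=True))
    return validate_ratings(ratings), validate_participants(participants)


# ---------------------------------------------------------------------------
# staircase simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StaircaseResult:
    """Trial log and threshold estimate of one staircase run."""

    trials: tuple[tuple[int, bool], ...]  # (dilution level, correct flag)
    reversal_levels: tuple[int, ...]
    threshold: float
    complete: bool


def simulate_staircase(true_level: float, guess_rate: float = 1.0 / 3.0,
                       lapse: float = 0.0, seed: int | None = None,
                       start_level: int = 16, step: int = 1,
                       n_reversals: int = 7, average_last: int = 4,
                       max_trials: int = 400) -> StaircaseResult:
    """Simulate the adaptive forced-choice detection-threshold staircase.

    The responder detects the odorant with probability ``1 - lapse`` whenever
    the presented level is at or below ``true_level`` (stronger or equal
    concentration) and otherwise guesses among the three pens, so the correct
    response probability is ``detection + (1 - detection) * guess_rate``.
    Levels are whole numbers clamped to [1, 16]. On normal termination the
    threshold is the arithmetic mean of the last ``average_last`` reversal
    levels; if the trial cap is reached first the result is flagged
    incomplete and the threshold falls back to the mean of the reversals seen
    so far (or the current level when none occurred).
    """
    if not 1 <= start_level <= 16:
        raise ValidationError("start_level must be in [1, 16]")
    rng = np.random.default_rng(seed)
    level = int(start_level)
    trials: list[tuple[int, bool]] = []
    reversals: list[int] = []
    last_direction = 0
    consecutive_correct = 0
    complete = False

    for _ in range(max_trials):
        detection = (1.0 - lapse) if level <= true_level else 0.0
        p_correct = detection + (1.0 - detection) * guess_rate
        correct = bool(rng.random() < p_correct)
        trials.append((level, correct))

        move = 0
        if correct:
            consecutive_correct += 1
            if consecutive_correct == 2:
                consecutive_correct = 0
                move = +1  # toward 16: weaker concentration
        else:
            consecutive_correct = 0
            move = -1  # toward 1: stronger concentration

        if move != 0:
            if last_direction != 0 and move != last_direction:
                reversals.append(level)
                if len(reversals) == n_reversals:
                    complete = True
                    break
            last_direction = move
            level = int(np.clip(level + move * step, 1, 16))

    if complete:
        threshold = float(np.mean(reversals[-average_last:]))
    elif reversals:
        threshold = float(np.mean(reversals))
    else:
        threshold = float(level)
    return StaircaseResult(tuple(trials), tuple(reversals), threshold, complete)


# ---------------------------------------------------------------------------
# outlier injection (test support for the exclusion rule)
# ---------------------------------------------------------------------------

def inject_outlier(ratings: pd.DataFrame, participant_id: int, odor_id: int,
                   variable: str, z_offset: float) -> pd.DataFrame:
    """Replace one rating with (per-odor mean + z_offset * per-odor SD).

    The per-odor statistics are taken across participants before the
    replacement; the result is clipped to the variable's scale range.
    """
    if variable not in _RATING_VARS:
        raise ValidationError(f"unknown rating variable {variable!r}")
    mask = (ratings["participant_id"] == participant_id) & (ratings["odor_id"] == odor_id)
    if not mask.any():
        raise ValidationError(
            f"no row for participant {participant_id}, odor {odor_id}")
    per_odor = ratings.loc[ratings["odor_id"] == odor_id, variable]
    value = per_odor.mean() + z_offset * per_odor.std(ddof=1)
    out = ratings.copy()
    out.loc[mask, variable] = _clip(np.asarray(value, dtype=float), variable)
    return out
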