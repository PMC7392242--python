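"""Core domain types, packaged reference fixtures, and table/network IO.

The package models odor-evoked affect with seven variables: per-odor valence
(V) and arousal (A) on a [-4, 4] grid, intensity (I) and familiarity (F) on a
[0, 100] slider, and three participant-level variables — baseline valence (BV)
and arousal (BA) on [-4, 4], and the Sniffin'-Sticks odor detection threshold
(T) on [1, 16]. All matrices in the package use the fixed node order
``("V", "A", "I", "F", "BV", "BA", "T")``.

Three fixtures ship with the package:

* 40 odor rating profiles (per-odor mean/SD of the four rating variables),
* the two published reference partial-correlation networks (unpleasant-odor
  UOEA and pleasant-odor POEA; absent relations are structural zeros),
* the literature-derived hypothesis model with signed relations R1..R14.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import IntegrityError, SchemaError, ValidationError

#: canonical node order used by every matrix in the package
NODES: tuple[str, ...] = ("V", "A", "I", "F", "BV", "BA", "T")

#: inclusive scale ranges per variable
SCALE_RANGES: dict[str, tuple[float, float]] = {
    "valence": (-4.0, 4.0),
    "arousal": (-4.0, 4.0),
    "intensity": (0.0, 100.0),
    "familiarity": (0.0, 100.0),
    "baseline_valence": (-4.0, 4.0),
    "baseline_arousal": (-4.0, 4.0),
    "threshold": (1.0, 16.0),
}

RATING_COLUMNS = ("participant_id", "odor_id", "valence", "arousal", "intensity", "familiarity")
PARTICIPANT_COLUMNS = ("participant_id", "baseline_valence", "baseline_arousal", "threshold")

#: absolute weight below which an edge counts as absent
EDGE_TOL = 1e-8


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OdorProfile:
    """Per-odor rating profile: mean (SD) of the four rating variables."""

    odor_id: int
    label: str
    code: str
    valence_mean: float
    valence_sd: float
    arousal_mean: float
    arousal_sd: float
    familiarity_mean: float
    familiarity_sd: float
    intensity_mean: float
    intensity_sd: float

    def validate(self) -> None:
        for var in ("valence", "arousal", "familiarity", "intensity"):
            lo, hi = SCALE_RANGES[var]
            mean = getattr(self, f"{var}_mean")
            sd = getattr(self, f"{var}_sd")
            if not lo <= mean <= hi:
                raise IntegrityError(f"odor {self.odor_id}: {var}_mean {mean} outside [{lo}, {hi}]")
            if sd < 0:
                raise IntegrityError(f"odor {self.odor_id}: {var}_sd {sd} negative")


@dataclass(frozen=True)
class PcorNetwork:
    """Symmetric weighted network of regularized partial correlations.

    ``weights[i, j]`` is the partial correlation between ``nodes[i]`` and
    ``nodes[j]`` conditioned on every other node; the diagonal is exactly 0
    and absent edges are exact zeros (the lasso shrinks them to zero).
    """

    nodes: tuple[str, ...]
    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        p = len(self.nodes)
        if w.shape != (p, p):
            raise ValidationError(f"weight matrix shape {w.shape} does not match {p} nodes")
        if not np.array_equal(w, w.T):
            raise ValidationError("weight matrix is not exactly symmetric")
        if np.any(np.diag(w) != 0.0):
            raise ValidationError("weight matrix diagonal must be exactly zero")
        if np.any(np.abs(w) >= 1.0):
            raise ValidationError("partial correlations must satisfy |rho| < 1")

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str, float]],
                   nodes: Sequence[str] = NODES) -> "PcorNetwork":
        nodes = tuple(nodes)
        idx = {n: i for i, n in enumerate(nodes)}
        w = np.zeros((len(nodes), len(nodes)))
        for a, b, rho in edges:
            if a not in idx or b not in idx:
                raise ValidationError(f"edge ({a}, {b}) uses a node outside {nodes}")
            w[idx[a], idx[b]] = w[idx[b], idx[a]] = float(rho)
        return cls(nodes, w)

    def weight(self, a: str, b: str) -> float:
        i, j = self.nodes.index(a), self.nodes.index(b)
        return float(self.weights[i, j])

    def edges(self, tol: float = EDGE_TOL) -> list[tuple[str, str, float]]:
        """Nonzero edges as (node_a, node_b, weight), upper triangle order."""
        out = []
        p = len(self.nodes)
        for i in range(p):
            for j in range(i + 1, p):
                if abs(self.weights[i, j]) > tol:
                    out.append((self.nodes[i], self.nodes[j], float(self.weights[i, j])))
        return out

    def upper_triangle(self) -> np.ndarray:
        """The 21 (for 7 nodes) vectorized upper-triangle weights."""
        iu = np.triu_indices(len(self.nodes), k=1)
        return self.weights[iu]

    def to_dict(self) -> dict:
        return {"nodes": list(self.nodes),
                "weights": [float(x) for x in self.weights.ravel()]}

    @classmethod
    def from_dict(cls, d: Mapping) -> "PcorNetwork":
        nodes = tuple(d["nodes"])
        p = len(nodes)
        w = np.asarray(d["weights"], dtype=float).reshape(p, p)
        return cls(nodes, w)


@dataclass(frozen=True)
class HypothesisRelation:
    """One literature-derived relation with its expected sign per odor set."""

    label: str
    pair: tuple[str, str]
    unpleasant_sign: str | None  # "+", "-" or None when absent from that set
    pleasant_sign: str | None

    def sign_for(self, odor_set: str) -> str | None:
        if odor_set == "unpleasant":
            return self.unpleasant_sign
        if odor_set == "pleasant":
            return self.pleasant_sign
        raise ValidationError(f"unknown odor set {odor_set!r}")


@dataclass(frozen=True)
class HypothesisModel:
    """The signed hypothesis networks for unpleasant and pleasant odors."""

    relations: tuple[HypothesisRelation, ...] = field(default_factory=tuple)

    def validate(self) -> None:
        labels = [r.label for r in self.relations]
        if len(set(labels)) != len(labels):
            raise IntegrityError("hypothesis relation labels are not unique")
        pairs = [frozenset(r.pair) for r in self.relations]
        if len(set(pairs)) != len(pairs):
            raise IntegrityError("hypothesis relation node pairs are not unique")
        for r in self.relations:
            for n in r.pair:
                if n not in NODES:
                    raise IntegrityError(f"{r.label}: node {n} not among {NODES}")
            for s in (r.unpleasant_sign, r.pleasant_sign):
                if s not in (None, "+", "-"):
                    raise IntegrityError(f"{r.label}: invalid sign {s!r}")

    def relation_for_pair(self, a: str, b: str) -> HypothesisRelation | None:
        key = frozenset((a, b))
        for r in self.relations:
            if frozenset(r.pair) == key:
                return r
        return None

    def n_relations(self) -> int:
        return len(self.relations)


def minimum_sample_size(model: HypothesisModel, per_parameter: int = 3) -> int:
    """Rule-of-thumb minimal group size: ``per_parameter`` observers per
    hypothesized edge (3 x 14 = 42 for the packaged model)."""
    return per_parameter * model.n_relations()


# ---------------------------------------------------------------------------
# packaged fixtures
# ---------------------------------------------------------------------------

def _data_path(name: str):
    return resources.files("odornet.data").joinpath(name)


def load_odor_profiles() -> list[OdorProfile]:
    """The 40 packaged odor rating profiles (means and SDs per odor)."""
    with _data_path("odor_profiles.csv").open("r", encoding="utf-8") as fh:
        df = pd.read_csv(fh)
    profiles = [OdorProfile(odor_id=int(r.odor_id), label=r.label, code=r.code,
                            valence_mean=r.valence_mean, valence_sd=r.valence_sd,
                            arousal_mean=r.arousal_mean, arousal_sd=r.arousal_sd,
                            familiarity_mean=r.familiarity_mean, familiarity_sd=r.familiarity_sd,
                            intensity_mean=r.intensity_mean, intensity_sd=r.intensity_sd)
                for r in df.itertuples()]
    if len(profiles) != 40:
        raise IntegrityError(f"expected 40 odor profiles, found {len(profiles)}")
    ids = {p.odor_id for p in profiles}
    if ids != set(range(1, 41)):
        raise IntegrityError("odor ids are not exactly 1..40")
    for p in profiles:
        p.validate()
    return profiles


def load_reference_networks() -> tuple[PcorNetwork, PcorNetwork]:
    """The packaged reference networks (UOEA, POEA).

    Relations absent from the published tables are stored as exact structural
    zeros: the lasso shrank them to zero, they are not missing values.
    """
    with _data_path("reference_networks.json").open("r", encoding="utf-8") as fh:
        d = json.load(fh)
    if tuple(d["nodes"]) != NODES:
        raise IntegrityError("reference network node order is corrupted")
    uoea = PcorNetwork.from_edges([tuple(e) for e in d["uoea"]["edges"]])
    poea = PcorNetwork.from_edges([tuple(e) for e in d["poea"]["edges"]])
    if len(uoea.edges()) != 6 or len(poea.edges()) != 7:
        raise IntegrityError("reference networks do not have the expected 6/7 edges")
    return uoea, poea


def load_hypothesis_model() -> HypothesisModel:
    """The literature-derived hypothesis model (relations R1..R14)."""
    with _data_path("hypothesis_model.json").open("r", encoding="utf-8") as fh:
        d = json.load(fh)
    rels = tuple(HypothesisRelation(label=r["label"], pair=tuple(r["pair"]),
                                    unpleasant_sign=r["unpleasant"], pleasant_sign=r["pleasant"])
                 for r in d["relations"])
    model = HypothesisModel(rels)
    model.validate()
    if model.n_relations() != 14:
        raise IntegrityError("hypothesis model must contain 14 relations")
    return model


# ---------------------------------------------------------------------------
# rating-table IO
# ---------------------------------------------------------------------------

def validate_ratings(ratings: pd.DataFrame) -> pd.DataFrame:
    """Validate a long-format rating table (one row per participant x odor)."""
    missing = [c for c in RATING_COLUMNS if c not in ratings.columns]
    if missing:
        raise SchemaError(f"rating table missing columns: {missing}")
    if len(ratings) == 0:
        raise SchemaError("rating table is empty")
    if ratings.duplicated(subset=["participant_id", "odor_id"]).any():
        raise ValidationError("duplicate (participant, odor) rows in rating table")
    for var in ("valence", "arousal", "intensity", "familiarity"):
        lo, hi = SCALE_RANGES[var]
        bad = ratings[(ratings[var] < lo) | (ratings[var] > hi)]
        if len(bad):
            row = bad.iloc[0]
            raise ValidationError(
                f"{var} value {row[var]} outside [{lo}, {hi}] "
                f"(participant {row['participant_id']}, odor {row['odor_id']})")
    return ratings


def validate_participants(participants: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in PARTICIPANT_COLUMNS if c not in participants.columns]
    if missing:
        raise SchemaError(f"participant table missing columns: {missing}")
    if len(participants) == 0:
        raise SchemaError("participant table is empty")
    if participants["participant_id"].duplicated().any():
        raise ValidationError("duplicate participant ids in participant table")
    for var in ("baseline_valence", "baseline_arousal", "threshold"):
        lo, hi = SCALE_RANGES[var]
        bad = participants[(participants[var] < lo) | (participants[var] > hi)]
        if len(bad):
            row = bad.iloc[0]
            raise ValidationError(
                f"{var} value {row[var]} outside [{lo}, {hi}] "
                f"(participant {row['participant_id']})")
    return participants


def read_ratings(ratings_path, participants_path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read and validate the rating and participant CSV tables."""
    try:
        ratings = pd.read_csv(ratings_path)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"empty ratings file: {ratings_path}") from exc
    try:
        participants = pd.read_csv(participants_path)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"empty participant file: {participants_path}") from exc
    return validate_ratings(ratings), validate_participants(participants)


def write_ratings(ratings: pd.DataFrame, participants: pd.DataFrame,
                  ratings_path, participants_path) -> None:
    validate_ratings(ratings).to_csv(ratings_path, index=False)
    validate_participants(participants).to_csv(participants_path, index=False)


# ---------------------------------------------------------------------------
# network IO: JSON (canonical, lossless) and GraphML (export)
# ---------------------------------------------------------------------------

_NETWORK_SCHEMA = "odornet.pcor-network/1"


def write_network(network: PcorNetwork, path, format: str = "json") -> None:
    """Write a network to disk; JSON round-trips bit-identically."""
    path = Path(path)
    if format == "json":
        doc = {"schema": _NETWORK_SCHEMA, **network.to_dict()}
        path.write_text(json.dumps(doc, indent=1) + "\n", encoding="utf-8")
    elif format == "graphml":
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(network.nodes)
        for a, b, w in network.edges():
            g.add_edge(a, b, weight=w)
        nx.write_graphml(g, path)
    else:
        raise ValidationError(f"unknown network format {format!r}")


def read_network(path) -> PcorNetwork:
    """Read a network from its canonical JSON representation."""
    path = Path(path)
    try:
        doc = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise SchemaError(f"not a network JSON file: {path}") from exc
    if doc.get("schema") != _NETWORK_SCHEMA:
        raise SchemaError(f"unexpected network schema {doc.get('schema')!r}")
    return PcorNetwork.from_dict(doc)
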