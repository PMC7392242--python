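"""End-to-end orchestration: simulate/load -> preprocess -> estimate ->
analyze -> robustness -> compare -> report.

A single :class:`RunConfig` (JSON or YAML on disk) drives the run; every
stochastic stage gets its own child seed derived deterministically from the
run seed, so a config fully determines the report (timestamps excluded).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .comparison import compare_to_hypothesis, nct
from .datasets import (
    load_hypothesis_model,
    load_reference_networks,
    minimum_sample_size,
    read_ratings,
)
from .exceptions import ValidationError
from .ggm import estimate_network
from .metrics import (
    centrality_report,
    connected_components,
    edge_summary,
    edge_weight_correlation,
    global_strength,
)
from .preprocessing import (
    exclude_participants,
    fit_quadratic_va,
    flag_outlier_participants,
    intensity_homogeneity,
    split_by_valence,
    standardize_within_individual,
)
from .robustness import bootstrap_edge_cis, case_dropping_stability, cs_coefficient
from .synthetic import GeneratorConfig, simulate_study

logger = logging.getLogger(__name__)

REPORT_SCHEMA = "odornet.run-report/1"


@dataclass
class RunConfig:
    """All stage parameters of one pipeline run.

    Defaults mirror the reference analysis settings (gamma 0.5, 1000-point
    penalty grid, 1000 bootstrap replicates, 10000 permutation iterations);
    desk-scale runs should lower ``bootstrap_B``, ``stability_B`` and
    ``nct_iterations``.
    """

    seed: int = 7
    n_participants: int = 52
    ratings_path: str | None = None        # load instead of simulate when set
    participants_path: str | None = None
    z_threshold: float = 2.0
    exclude_flagged: bool = False  # flagging reports evidence; dropping is opt-in
    gamma: float = 0.5
    n_lambda: int = 1000
    min_ratio: float = 0.01
    bootstrap_B: int = 0                   # 0 disables the stage
    stability_B: int = 0
    drop_grid: tuple = tuple(np.round(np.arange(0.05, 0.80, 0.05), 2))
    nct_iterations: int = 0
    nct_paired: bool = False
    out_dir: str | None = None

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text(encoding="utf-8")
        try:
            data = json.loads(text)
        except json.JSONDecodeError:
            data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ValidationError(f"config file {path} must contain a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.drop_grid = tuple(float(d) for d in cfg.drop_grid)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["drop_grid"] = list(self.drop_grid)
        return d


def _stage_seeds(seed: int) -> dict[str, int]:
    """Deterministic child seeds (below 2^31) for the stochastic stages."""
    ss = np.random.SeedSequence(seed)
    names = ("simulate", "bootstrap_unpleasant", "bootstrap_pleasant",
             "stability_unpleasant", "stability_pleasant", "nct")
    states = ss.generate_state(len(names)) % (2**31)
    return {name: int(s) for name, s in zip(names, states)}


def _network_block(net, fit=None) -> dict:
    n_edges, n_pos, n_neg = edge_summary(net)
    rep = centrality_report(net)
    block = {
        "nodes": list(net.nodes),
        "weights": [[float(x) for x in row] for row in net.weights],
        "n_edges": n_edges,
        "n_positive": n_pos,
        "n_negative": n_neg,
        "global_strength": global_strength(net),
        "components": [sorted(c) for c in connected_components(net)],
        "centrality_raw": rep.raw.round(10).to_dict(),
        "centrality_z": rep.z.round(10).to_dict(),
    }
    if fit is not None:
        block["fit"] = {"lambda": fit.lambda_, "gamma": fit.gamma, "n": fit.n,
                        "ebic": fit.ebic, "loglik": fit.loglik,
                        "n_edges": fit.n_edges}
    return block


def reference_summary() -> dict:
    """Summary of the packaged reference networks (no estimation)."""
    uoea, poea = load_reference_networks()
    model = load_hypothesis_model()
    return {
        "uoea": _network_block(uoea),
        "poea": _network_block(poea),
        "edge_weight_correlation": edge_weight_correlation(uoea, poea),
        "minimum_sample_size": minimum_sample_size(model),
        "hypothesis": {
            "unpleasant": compare_to_hypothesis(uoea, model, "unpleasant").by_label,
            "pleasant": compare_to_hypothesis(poea, model, "pleasant").by_label,
        },
    }


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all configured stages in order and return the run report."""
    seeds = _stage_seeds(cfg.seed)
    report: dict = {"schema": REPORT_SCHEMA, "config": cfg.to_dict(),
                    "stage_seeds": seeds, "stages": {}}

    # --- data ---------------------------------------------------------
    if cfg.ratings_path is not None:
        if cfg.participants_path is None:
            raise ValidationError("participants_path required with ratings_path")
        ratings, participants = read_ratings(cfg.ratings_path, cfg.participants_path)
        report["stages"]["data"] = {"source": "files",
                                    "ratings_path": str(cfg.ratings_path)}
    else:
        gen = GeneratorConfig(n_participants=cfg.n_participants, seed=seeds["simulate"])
        ratings, participants = simulate_study(gen)
        report["stages"]["data"] = {"source": "simulated", "seed": seeds["simulate"]}
    report["stages"]["data"].update(n_rows=len(ratings), n_participants=len(participants))

    # --- preprocessing ------------------------------------------------
    outliers = flag_outlier_participants(ratings, z_threshold=cfg.z_threshold)
    if cfg.exclude_flagged and outliers.flagged:
        ratings, participants = exclude_participants(ratings, participants,
                                                     outliers.flagged)
    unpleasant_ids, pleasant_ids = split_by_valence(ratings)
    odor_means = ratings.groupby("odor_id")[["valence", "arousal", "intensity"]].mean()
    quad = fit_quadratic_va(odor_means["valence"], odor_means["arousal"])
    homogeneity = intensity_homogeneity(odor_means["intensity"])
    report["stages"]["preprocess"] = {
        "flagged_participants": list(outliers.flagged),
        "excluded": bool(cfg.exclude_flagged and outliers.flagged),
        "n_unpleasant_odors": len(unpleasant_ids),
        "n_pleasant_odors": len(pleasant_ids),
        "unpleasant_odor_ids": unpleasant_ids,
        "pleasant_odor_ids": pleasant_ids,
        "quadratic_fit": {"beta2": quad.beta2, "beta1": quad.beta1,
                          "beta0": quad.beta0, "r_squared": quad.r_squared},
        "intensity_homogeneity_pct": homogeneity,
    }

    matrices = {
        "unpleasant": standardize_within_individual(ratings, participants,
                                                    unpleasant_ids, "unpleasant"),
        "pleasant": standardize_within_individual(ratings, participants,
                                                  pleasant_ids, "pleasant"),
    }

    # --- estimation + analysis ----------------------------------------
    est = {"gamma": cfg.gamma, "n_lambda": cfg.n_lambda, "min_ratio": cfg.min_ratio}
    networks = {}
    report["stages"]["networks"] = {}
    for name, X in matrices.items():
        net, fit = estimate_network(X, **est)
        networks[name] = net
        report["stages"]["networks"][name] = _network_block(net, fit)
    report["stages"]["comparison"] = {
        "edge_weight_correlation": edge_weight_correlation(
            networks["unpleasant"], networks["pleasant"]),
    }

    # --- robustness (optional) ----------------------------------------
    if cfg.bootstrap_B > 0 or cfg.stability_B > 0:
        rob = {}
        for name, X in matrices.items():
            block = {}
            if cfg.bootstrap_B > 0:
                boot = bootstrap_edge_cis(X, B=cfg.bootstrap_B,
                                          seed=seeds[f"bootstrap_{name}"], **est)
                block["bootstrap"] = {
                    "B": boot.B, "level": boot.level,
                    "pairs": [list(pr) for pr in boot.pairs],
                    "point": boot.point.tolist(),
                    "lower": boot.lower.tolist(),
                    "upper": boot.upper.tolist(),
                }
            if cfg.stability_B > 0:
                stab = case_dropping_stability(X, drop_grid=cfg.drop_grid,
                                               B=cfg.stability_B,
                                               seed=seeds[f"stability_{name}"], **est)
                block["cs_coefficients"] = cs_coefficient(stab)
            rob[name] = block
        report["stages"]["robustness"] = rob

    # --- network comparison test (optional) ---------------------------
    if cfg.nct_iterations > 0:
        res = nct(matrices["unpleasant"], matrices["pleasant"],
                  iterations=cfg.nct_iterations, paired=cfg.nct_paired,
                  seed=seeds["nct"], **est)
        report["stages"]["comparison"].update(
            nct={"m_observed": res.m_observed, "s_observed": res.s_observed,
                 "p_m": res.p_m, "p_s": res.p_s, "iterations": res.iterations,
                 "paired": res.paired})

    # --- hypothesis comparison ----------------------------------------
    model = load_hypothesis_model()
    report["stages"]["hypothesis"] = {
        name: compare_to_hypothesis(networks[name], model, name).by_label
        for name in networks
    }
    report["summary"] = {
        "edge_counts": {name: report["stages"]["networks"][name]["n_edges"]
                        for name in networks},
        "global_strength": {name: report["stages"]["networks"][name]["global_strength"]
                            for name in networks},
        "edge_weight_correlation":
            report["stages"]["comparison"]["edge_weight_correlation"],
    }

    if cfg.out_dir is not None:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True),
                                         encoding="utf-8")
    return report
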