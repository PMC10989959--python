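"""Discovery/validation orchestration and evaluation utilities.

``run_discovery`` executes the full subtyping chain — background network,
rank transform, delta ranks, normal benchmark, perturbation matrices, dual
top-K feature selection, subsampled PAM consensus clustering, signature
derivation — from a single configuration mapping, logging the counts at every
stage and returning a reproducibility manifest alongside the results.
``run_validation`` re-assigns subtypes in a new cohort by nearest-template
prediction and checks subtype correspondence against the discovery cohort.

Evaluation helpers: adjusted Rand index against a reference labeling,
Kaplan-Meier curves, and the k-group log-rank test.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from sklearn.metrics import adjusted_rand_score

from . import consensus as consensus_mod
from . import io as net_io
from . import simulate as simulate_mod
from .correspond import CorrespondenceResult, subtype_correspondence
from .featsel import FeatureSelection, select_features
from .ntp import SignatureSet, derive_signatures, ntp_classify
from .perturb import (
    benchmark_from_normals,
    delta_rank,
    perturbation,
    perturbation_magnitude,
    rank_transform,
)

logger = logging.getLogger(__name__)

__all__ = [
    "RunManifest",
    "DiscoveryResult",
    "ValidationResult",
    "DEFAULT_CONFIG",
    "load_config",
    "compute_perturbation",
    "run_discovery",
    "run_validation",
    "adjusted_rand_index",
    "majority_label_map",
    "logrank_test",
    "kaplan_meier",
]

VERSION = "netperturb 0.1.0"

# every tunable of the method surfaces here with its reference default
DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "min_confidence": 0.7,
    "k_p": 4000,
    "k_sd": 4000,
    "k_min": 2,
    "k_max": 9,
    "n_reps": 1000,
    "subsample_fraction": 0.8,
    "stability_threshold": 0.1,
    "k": None,  # override the CDF-based choice
    "n_per_subtype": 300,
    "ntp_fdr": 0.2,
    "ntp_resample": 1000,
    "correspondence_perm": 1000,
    "correspondence_alpha": 0.05,
}


@dataclass
class RunManifest:
    """Reproducibility record: resolved config, seeds, output digests."""

    resolved_config: dict[str, Any]
    seed: int
    digests: dict[str, str] = field(default_factory=dict)
    output_paths: dict[str, str] = field(default_factory=dict)
    version: str = VERSION

    def digest(self) -> str:
        payload = json.dumps(
            {"config": self.resolved_config, "digests": self.digests},
            sort_keys=True, default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()


@dataclass
class DiscoveryResult:
    manifest: RunManifest
    network: net_io.Network
    tumor_pert: pd.DataFrame
    normal_pert: pd.DataFrame
    selection: FeatureSelection
    consensus: consensus_mod.ConsensusResult
    assignments: pd.Series
    signatures: SignatureSet
    tumor_expr: pd.DataFrame
    study: simulate_mod.SimulatedStudy | None = None


@dataclass
class ValidationResult:
    manifest: RunManifest
    ntp: pd.DataFrame
    correspondence: CorrespondenceResult
    proportions: pd.DataFrame


def load_config(path: str | Path) -> dict[str, Any]:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _resolve(config: Mapping[str, Any] | None) -> dict[str, Any]:
    resolved = dict(DEFAULT_CONFIG)
    resolved.update(config or {})
    return resolved


def _digest_frame(df: pd.DataFrame | pd.Series) -> str:
    return hashlib.sha256(df.to_csv().encode()).hexdigest()


def compute_perturbation(
    tumor_expr: pd.DataFrame,
    normal_expr: pd.DataFrame,
    network: net_io.Network,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Rank -> delta-rank -> benchmark -> perturbation for both cohorts.

    The network is restricted to genes measured in both cohorts first.  The
    normal cohort's perturbation is computed against the same benchmark as
    the tumors (its own averaged profile).
    """
    if normal_expr.shape[1] == 0:
        raise ValueError("benchmark requires a normal cohort")
    net = net_io.restrict_to_measured(network, tumor_expr)
    net = net_io.restrict_to_measured(net, normal_expr)
    bench = benchmark_from_normals(normal_expr, net)
    tumor_delta = delta_rank(rank_transform(tumor_expr), net)
    normal_delta = delta_rank(rank_transform(normal_expr), net)
    return perturbation(tumor_delta, bench), perturbation(normal_delta, bench), bench


def _load_inputs(config: Mapping[str, Any]):
    if "simulate" in config and config["simulate"] is not None:
        sim_block = dict(config["simulate"])
        sim_block.setdefault("seed", config["seed"])
        if isinstance(sim_block.get("subtype_proportions"), list):
            sim_block["subtype_proportions"] = tuple(sim_block["subtype_proportions"])
        if isinstance(sim_block.get("hazard_per_subtype"), list):
            sim_block["hazard_per_subtype"] = tuple(sim_block["hazard_per_subtype"])
        study = simulate_mod.simulate_study(simulate_mod.SimulationConfig(**sim_block))
        return study.tumor_expr, study.normal_expr, study.network, study
    if "normal_expression" not in config or config["normal_expression"] is None:
        raise ValueError("benchmark requires a normal cohort")
    tumor = net_io.load_expression(config["tumor_expression"])
    normal = net_io.load_expression(config["normal_expression"])
    universe = (
        net_io.load_gene_universe(config["gene_universe"])
        if config.get("gene_universe")
        else None
    )
    network = net_io.load_network(
        config["network"], min_confidence=config["min_confidence"], universe=universe
    )
    return tumor, normal, network, None


def run_discovery(
    config: Mapping[str, Any] | None = None, out_dir: str | Path | None = None
) -> DiscoveryResult:
    """Run the full discovery pipeline from a configuration mapping.

    The config either names ``tumor_expression`` / ``normal_expression`` /
    ``network`` files (plus an optional ``gene_universe``) or carries a
    ``simulate`` block of :class:`~netperturb.simulate.SimulationConfig`
    fields.  Intermediates are written under ``out_dir`` when given.
    """
    cfg = _resolve(config)
    tumor_expr, normal_expr, network, study = _load_inputs(cfg)
    _, n_nodes, n_edges = net_io.degree_summary(network)
    logger.info(
        "background network: %d nodes, %d edges (cohort-dependent)", n_nodes, n_edges
    )

    tumor_pert, normal_pert, bench = compute_perturbation(
        tumor_expr, normal_expr, network
    )
    logger.info(
        "perturbation: %d edges x %d tumors / %d normals",
        tumor_pert.shape[0], tumor_pert.shape[1], normal_pert.shape[1],
    )

    selection = select_features(
        tumor_pert, normal_pert, k_p=cfg["k_p"], k_sd=cfg["k_sd"]
    )
    logger.info(
        "selected %d interactions over %d genes (cohort-dependent)",
        len(selection.selected_edges),
        len({g for e in selection.selected_edges for g in e.split(net_io.EDGE_SEP)}),
    )
    if not selection.selected_edges:
        raise ValueError("feature selection returned no edges")

    features = tumor_pert.loc[selection.selected_edges]
    cons = consensus_mod.consensus_cluster(
        features,
        k_min=cfg["k_min"], k_max=cfg["k_max"], n_reps=cfg["n_reps"],
        subsample_fraction=cfg["subsample_fraction"], seed=cfg["seed"],
        stability_threshold=cfg["stability_threshold"],
    )
    chosen = cfg["k"] if cfg["k"] else cons.chosen_k
    assignments = cons.assignments[chosen].rename("subtype")
    labels = assignments.map(lambda c: f"C{c}")
    logger.info(
        "chose k=%d; per-subtype sizes (cohort-dependent): %s",
        chosen, labels.value_counts().sort_index().to_dict(),
    )

    signatures = derive_signatures(
        tumor_expr, labels, n_per_subtype=cfg["n_per_subtype"]
    )

    manifest = RunManifest(resolved_config=cfg, seed=cfg["seed"])
    manifest.digests = {
        "benchmark": _digest_frame(bench),
        "tumor_perturbation": _digest_frame(tumor_pert),
        "selected_edges": hashlib.sha256(
            "\n".join(selection.selected_edges).encode()
        ).hexdigest(),
        "assignments": _digest_frame(labels),
        "consensus_chosen_k": _digest_frame(cons.consensus[chosen]),
        "signatures": _digest_frame(signatures.to_frame()),
    }
    result = DiscoveryResult(
        manifest=manifest, network=network, tumor_pert=tumor_pert,
        normal_pert=normal_pert, selection=selection, consensus=cons,
        assignments=labels, signatures=signatures, tumor_expr=tumor_expr,
        study=study,
    )
    if out_dir is not None:
        _write_discovery(result, Path(out_dir))
    return result


def _write_discovery(result: DiscoveryResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "tumor_perturbation": out_dir / "tumor_perturbation.tsv",
        "normal_perturbation": out_dir / "normal_perturbation.tsv",
        "assignments": out_dir / "assignments.tsv",
        "signatures": out_dir / "signatures.tsv",
        "manifest": out_dir / "manifest.json",
    }
    result.tumor_pert.to_csv(paths["tumor_perturbation"], sep="\t", index_label="edge")
    result.normal_pert.to_csv(paths["normal_perturbation"], sep="\t", index_label="edge")
    result.assignments.to_csv(paths["assignments"], sep="\t", index_label="sample")
    result.signatures.to_frame().to_csv(paths["signatures"], sep="\t", index=False)
    for k in result.consensus.k_range:
        p = out_dir / f"consensus_k{k}.tsv"
        result.consensus.consensus[k].to_csv(p, sep="\t")
    (out_dir / "areas.json").write_text(json.dumps(
        {
            "areas": result.consensus.areas,
            "delta_areas": result.consensus.delta_areas,
            "chosen_k": result.consensus.chosen_k,
        }, indent=2,
    ))
    result.manifest.output_paths = {k: str(v) for k, v in paths.items()}
    paths["manifest"].write_text(json.dumps(
        {
            "config": result.manifest.resolved_config,
            "seed": result.manifest.seed,
            "digests": result.manifest.digests,
            "outputs": result.manifest.output_paths,
            "version": result.manifest.version,
        }, indent=2, default=str,
    ))


def run_validation(
    discovery: DiscoveryResult,
    validation_expr: pd.DataFrame,
    config: Mapping[str, Any] | None = None,
    seed: int | None = None,
) -> ValidationResult:
    """Classify a validation cohort and test correspondence with discovery.

    NTP re-assigns each validation sample to a discovery subtype; the
    correspondence test then asks whether the validation subtypes match the
    discovery subtypes over the signature-gene union.  Also returns the
    per-cohort subtype proportion table.
    """
    cfg = _resolve(config)
    if seed is not None:
        cfg["seed"] = seed
    ntp_result = ntp_classify(
        validation_expr, discovery.signatures,
        n_resample=cfg["ntp_resample"], fdr_threshold=cfg["ntp_fdr"],
        seed=cfg["seed"],
    )
    corr = subtype_correspondence(
        discovery.tumor_expr, discovery.assignments,
        validation_expr, ntp_result["predicted"],
        genes=discovery.signatures.union,
        n_perm=cfg["correspondence_perm"], seed=cfg["seed"],
        alpha=cfg["correspondence_alpha"],
    )
    proportions = pd.DataFrame({
        "discovery": discovery.assignments.value_counts(normalize=True),
        "validation": ntp_result["predicted"].value_counts(normalize=True),
    }).fillna(0.0).sort_index()

    manifest = RunManifest(resolved_config=cfg, seed=cfg["seed"])
    manifest.digests = {
        "ntp": _digest_frame(ntp_result),
        "correspondence_p": _digest_frame(corr.adjusted_p),
    }
    return ValidationResult(
        manifest=manifest, ntp=ntp_result, correspondence=corr,
        proportions=proportions,
    )


def majority_label_map(labels: pd.Series, reference: pd.Series) -> dict:
    """Map each cluster label to the reference label it mostly overlaps.

    Cluster names produced by consensus clustering are arbitrary; this gives
    the translation needed before comparing assignments to a reference
    labeling sample-by-sample (ARI does not need it).
    """
    reference = reference.loc[labels.index]
    return {
        c: reference[labels == c].mode().iloc[0] for c in sorted(labels.unique())
    }


def adjusted_rand_index(labels_a: pd.Series, labels_b: pd.Series) -> float:
    """Chance-corrected agreement of two partitions of the same samples."""
    if set(labels_a.index) != set(labels_b.index):
        raise ValueError("labelings cover different sample sets")
    aligned = labels_b.loc[labels_a.index]
    return float(adjusted_rand_score(labels_a.to_numpy(), aligned.to_numpy()))


def logrank_test(
    times: pd.Series | np.ndarray,
    events: pd.Series | np.ndarray,
    groups: pd.Series | np.ndarray,
) -> tuple[float, int, float]:
    """k-group log-rank test -> (chi-square statistic, df = k-1, p)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    groups = np.asarray(groups)
    k = len(np.unique(groups))
    if k < 2:
        raise ValueError("log-rank needs at least two groups")
    if not events.any():
        raise ValueError("log-rank needs at least one observed event")
    res = multivariate_logrank_test(times, groups, events)
    return float(res.test_statistic), k - 1, float(res.p_value)


def kaplan_meier(
    times: pd.Series | np.ndarray, events: pd.Series | np.ndarray
) -> pd.DataFrame:
    """Kaplan-Meier survival curve: columns ``time`` and ``survival``.

    The estimate starts at 1, is right-continuous and non-increasing.
    """
    kmf = KaplanMeierFitter()
    kmf.fit(np.asarray(times, dtype=float), np.asarray(events, dtype=bool))
    sf = kmf.survival_function_
    return pd.DataFrame(
        {"time": sf.index.to_numpy(), "survival": sf.iloc[:, 0].to_numpy()}
    )
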