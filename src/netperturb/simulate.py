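"""Synthetic studies with planted subtype structure.

The generator emulates the kind of data the pipeline is built for: a
scale-free interaction network (Barabasi-Albert preferential attachment), a
conservative normal cohort, a higher-variance tumor cohort in which each
subtype carries expression shifts on its own disjoint set of dysregulated
genes, and subtype-dependent censored survival times.  Dysregulated genes are
sampled preferentially from high-degree nodes so that a shift on one gene
perturbs many edges — the property that makes edge perturbation informative.

Expression is on the log2 scale: gene baselines are Uniform(2, 10), noise is
Gaussian, and each dysregulated gene moves by ``shift_magnitude`` with a sign
fixed per gene at generation time.  Survival is exponential with a
subtype-specific hazard and independent exponential censoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd

from .io import Network

__all__ = [
    "SimulationConfig",
    "SimulatedStudy",
    "simulate_network",
    "simulate_cohorts",
    "simulate_survival",
    "simulate_study",
    "simulate_validation_cohort",
]

SUBTYPE_NAMES = ("C1", "C2", "C3", "C4", "C5", "C6", "C7", "C8")


@dataclass(frozen=True)
class SimulationConfig:
    """Study design parameters; the defaults are the package's reference
    conditions (4 subtypes at realistic tumor-cohort proportions, log2-scale
    Gaussian noise, a best-prognosis fourth subtype)."""

    n_genes: int = 1000
    ba_attachment: int = 3
    n_normal: int = 100
    n_tumor: int = 200
    subtype_proportions: tuple[float, ...] = (0.25, 0.28, 0.26, 0.21)
    n_dysregulated_per_subtype: int = 60
    shift_magnitude: float = 3.0
    noise_sd_normal: float = 0.5
    noise_sd_tumor: float = 1.0
    hazard_per_subtype: tuple[float, ...] = (0.10, 0.14, 0.12, 0.05)
    censor_rate: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.subtype_proportions) - 1.0) > 1e-9:
            raise ValueError("subtype proportions must sum to 1")
        if self.noise_sd_normal <= 0 or self.noise_sd_tumor <= 0:
            raise ValueError("noise standard deviations must be positive")
        if self.noise_sd_tumor < self.noise_sd_normal:
            raise ValueError("tumor noise sd must be >= normal noise sd")
        if len(self.hazard_per_subtype) != len(self.subtype_proportions):
            raise ValueError("one hazard per subtype required")


@dataclass
class SimulatedStudy:
    """A generated study: network, cohorts, planted labels, design, survival."""

    config: SimulationConfig
    network: Network
    normal_expr: pd.DataFrame
    tumor_expr: pd.DataFrame
    true_labels: pd.Series
    dysregulated_sets: dict[str, set[str]]
    survival: pd.DataFrame
    baselines: pd.Series = field(repr=False, default=None)
    signs: pd.Series = field(repr=False, default=None)


def _gene_name(i: int, width: int) -> str:
    return f"G{i:0{width}d}"  # zero-padded so lexicographic = numeric order


def simulate_network(n_genes: int, ba_attachment: int, seed: int) -> Network:
    """Scale-free background network by preferential attachment.

    Growth starts from a complete graph on ``ba_attachment`` nodes, so the
    edge count is exactly m*(n-m) + C(m,2) — a deterministic function of the
    parameters.  All confidences are 1.0; the graph is connected.
    """
    if not (1 <= ba_attachment < n_genes):
        raise ValueError("need n_genes > ba_attachment >= 1")
    g = nx.barabasi_albert_graph(
        n_genes, ba_attachment, seed=seed,
        initial_graph=nx.complete_graph(ba_attachment),
    )
    width = len(str(n_genes - 1))
    rows = []
    for u, v in sorted(tuple(sorted(e)) for e in g.edges()):
        rows.append((_gene_name(u, width), _gene_name(v, width), 1.0))
    return Network(pd.DataFrame(rows, columns=["gene_a", "gene_b", "confidence"]))


def _draw_design(
    config: SimulationConfig, network: Network, rng: np.random.Generator
) -> tuple[pd.Index, pd.Series, pd.Series, dict[str, set[str]]]:
    """Frozen study design: gene order, baselines, shift signs, dysregulated sets."""
    width = len(str(config.n_genes - 1))
    genes = pd.Index([_gene_name(i, width) for i in range(config.n_genes)], name="gene")
    baselines = pd.Series(rng.uniform(2.0, 10.0, size=config.n_genes), index=genes)
    signs = pd.Series(rng.choice([-1.0, 1.0], size=config.n_genes), index=genes)

    n_subtypes = len(config.subtype_proportions)
    total = n_subtypes * config.n_dysregulated_per_subtype
    if total > config.n_genes:
        raise ValueError("more dysregulated genes requested than genes exist")
    degree = pd.Series(0.0, index=genes)
    counts = pd.concat([network.edges["gene_a"], network.edges["gene_b"]]).value_counts()
    degree.loc[counts.index] = counts.astype(float)
    prob = degree / degree.sum()  # hub bias: P(pick) proportional to degree
    chosen = rng.choice(config.n_genes, size=total, replace=False, p=prob.to_numpy())
    dysregulated = {
        SUBTYPE_NAMES[t]: set(
            genes[chosen[t * config.n_dysregulated_per_subtype:
                         (t + 1) * config.n_dysregulated_per_subtype]]
        )
        for t in range(n_subtypes)
    }
    return genes, baselines, signs, dysregulated


def _sample_tumors(
    config: SimulationConfig,
    genes: pd.Index,
    baselines: pd.Series,
    signs: pd.Series,
    dysregulated: dict[str, set[str]],
    n_tumor: int,
    rng: np.random.Generator,
    prefix: str,
) -> tuple[pd.DataFrame, pd.Series]:
    n_subtypes = len(config.subtype_proportions)
    label_idx = rng.choice(n_subtypes, size=n_tumor, p=config.subtype_proportions)
    sample_ids = [f"{prefix}{i:03d}" for i in range(n_tumor)]
    labels = pd.Series(
        [SUBTYPE_NAMES[t] for t in label_idx], index=sample_ids, name="subtype"
    )
    shift = np.zeros((len(genes), n_subtypes))
    for t in range(n_subtypes):
        mask = genes.isin(dysregulated[SUBTYPE_NAMES[t]])
        shift[mask, t] = config.shift_magnitude * signs.to_numpy()[mask]
    values = (
        baselines.to_numpy()[:, None]
        + shift[:, label_idx]
        + rng.normal(0.0, config.noise_sd_tumor, size=(len(genes), n_tumor))
    )
    return pd.DataFrame(values, index=genes, columns=sample_ids), labels


def simulate_cohorts(config: SimulationConfig, network: Network) -> SimulatedStudy:
    """Generate normal and tumor cohorts with planted subtype structure.

    Normals are baseline plus i.i.d. Gaussian noise; a tumor of subtype t
    additionally shifts its subtype's dysregulated genes.  Labels are drawn
    i.i.d. from the configured proportions.  Survival is left empty; use
    :func:`simulate_survival` or :func:`simulate_study`.
    """
    rng = np.random.default_rng(config.seed)
    genes, baselines, signs, dysregulated = _draw_design(config, network, rng)

    normal_ids = [f"N{i:03d}" for i in range(config.n_normal)]
    normal = pd.DataFrame(
        baselines.to_numpy()[:, None]
        + rng.normal(0.0, config.noise_sd_normal, size=(config.n_genes, config.n_normal)),
        index=genes, columns=normal_ids,
    )
    tumor, labels = _sample_tumors(
        config, genes, baselines, signs, dysregulated, config.n_tumor, rng, "T"
    )
    return SimulatedStudy(
        config=config, network=network, normal_expr=normal, tumor_expr=tumor,
        true_labels=labels, dysregulated_sets=dysregulated,
        survival=pd.DataFrame(columns=["time", "event"]),
        baselines=baselines, signs=signs,
    )


def simulate_survival(
    labels: pd.Series,
    hazard_per_subtype: dict[str, float] | tuple[float, ...],
    censor_rate: float,
    seed: int,
) -> pd.DataFrame:
    """Exponential event times with independent exponential censoring.

    Returns a DataFrame (index = samples) with ``time`` = min(event, censor)
    and boolean ``event`` = the event came first.  ``censor_rate`` of 0 means
    no censoring.
    """
    if not isinstance(hazard_per_subtype, dict):
        hazard_per_subtype = {
            SUBTYPE_NAMES[i]: h for i, h in enumerate(hazard_per_subtype)
        }
    unknown = set(labels.unique()) - set(hazard_per_subtype)
    if unknown:
        raise ValueError(f"no hazard configured for subtype {sorted(unknown)[0]!r}")
    if any(h <= 0 for h in hazard_per_subtype.values()):
        raise ValueError("hazards must be positive")
    rng = np.random.default_rng(seed)
    hazards = labels.map(hazard_per_subtype).to_numpy(dtype=float)
    event_time = rng.exponential(1.0 / hazards)
    if censor_rate > 0:
        censor_time = rng.exponential(1.0 / censor_rate, size=len(labels))
    else:
        censor_time = np.full(len(labels), np.inf)
    time = np.minimum(event_time, censor_time)
    event = event_time <= censor_time
    return pd.DataFrame({"time": time, "event": event}, index=labels.index)


def simulate_study(config: SimulationConfig | None = None) -> SimulatedStudy:
    """Full study: network, cohorts and survival from one config/seed."""
    config = config or SimulationConfig()
    network = simulate_network(config.n_genes, config.ba_attachment, config.seed)
    study = simulate_cohorts(config, network)
    study.survival = simulate_survival(
        study.true_labels, config.hazard_per_subtype, config.censor_rate,
        seed=config.seed + 1,
    )
    return study


def simulate_validation_cohort(
    study: SimulatedStudy, n_tumor: int, seed: int
) -> tuple[pd.DataFrame, pd.Series]:
    """Draw a new tumor cohort from the SAME planted design as ``study``.

    The network, baselines, dysregulated sets and shift signs are reused so
    the new cohort carries the same subtypes; only the samples (labels and
    noise) are new.  Returns (expression, labels) with a ``V`` sample prefix.
    """
    rng = np.random.default_rng(seed)
    return _sample_tumors(
        study.config, study.tumor_expr.index, study.baselines, study.signs,
        study.dysregulated_sets, n_tumor, rng, "V",
    )
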