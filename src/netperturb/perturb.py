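"""The single-sample interaction-perturbation statistic.

Given a genes x samples expression matrix and a background interaction
network, each sample's expression profile is reduced to within-sample ranks
(R), each network edge (A, B) to the rank difference delta = R_A - R_B, and
each sample's delta vector is contrasted against the delta vector of the
averaged normal cohort (the benchmark) to give the perturbation
Delta_{E,S} = delta_{E,S} - benchmark_E.  Because the statistic is built on
within-sample ranks it is invariant to any monotone transform of a single
profile, which makes it comparable across samples and platforms.

All matrices are pandas DataFrames: ranks and expression are indexed by gene,
delta/perturbation matrices by canonical edge id ``"A|B"``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io import EDGE_SEP, Network, validate_expression

__all__ = [
    "rank_transform",
    "delta_rank",
    "benchmark_from_normals",
    "perturbation",
    "perturbation_magnitude",
]


def rank_transform(expr: pd.DataFrame) -> pd.DataFrame:
    """Rank each gene within each sample (ascending, ties averaged).

    The lowest-expressed gene gets rank 1; tied values receive the average of
    the positions they span, so every column sums to G(G+1)/2 exactly.
    """
    validate_expression(expr)
    ranks = rankdata(expr.to_numpy(), method="average", axis=0)
    return pd.DataFrame(ranks, index=expr.index, columns=expr.columns)


def _edge_indices(ranks: pd.DataFrame, net: Network) -> tuple[np.ndarray, np.ndarray]:
    pos = pd.Series(np.arange(len(ranks.index)), index=ranks.index)
    for col in ("gene_a", "gene_b"):
        missing = ~net.edges[col].isin(pos.index)
        if missing.any():
            gene = net.edges.loc[missing, col].iloc[0]
            raise KeyError(
                f"network gene {gene!r} absent from the rank matrix; "
                "apply restrict_to_measured first"
            )
    return pos[net.edges["gene_a"]].to_numpy(), pos[net.edges["gene_b"]].to_numpy()


def delta_rank(ranks: pd.DataFrame, net: Network) -> pd.DataFrame:
    """Edge delta-rank matrix: row (A,B) holds R_A - R_B per sample.

    Rows follow the network's edge order; edge ids are ``"A|B"`` with A
    lexicographically before B.
    """
    ia, ib = _edge_indices(ranks, net)
    values = ranks.to_numpy()[ia] - ranks.to_numpy()[ib]
    return pd.DataFrame(values, index=net.edge_ids, columns=ranks.columns)


def benchmark_from_normals(normals: pd.DataFrame, net: Network) -> pd.Series:
    """Benchmark delta-rank vector from the averaged normal cohort.

    The normal profiles are averaged gene-wise into one pseudo-sample, which
    is then rank-transformed and reduced to edge delta-ranks.  The order of
    operations is mean-then-rank: with a single normal sample the benchmark
    equals that sample's own delta-rank vector.
    """
    validate_expression(normals)
    if normals.shape[1] == 0:
        raise ValueError("benchmark requires at least one normal sample")
    pseudo = normals.mean(axis=1).to_frame(name="normal_mean")
    bench = delta_rank(rank_transform(pseudo), net)["normal_mean"]
    bench.name = "benchmark"
    return bench


def perturbation(tumor_delta: pd.DataFrame, benchmark: pd.Series) -> pd.DataFrame:
    """Perturbation matrix Delta = delta - benchmark, element-wise per edge."""
    if len(tumor_delta.index) != len(benchmark.index) or (
        tumor_delta.index != benchmark.index
    ).any():
        raise ValueError("edge ids of delta matrix and benchmark differ or are misordered")
    return tumor_delta.sub(benchmark, axis=0)


def perturbation_magnitude(pert: pd.DataFrame) -> pd.Series:
    """Per-sample mean absolute perturbation over all edges.

    Zero exactly when the sample's delta-rank vector equals the benchmark.
    """
    if pert.shape[0] < 1:
        raise ValueError("perturbation matrix has no edges")
    return pert.abs().mean(axis=0)
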