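"""Clustering-feature selection on the perturbation matrix.

Edges are scored two ways: a two-sided Wilcoxon rank-sum (Mann-Whitney) test
of tumor versus normal perturbation values per edge, and the sample standard
deviation of the perturbation across tumors.  The top K_p edges by smallest p
and the top K_sd edges by largest SD are intersected; the intersection is the
feature set handed to consensus clustering.  No multiplicity adjustment is
applied — selection is by raw-p ranking, not an FDR cut.

The rank-sum test is exact (full enumeration of all C(n1+n2, n1) group
assignments, ties handled through averaged ranks) when both groups have at
most 8 samples, and otherwise uses the tie-corrected normal approximation
with a continuity correction.  Because the perturbation differs from the raw
delta-rank by a per-edge constant, testing either matrix gives identical
p-values.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

__all__ = ["FeatureSelection", "ranksum_pvalues", "select_features"]

_EXACT_MAX = 8  # enumerate all splits when both groups are this small


def _ranksum_stats(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided rank-sum p and standardized statistic, row-wise.

    ``x`` (E x n1) and ``y`` (E x n2) hold the two groups' values per edge.
    Returns (p, z) where z = (W - E[W]) / sd[W] without continuity correction
    (used only for deterministic tie-breaking) and p is exact for small
    groups, otherwise normal-approximate with tie correction and continuity
    correction.
    """
    n1, n2 = x.shape[1], y.shape[1]
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups need at least one sample")
    n = n1 + n2
    pooled = np.concatenate([x, y], axis=1)
    ranks = rankdata(pooled, method="average", axis=1)
    w = ranks[:, :n1].sum(axis=1)
    mu = n1 * (n + 1) / 2.0
    # permutation variance of W from the realized (tie-averaged) ranks
    mean_rank = (n + 1) / 2.0
    ss = (ranks**2).sum(axis=1) - n * mean_rank**2
    var = n1 * n2 * ss / (n * (n - 1))
    sd = np.sqrt(var)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 0, (w - mu) / np.where(sd > 0, sd, 1.0), 0.0)

    if n1 <= _EXACT_MAX and n2 <= _EXACT_MAX:
        combos = np.array(list(combinations(range(n), n1)))
        w_null = ranks[:, combos].sum(axis=2)  # E x C
        dev = np.abs(w - mu)
        p = (np.abs(w_null - mu) >= dev[:, None] - 1e-12).mean(axis=1)
    else:
        z_cc = np.maximum(np.abs(w - mu) - 0.5, 0.0) / np.where(sd > 0, sd, 1.0)
        p = np.where(sd > 0, 2.0 * norm.sf(z_cc), 1.0)
        p = np.minimum(p, 1.0)
    return p, z


def ranksum_pvalues(tumor_pert: pd.DataFrame, normal_pert: pd.DataFrame) -> pd.Series:
    """Two-sided rank-sum p per edge, tumor vs normal perturbation values."""
    if len(tumor_pert.index) != len(normal_pert.index) or (
        tumor_pert.index != normal_pert.index
    ).any():
        raise ValueError("tumor and normal matrices must share the same edge order")
    p, _ = _ranksum_stats(tumor_pert.to_numpy(), normal_pert.to_numpy())
    return pd.Series(p, index=tumor_pert.index, name="pvalue")


@dataclass(frozen=True)
class FeatureSelection:
    """Result of the dual top-K edge selection.

    ``selected_edges`` is the intersection of the two top lists, ordered by
    edge id; ``pvalues``/``sds`` cover every edge.
    """

    pvalues: pd.Series
    sds: pd.Series
    zstats: pd.Series
    selected_edges: list[str]
    k_p: int
    k_sd: int


def select_features(
    tumor_pert: pd.DataFrame,
    normal_pert: pd.DataFrame,
    k_p: int = 4000,
    k_sd: int = 4000,
) -> FeatureSelection:
    """Intersect the top-``k_p`` discriminating and top-``k_sd`` variable edges.

    The discrimination list ranks edges by ascending rank-sum p (ties broken
    by larger absolute standardized statistic, then edge id); the
    heterogeneity list ranks by descending tumor SD (denominator n-1, ties by
    edge id).  Deterministic given the inputs; both K default to 4000, the
    convention for genome-scale networks, and should be scaled down for
    smaller ones.
    """
    if k_p < 0 or k_sd < 0:
        raise ValueError("k_p and k_sd must be non-negative")
    p, z = _ranksum_stats(tumor_pert.to_numpy(), normal_pert.to_numpy())
    edges = tumor_pert.index
    pvalues = pd.Series(p, index=edges, name="pvalue")
    zstats = pd.Series(z, index=edges, name="zstat")
    sds = pd.Series(
        tumor_pert.to_numpy().std(axis=1, ddof=1), index=edges, name="sd"
    )

    by_p = (
        pd.DataFrame({"p": pvalues, "negabsz": -zstats.abs(), "edge": edges})
        .sort_values(["p", "negabsz", "edge"], kind="mergesort")
        .head(k_p)["edge"]
    )
    by_sd = (
        pd.DataFrame({"negsd": -sds, "edge": edges})
        .sort_values(["negsd", "edge"], kind="mergesort")
        .head(k_sd)["edge"]
    )
    selected = sorted(set(by_p) & set(by_sd))
    return FeatureSelection(
        pvalues=pvalues, sds=sds, zstats=zstats,
        selected_edges=selected, k_p=k_p, k_sd=k_sd,
    )
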