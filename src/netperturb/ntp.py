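"""Subtype signature genes and nearest-template prediction (NTP).

Signatures are derived per subtype by one-vs-rest rank-sum differential
expression: candidate markers have Benjamini-Hochberg adjusted p < 0.05 and a
positive effect size (mean log2 expression in the subtype minus the rest);
each gene may mark only the subtype where its effect is largest, and the top
``n_per_subtype`` by effect are kept.

NTP classifies each sample of a new cohort independently: genes are
standardized across the cohort, each subtype's template is a binary indicator
vector over the signature-gene union, and the sample is assigned to the
template with the smallest cosine distance.  Confidence comes from a
gene-resampling null — templates rebuilt from random gene sets of the same
size — with an add-one permutation p per sample and BH adjustment across
samples; samples pass the confidence gate at FDR <= 0.2 by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .featsel import _ranksum_stats

logger = logging.getLogger(__name__)

__all__ = ["SignatureSet", "derive_signatures", "ntp_classify"]


@dataclass(frozen=True)
class SignatureSet:
    """Per-subtype marker gene lists with derivation statistics.

    ``markers`` maps subtype -> ordered marker list (largest effect first);
    lists are pairwise disjoint and every marker is upregulated in its
    subtype.  ``stats`` holds gene, subtype, effect and adjusted p for every
    retained marker.
    """

    markers: dict[str, list[str]]
    n_per_subtype: int
    stats: pd.DataFrame

    @property
    def union(self) -> list[str]:
        genes: list[str] = []
        for subtype in sorted(self.markers):
            genes.extend(self.markers[subtype])
        return genes

    def to_frame(self) -> pd.DataFrame:
        rows = [(g, s) for s in sorted(self.markers) for g in self.markers[s]]
        return pd.DataFrame(rows, columns=["gene", "subtype"])

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "SignatureSet":
        markers = {
            str(s): list(sub["gene"]) for s, sub in frame.groupby("subtype", sort=True)
        }
        n = max((len(v) for v in markers.values()), default=0)
        return cls(markers=markers, n_per_subtype=n, stats=pd.DataFrame())


def derive_signatures(
    expr: pd.DataFrame,
    labels: pd.Series,
    n_per_subtype: int = 300,
    alpha: float = 0.05,
) -> SignatureSet:
    """Derive upregulated marker genes per subtype by one-vs-rest rank-sum tests."""
    labels = labels.loc[expr.columns]
    subtypes = sorted(labels.unique())
    if len(subtypes) < 2:
        raise ValueError("need at least two subtypes")
    counts = labels.value_counts()
    small = counts[counts < 2]
    if not small.empty:
        raise ValueError(f"subtype {small.index[0]!r} has fewer than 2 samples")

    values = expr.to_numpy()
    records: dict[str, pd.DataFrame] = {}
    for subtype in subtypes:
        in_mask = (labels == subtype).to_numpy()
        p, _ = _ranksum_stats(values[:, in_mask], values[:, ~in_mask])
        adj = multipletests(p, method="fdr_bh")[1]
        effect = values[:, in_mask].mean(axis=1) - values[:, ~in_mask].mean(axis=1)
        records[subtype] = pd.DataFrame(
            {"effect": effect, "adj_p": adj}, index=expr.index
        )

    effects = pd.DataFrame({s: records[s]["effect"] for s in subtypes})
    best_subtype = effects.idxmax(axis=1)  # a gene marks only its strongest subtype

    markers: dict[str, list[str]] = {}
    stat_rows = []
    for subtype in subtypes:
        rec = records[subtype]
        eligible = rec[
            (rec["adj_p"] < alpha) & (rec["effect"] > 0) & (best_subtype == subtype)
        ]
        top = eligible.sort_values(
            ["effect"], ascending=False, kind="mergesort"
        ).head(n_per_subtype)
        markers[str(subtype)] = list(top.index)
        for gene, row in top.iterrows():
            stat_rows.append((gene, str(subtype), row["effect"], row["adj_p"]))
    stats = pd.DataFrame(stat_rows, columns=["gene", "subtype", "effect", "adj_p"])
    return SignatureSet(markers=markers, n_per_subtype=n_per_subtype, stats=stats)


def _standardize(expr: pd.DataFrame, ref_mean: pd.Series | None, ref_sd: pd.Series | None) -> pd.DataFrame:
    if expr.shape[1] == 1:
        if ref_mean is None or ref_sd is None:
            raise ValueError(
                "single-sample classification needs reference means and sds "
                "for gene standardization"
            )
        mean, sd = ref_mean.loc[expr.index], ref_sd.loc[expr.index]
    elif ref_mean is not None and ref_sd is not None:
        mean, sd = ref_mean.loc[expr.index], ref_sd.loc[expr.index]
    else:
        mean, sd = expr.mean(axis=1), expr.std(axis=1, ddof=0)
    sd = sd.where(sd > 0, 1.0)  # constant genes carry no signal; avoid 0/0
    return expr.sub(mean, axis=0).div(sd, axis=0)


def _cosine_to_indicator(x: np.ndarray, member: np.ndarray) -> np.ndarray:
    """Cosine distance of columns of ``x`` (genes x samples) to the indicator
    vector of ``member`` (boolean over genes)."""
    norm_x = np.linalg.norm(x, axis=0)
    norm_t = np.sqrt(member.sum())
    num = x[member].sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        cos = np.where((norm_x > 0) & (norm_t > 0), num / (norm_x * norm_t), 0.0)
    return 1.0 - cos


def ntp_classify(
    expr: pd.DataFrame,
    signatures: SignatureSet,
    n_resample: int = 1000,
    fdr_threshold: float = 0.2,
    seed: int = 0,
    ref_mean: pd.Series | None = None,
    ref_sd: pd.Series | None = None,
) -> pd.DataFrame:
    """Assign each sample to its nearest subtype template with an FDR gate.

    Returns a DataFrame indexed by sample with columns ``predicted``,
    ``dist_<subtype>`` for every template, ``pvalue``, ``fdr`` and
    ``confident``.  Nominal p is the add-one fraction of random-template
    distances at most as small as the observed one, so it lies in
    [1/(n_resample+1), 1]; confidence is FDR <= ``fdr_threshold`` after BH
    adjustment across samples.  Raises if fewer than half of the signature
    genes are measured.
    """
    subtypes = sorted(signatures.markers)
    union = signatures.union
    present = [g for g in union if g in expr.index]
    if len(present) < 0.5 * len(union):
        raise ValueError(
            f"only {len(present)}/{len(union)} signature genes measured; "
            "need at least 50% coverage"
        )
    if len(present) < len(union):
        logger.warning(
            "%d signature genes missing from the cohort; dropped",
            len(union) - len(present),
        )

    z = _standardize(expr, ref_mean, ref_sd)
    present_set = set(present)
    kept = {s: [g for g in signatures.markers[s] if g in present_set] for s in subtypes}
    union_kept = [g for s in subtypes for g in kept[s]]
    zu = z.loc[union_kept].to_numpy()

    dists = pd.DataFrame(index=expr.columns, dtype=float)
    offset = 0
    sizes: dict[str, tuple[int, int]] = {}
    for s in subtypes:
        m = len(kept[s])
        member = np.zeros(len(union_kept), dtype=bool)
        member[offset : offset + m] = True
        sizes[s] = (offset, m)
        dists[f"dist_{s}"] = _cosine_to_indicator(zu, member)
        offset += m

    dist_mat = dists.to_numpy()
    pred_idx = dist_mat.argmin(axis=1)
    predicted = np.array(subtypes, dtype=object)[pred_idx]
    observed = dist_mat[np.arange(len(expr.columns)), pred_idx]

    # gene-resampling null: random gene sets of the same sizes from all
    # measured genes, template = indicator of the predicted subtype's block
    rng = np.random.default_rng(seed)
    z_all = z.to_numpy()
    n_union = len(union_kept)
    null_by_subtype = {}
    for s in subtypes:
        _, m = sizes[s]
        null = np.empty((n_resample, len(expr.columns)))
        for r in range(n_resample):
            pick = rng.choice(z_all.shape[0], size=n_union, replace=False)
            member = np.zeros(n_union, dtype=bool)
            member[:m] = True  # random draw order makes the first m a random subset
            null[r] = _cosine_to_indicator(z_all[pick], member)
        null_by_subtype[s] = null

    pvals = np.empty(len(expr.columns))
    for j, s in enumerate(predicted):
        null = null_by_subtype[s][:, j]
        pvals[j] = (1.0 + (null <= observed[j]).sum()) / (n_resample + 1.0)

    fdr = multipletests(pvals, method="fdr_bh")[1]
    result = dists.copy()
    result.insert(0, "predicted", predicted)
    result["pvalue"] = pvals
    result["fdr"] = fdr
    result["confident"] = fdr <= fdr_threshold
    return result
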