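"""Subtype correspondence between two cohorts (subclass-mapping style).

For every pair (subtype i in cohort A, subtype j in cohort B) the statistic
is the Spearman correlation between the two subtype centroids over a shared
gene set, after standardizing each cohort's genes internally (which makes the
statistic invariant to per-gene affine transforms within a cohort).
Significance comes from permuting cohort B's labels: the full statistic
matrix is recomputed for each permutation, nominal p is the add-one
upper-tail fraction per pair, and Benjamini-Hochberg adjustment is applied
across all k_A x k_B pairs.  A pair with adjusted p < 0.05 is reported as a
significant correspondence.

This is a deliberately simplified permutation test standing in for the full
subclass-mapping machinery (which uses mutual enrichment scores); it answers
the same yes/no question — do subtypes found in two cohorts match up?
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

__all__ = ["CorrespondenceResult", "subtype_correspondence"]

MIN_SHARED_GENES = 20


@dataclass(frozen=True)
class CorrespondenceResult:
    """Statistic, nominal-p and adjusted-p matrices over subtype pairs.

    Rows are cohort-A subtypes, columns cohort-B subtypes.  ``significant``
    flags adjusted p below the significance level.
    """

    statistic: pd.DataFrame
    pvalue: pd.DataFrame
    adjusted_p: pd.DataFrame
    significant: pd.DataFrame
    n_permutations: int
    seed: int
    alpha: float


def _standardize_rows(x: np.ndarray) -> np.ndarray:
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=0, keepdims=True)
    sd[sd == 0] = 1.0
    return (x - mean) / sd


def _centroids(x: np.ndarray, label_idx: np.ndarray, k: int) -> np.ndarray:
    """Group means of columns of ``x`` (genes x samples) -> k x genes."""
    out = np.zeros((k, x.shape[0]))
    for g in range(k):
        out[g] = x[:, label_idx == g].mean(axis=1)
    return out


def _rank_rows(x: np.ndarray) -> np.ndarray:
    r = rankdata(x, method="average", axis=1)
    return _standardize_rows(r)


def _spearman_matrix(ca: np.ndarray, cb: np.ndarray) -> np.ndarray:
    """Spearman correlation of every cohort-A centroid with every cohort-B
    centroid (rows = genes dimension already collapsed to k x genes)."""
    ra, rb = _rank_rows(ca), _rank_rows(cb)
    return ra @ rb.T / ca.shape[1]


def subtype_correspondence(
    expr_a: pd.DataFrame,
    labels_a: pd.Series,
    expr_b: pd.DataFrame,
    labels_b: pd.Series,
    genes: list[str] | None = None,
    n_perm: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> CorrespondenceResult:
    """Permutation test of subtype correspondence between two cohorts.

    ``genes`` (typically the signature-gene union) is intersected with both
    expression indexes; at least 20 shared genes are required.  Cohort B's
    labels are permuted ``n_perm`` times while cohort A stays fixed.
    """
    shared = pd.Index(genes) if genes is not None else expr_a.index
    shared = shared.intersection(expr_a.index).intersection(expr_b.index)
    if len(shared) < MIN_SHARED_GENES:
        raise ValueError(
            f"only {len(shared)} shared genes; need at least {MIN_SHARED_GENES}"
        )
    labels_a = labels_a.loc[expr_a.columns]
    labels_b = labels_b.loc[expr_b.columns]
    for name, lab in (("A", labels_a), ("B", labels_b)):
        counts = lab.value_counts()
        if (counts < 2).any():
            raise ValueError(
                f"cohort {name} subtype {counts[counts < 2].index[0]!r} has < 2 samples"
            )

    xa = _standardize_rows(expr_a.loc[shared].to_numpy())
    xb = _standardize_rows(expr_b.loc[shared].to_numpy())
    subtypes_a = sorted(labels_a.unique())
    subtypes_b = sorted(labels_b.unique())
    ia = labels_a.map({s: i for i, s in enumerate(subtypes_a)}).to_numpy()
    ib = labels_b.map({s: i for i, s in enumerate(subtypes_b)}).to_numpy()

    ca = _centroids(xa, ia, len(subtypes_a))
    ra = _rank_rows(ca)  # A side is fixed across permutations
    obs = ra @ _rank_rows(_centroids(xb, ib, len(subtypes_b))).T / len(shared)

    rng = np.random.default_rng(seed)
    exceed = np.zeros_like(obs)
    for _ in range(n_perm):
        perm = rng.permutation(ib)
        stat = ra @ _rank_rows(_centroids(xb, perm, len(subtypes_b))).T / len(shared)
        exceed += stat >= obs - 1e-12
    pvals = (1.0 + exceed) / (n_perm + 1.0)

    adj = multipletests(pvals.ravel(), method="fdr_bh")[1].reshape(pvals.shape)
    idx, cols = pd.Index(subtypes_a, name="cohort_a"), pd.Index(subtypes_b, name="cohort_b")
    return CorrespondenceResult(
        statistic=pd.DataFrame(obs, index=idx, columns=cols),
        pvalue=pd.DataFrame(pvals, index=idx, columns=cols),
        adjusted_p=pd.DataFrame(adj, index=idx, columns=cols),
        significant=pd.DataFrame(adj < alpha, index=idx, columns=cols),
        n_permutations=n_perm,
        seed=seed,
        alpha=alpha,
    )
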