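"""Subsampled PAM consensus clustering with CDF/delta-area model selection.

Samples are clustered as points in the selected-edge perturbation space using
unscaled Euclidean distance.  For each of ``n_reps`` repetitions a fraction
of the samples is drawn without replacement and partitioned around medoids
(PAM: BUILD initialization, then best-improvement SWAP passes).  The
consensus matrix entry for a sample pair is the fraction of co-drawn
repetitions in which they co-cluster.  The final assignment at each k cuts an
average-linkage tree on 1 - consensus.  The number of clusters is chosen from
the relative increase of the area under the consensus CDF ("delta area"): the
largest k whose relative area gain still meets a stability threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import ceil

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cdist, squareform

logger = logging.getLogger(__name__)

__all__ = ["ConsensusResult", "pam", "consensus_cluster", "choose_k", "consensus_areas"]

_CDF_GRID = np.round(np.arange(0.0, 1.01, 0.01), 2)


def _pam_build(dist: np.ndarray, k: int) -> list[int]:
    n = dist.shape[0]
    medoids = [int(np.argmin(dist.sum(axis=0)))]
    dnear = dist[:, medoids[0]].copy()
    while len(medoids) < k:
        # gain of adding candidate j: sum over points of max(dnear - d(., j), 0)
        gains = np.maximum(dnear[:, None] - dist, 0.0).sum(axis=0)
        gains[medoids] = -np.inf
        j = int(np.argmax(gains))
        medoids.append(j)
        dnear = np.minimum(dnear, dist[:, j])
    return medoids


def _pam_swap(dist: np.ndarray, medoids: list[int], max_iter: int = 300) -> list[int]:
    n = dist.shape[0]
    medoids = sorted(medoids)
    for _ in range(max_iter):
        med = np.asarray(medoids)
        dmed = dist[:, med]  # n x k
        order = np.argsort(dmed, axis=1, kind="stable")
        near = order[:, 0]  # index into med
        dnear = dmed[np.arange(n), near]
        dsecond = dmed[np.arange(n), order[:, 1]] if len(med) > 1 else np.full(n, np.inf)

        # delta cost of swapping medoid i out and candidate j in, all pairs:
        #   points not owned by i: min(d(., j) - dnear, 0)
        #   points owned by i:     min(d(., j), dsecond) - dnear
        a = np.minimum(dist - dnear[:, None], 0.0)  # n x n (cols = candidates)
        b = np.minimum(dist, dsecond[:, None]) - dnear[:, None]
        total_a = a.sum(axis=0)
        delta = np.empty((len(med), n))
        for idx in range(len(med)):
            owned = near == idx
            delta[idx] = total_a - a[owned].sum(axis=0) + b[owned].sum(axis=0)
        delta[:, med] = np.inf  # cannot swap a medoid in
        best_flat = int(np.argmin(delta))
        i, j = divmod(best_flat, n)
        if delta[i, j] < -1e-10:
            medoids[i] = j
            medoids = sorted(medoids)
        else:
            break
    return medoids


def _pam_distance(dist: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """PAM on a precomputed distance matrix -> (labels 0..k-1, medoid indices)."""
    n = dist.shape[0]
    if k < 1 or k > n:
        raise ValueError(f"k={k} must be between 1 and the number of points ({n})")
    if k == n:
        medoids = list(range(n))
    else:
        medoids = _pam_swap(dist, _pam_build(dist, k))
    med = np.asarray(sorted(medoids))
    labels = np.argmin(dist[:, med], axis=1)
    return labels, med


def pam(points: np.ndarray, k: int, seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Partition ``points`` (n x features) around ``k`` medoids (Euclidean).

    BUILD initialization followed by best-improvement SWAP passes until no
    swap lowers the total within-cluster distance to medoids.  Exact cost
    ties are broken by the lowest candidate index, so the result is
    deterministic; ``seed`` is accepted for interface symmetry with the
    stochastic stages but does not influence the outcome.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim == 1:
        points = points[:, None]
    dist = cdist(points, points)
    return _pam_distance(dist, k)


@dataclass
class ConsensusResult:
    """Per-k consensus matrices, assignments and CDF-area diagnostics."""

    k_range: list[int]
    consensus: dict[int, pd.DataFrame]
    assignments: dict[int, pd.Series]
    areas: dict[int, float]
    delta_areas: dict[int, float]
    chosen_k: int
    seed: int
    n_reps: int
    subsample_fraction: float
    stability_threshold: float = 0.1
    never_codrawn_pairs: int = field(default=0)


def _cdf_area(consensus: np.ndarray) -> float:
    """Trapezoid area under the empirical CDF of upper-triangle consensus values."""
    vals = consensus[np.triu_indices_from(consensus, k=1)]
    cdf = np.searchsorted(np.sort(vals), _CDF_GRID, side="right") / vals.size
    return float(np.trapezoid(cdf, _CDF_GRID))


def consensus_areas(consensus_by_k: dict[int, pd.DataFrame]) -> tuple[dict[int, float], dict[int, float]]:
    """Areas under the per-k consensus CDFs and their relative increases."""
    ks = sorted(consensus_by_k)
    areas = {k: _cdf_area(consensus_by_k[k].to_numpy()) for k in ks}
    delta: dict[int, float] = {}
    for i, k in enumerate(ks):
        if i == 0:
            delta[k] = areas[k]
        else:
            prev = areas[ks[i - 1]]
            delta[k] = (areas[k] - prev) / prev if prev > 0 else 0.0
    return areas, delta


def choose_k(result: ConsensusResult, stability_threshold: float = 0.1) -> int:
    """Largest k whose relative CDF-area increase meets the threshold.

    Automates the usual visual delta-area inspection: once extra clusters stop
    adding consensus-CDF area, larger k is no longer supported.
    """
    candidates = [k for k in result.k_range if result.delta_areas[k] >= stability_threshold]
    return max(candidates) if candidates else min(result.k_range)


def consensus_cluster(
    features: pd.DataFrame,
    k_min: int = 2,
    k_max: int = 9,
    n_reps: int = 1000,
    subsample_fraction: float = 0.8,
    seed: int = 0,
    stability_threshold: float = 0.1,
) -> ConsensusResult:
    """Consensus clustering of samples over a selected-edge feature matrix.

    ``features`` is edges x samples; samples are the points.  Each repetition
    draws ``ceil(fraction * S)`` samples without replacement and runs PAM for
    every k in ``[k_min, k_max]`` on the same draw.  Consensus for a pair is
    co-cluster count / co-draw count (pairs never drawn together score 0 and
    are counted in ``never_codrawn_pairs``).  Final labels at each k come from
    average-linkage agglomeration on 1 - consensus.  Fully deterministic
    given ``seed``.
    """
    if not (0.0 < subsample_fraction <= 1.0):
        raise ValueError("subsample_fraction must be in (0, 1]")
    samples = features.columns
    s = len(samples)
    if s < k_max + 2:
        raise ValueError(f"need at least k_max + 2 = {k_max + 2} samples, got {s}")
    points = features.to_numpy().T
    n_draw = ceil(subsample_fraction * s)
    ks = list(range(k_min, k_max + 1))

    rng = np.random.default_rng(seed)
    codraw = np.zeros((s, s))
    cocluster = {k: np.zeros((s, s)) for k in ks}
    for _ in range(n_reps):
        idx = np.sort(rng.choice(s, size=n_draw, replace=False))
        dist = cdist(points[idx], points[idx])
        codraw[np.ix_(idx, idx)] += 1.0
        for k in ks:
            labels, _ = _pam_distance(dist, k)
            cocluster[k][np.ix_(idx, idx)] += labels[:, None] == labels[None, :]

    never = int((codraw[np.triu_indices(s, k=1)] == 0).sum())
    if never:
        logger.warning(
            "%d sample pairs were never co-drawn across %d repetitions; "
            "their consensus is reported as 0", never, n_reps,
        )
    denom = np.where(codraw > 0, codraw, 1.0)

    consensus: dict[int, pd.DataFrame] = {}
    assignments: dict[int, pd.Series] = {}
    for k in ks:
        c = cocluster[k] / denom
        c = (c + c.T) / 2.0
        np.fill_diagonal(c, 1.0)
        consensus[k] = pd.DataFrame(c, index=samples, columns=samples)
        z = linkage(squareform(1.0 - c, checks=False), method="average")
        labels = fcluster(z, t=k, criterion="maxclust")
        # relabel by order of first appearance so labels are stable 1..k
        relabel: dict[int, int] = {}
        stable = np.empty_like(labels)
        for i, lab in enumerate(labels):
            if lab not in relabel:
                relabel[lab] = len(relabel) + 1
            stable[i] = relabel[lab]
        assignments[k] = pd.Series(stable, index=samples, name=f"k{k}")

    areas, delta_areas = consensus_areas(consensus)
    result = ConsensusResult(
        k_range=ks, consensus=consensus, assignments=assignments,
        areas=areas, delta_areas=delta_areas, chosen_k=min(ks),
        seed=seed, n_reps=n_reps, subsample_fraction=subsample_fraction,
        stability_threshold=stability_threshold, never_codrawn_pairs=never,
    )
    result.chosen_k = choose_k(result, stability_threshold)
    return result
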