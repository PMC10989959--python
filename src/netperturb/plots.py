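"""Plain diagnostic plots: consensus heatmap, CDF/delta-area, KM curves."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .consensus import ConsensusResult
from .pipeline import kaplan_meier

__all__ = ["plot_consensus_heatmap", "plot_cdf_delta_area", "plot_km_curves"]


def plot_consensus_heatmap(result: ConsensusResult, k: int, path: str) -> None:
    """Consensus matrix at ``k`` with samples ordered by assigned cluster."""
    order = result.assignments[k].sort_values(kind="mergesort").index
    mat = result.consensus[k].loc[order, order]
    fig, ax = plt.subplots(figsize=(5, 4.5))
    im = ax.imshow(mat.to_numpy(), vmin=0, vmax=1, cmap="Blues")
    ax.set_title(f"Consensus matrix, k={k}")
    ax.set_xticks([]), ax.set_yticks([])
    fig.colorbar(im, ax=ax, label="consensus")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def plot_cdf_delta_area(result: ConsensusResult, path: str) -> None:
    """Per-k consensus CDFs (left) and relative area increases (right)."""
    grid = np.arange(0.0, 1.01, 0.01)
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 3.5))
    for k in result.k_range:
        vals = result.consensus[k].to_numpy()
        vals = vals[np.triu_indices_from(vals, k=1)]
        cdf = np.searchsorted(np.sort(vals), grid, side="right") / vals.size
        ax1.plot(grid, cdf, label=f"k={k}")
    ax1.set_xlabel("consensus value"), ax1.set_ylabel("CDF"), ax1.legend(fontsize=7)
    ks = result.k_range
    ax2.plot(ks, [result.delta_areas[k] for k in ks], "o-")
    ax2.axhline(result.stability_threshold, ls="--", c="grey")
    ax2.set_xlabel("k"), ax2.set_ylabel("relative area increase")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def plot_km_curves(
    times: pd.Series, events: pd.Series, groups: pd.Series, path: str
) -> None:
    """Kaplan-Meier survival curve per group."""
    fig, ax = plt.subplots(figsize=(5, 4))
    for g in sorted(pd.Series(groups).unique()):
        mask = np.asarray(groups) == g
        km = kaplan_meier(np.asarray(times)[mask], np.asarray(events)[mask])
        ax.step(km["time"], km["survival"], where="post", label=str(g))
    ax.set_xlabel("time"), ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02), ax.legend()
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
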