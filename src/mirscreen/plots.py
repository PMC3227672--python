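"""Small QC plots: duplicate B-score scatter and E-vs-R hit scatter."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .plates import BScoreGrid
from .scoring import HitTable

__all__ = ["plot_replicate_bscores", "plot_e_vs_r"]


def plot_replicate_bscores(b1: BScoreGrid, b2: BScoreGrid, path: str | Path) -> None:
    """Scatter of duplicate B-scores over shared unmasked wells."""
    sel = b1.mask & b2.mask
    x, y = b1.b[sel], b2.b[sel]
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(x, y, s=12, alpha=0.7, edgecolors="none")
    lim = max(1.0, float(np.nanmax(np.abs(np.concatenate([x, y])))))
    ax.plot([-lim, lim], [-lim, lim], lw=0.8, color="grey", zorder=0)
    ax.set_xlabel("B-score, replicate 1")
    ax.set_ylabel("B-score, replicate 2")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_e_vs_r(hits: HitTable, path: str | Path) -> None:
    """Enrichment vs scaled invasive reads, hits highlighted, S = threshold
    contour drawn."""
    t = hits.table
    fig, ax = plt.subplots(figsize=(4.5, 4))
    ax.scatter(t["R_invasive"], t["E"], s=14,
               c=np.where(t["is_hit"], "crimson", "steelblue"),
               alpha=0.8, edgecolors="none")
    r = np.geomspace(max(t["R_invasive"].min(), 1e-3), max(t["R_invasive"].max(), 1), 200)
    ax.plot(r, hits.threshold / r, lw=0.8, color="grey",
            label=f"E x R = {hits.threshold:g}")
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel("scaled reads in invasive fraction (R)")
    ax.set_ylabel("enrichment (E)")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
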