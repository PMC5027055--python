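"""Figure export: trend-profile grids, enrichment bars, qPCR-vs-array
curves and the DE heat map.  All functions write a file and return its
path; they are deliberately plain matplotlib so the pipeline stays
headless."""
from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix
from .stc import TrendProfile

__all__ = [
    "plot_profile_trends",
    "plot_enrichment_bar",
    "plot_qpcr_curves",
    "plot_heatmap",
]


def plot_profile_trends(
    profiles: Sequence[TrendProfile],
    significance: pd.DataFrame,
    out_path: str | Path,
) -> Path:
    """Grid of model profiles; significant ones (adj_p < 0.05) in red."""
    sig = dict(zip(significance["profile_id"], significance["significant"]))
    counts = dict(zip(significance["profile_id"], significance["genes_assigned"]))
    n = len(profiles)
    ncol = 10
    nrow = int(np.ceil(n / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(2 * ncol, 1.6 * nrow), squeeze=False)
    for ax in axes.ravel():
        ax.axis("off")
    for p in profiles:
        ax = axes[p.profile_id // ncol][p.profile_id % ncol]
        ax.axis("on")
        color = "red" if sig.get(p.profile_id, False) else "steelblue"
        ax.plot(p.values, color=color, lw=1.5)
        ax.set_title(f"#{p.profile_id} n={counts.get(p.profile_id, 0)}", fontsize=7)
        ax.set_xticks([])
        ax.set_yticks([])
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return Path(out_path)


def plot_enrichment_bar(results: pd.DataFrame, out_path: str | Path, top: int = 10) -> Path:
    """Horizontal -log10(Fisher p) bars for the top terms."""
    sub = results.nsmallest(top, "fisher_p").iloc[::-1]
    fig, ax = plt.subplots(figsize=(6, 0.4 * len(sub) + 1.5))
    ax.barh(sub["term_id"], -np.log10(np.maximum(sub["fisher_p"], 1e-300)), color="seagreen")
    ax.set_xlabel("-log10(Fisher p)")
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return Path(out_path)


def plot_qpcr_curves(
    quant: pd.DataFrame,
    array_fc: Mapping[tuple[str, float], float],
    out_path: str | Path,
) -> Path:
    """Per-gene qPCR fold (red) vs microarray fold (green) over time."""
    genes = sorted(quant["gene_id"].unique())
    ncol = min(4, len(genes))
    nrow = int(np.ceil(len(genes) / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(3 * ncol, 2.4 * nrow), squeeze=False)
    for ax in axes.ravel():
        ax.axis("off")
    for i, gene in enumerate(genes):
        ax = axes[i // ncol][i % ncol]
        ax.axis("on")
        sub = quant[quant["gene_id"] == gene].sort_values("time_day")
        days = sub["time_day"].to_numpy()
        ax.plot(days, sub["fold"], "r-o", ms=3, label="qPCR")
        arr = [2.0 ** array_fc.get((gene, d), 0.0) for d in days]
        ax.plot(days, arr, "g-s", ms=3, label="array")
        ax.set_title(gene, fontsize=8)
        if i == 0:
            ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return Path(out_path)


def plot_heatmap(
    m: ExpressionMatrix, gene_order: Sequence[str], out_path: str | Path
) -> Path:
    """Row-ordered heat map of per-time means, row-centered (red high,
    green low, black mean)."""
    tm = m.time_means(list(gene_order))
    z = tm.to_numpy(float)
    z = z - z.mean(axis=1, keepdims=True)
    fig, ax = plt.subplots(figsize=(4, max(3, 0.02 * len(gene_order) + 2)))
    vmax = np.abs(z).max() or 1.0
    ax.imshow(z, aspect="auto", cmap="RdYlGn_r", vmin=-vmax, vmax=vmax, interpolation="nearest")
    ax.set_xticks(range(tm.shape[1]))
    ax.set_xticklabels([f"d{c:g}" for c in tm.columns], fontsize=7)
    ax.set_yticks([])
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return Path(out_path)
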