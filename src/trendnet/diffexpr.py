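"""Differential expression against day 0, union sets, heat-map ordering.

Fold change is the difference of group means on the log2 scale; per-gene
two-sample t p-values (day-0 replicates vs the tested day's replicates)
are BH-adjusted within each time-point comparison.  A gene is called up
when log2FC >= log2(fc_threshold) and q <= fdr_threshold, down when
log2FC <= -log2(fc_threshold) and q <= fdr_threshold (boundaries
inclusive), otherwise unchanged.  Pooled matrices (one column per time
point) have no replicate variance, so only the fold-change rule can
apply; that degraded mode must be requested explicitly.
"""
from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sps
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist
from sklearn.base import BaseEstimator

from .matrix import ExpressionMatrix
from .stats import bh_fdr

__all__ = [
    "log2_fold_change",
    "call_differential",
    "union_set",
    "hierarchical_order",
    "DifferentialExpressionCaller",
]


def log2_fold_change(m: ExpressionMatrix, time_day: float) -> pd.Series:
    """Per-gene mean log2 signal at ``time_day`` minus the day-0 mean."""
    day0_cols = m.columns_at(0)
    cols = m.columns_at(time_day)
    return m.values[cols].mean(axis=1) - m.values[day0_cols].mean(axis=1)


def _vectorized_t_pvalues(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise pooled-variance t-test p-values with the degenerate-variance
    convention (p=1 equal means, p=0 unequal means)."""
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p = _sps.ttest_ind(a, b, axis=1, equal_var=True).pvalue
    pooled_zero = (a.var(axis=1, ddof=1) == 0) & (b.var(axis=1, ddof=1) == 0)
    diff = a.mean(axis=1) - b.mean(axis=1)
    p = np.where(pooled_zero, np.where(diff == 0, 1.0, 0.0), p)
    return p


def call_differential(
    m: ExpressionMatrix,
    time_day: float,
    fc_threshold: float = 2.0,
    fdr_threshold: float | None = 0.05,
    fc_only: bool = False,
) -> pd.DataFrame:
    """Call per-gene differential expression at one time point vs day 0.

    Returns a DataFrame indexed by gene with columns ``log2fc``, ``p``,
    ``q`` and ``call`` in {up, down, unchanged}.  With a pooled matrix
    p-values are undefined; pass ``fc_only=True`` to fall back to the
    fold-change rule alone (p and q are then NaN).
    """
    if fc_threshold < 1:
        raise ValueError("fc_threshold is a fold and must be >= 1")
    lfc = log2_fold_change(m, time_day)
    day0_cols = m.columns_at(0)
    cols = m.columns_at(time_day)
    pooled = len(day0_cols) < 2 or len(cols) < 2
    if pooled and not fc_only:
        raise ValueError(
            "matrix has < 2 replicates per group, p-values are undefined; "
            "pass fc_only=True to call on fold change alone"
        )
    if pooled:
        p = np.full(len(lfc), np.nan)
        q = p
        passes_fdr = np.ones(len(lfc), dtype=bool)
    else:
        p = _vectorized_t_pvalues(
            m.values[cols].to_numpy(float), m.values[day0_cols].to_numpy(float)
        )
        q = bh_fdr(p)
        passes_fdr = q <= (fdr_threshold if fdr_threshold is not None else 1.0)
    log2_cut = np.log2(fc_threshold)
    call = np.where(
        (lfc >= log2_cut) & passes_fdr,
        "up",
        np.where((lfc <= -log2_cut) & passes_fdr, "down", "unchanged"),
    )
    return pd.DataFrame(
        {"log2fc": lfc, "p": p, "q": q, "call": call}, index=m.gene_ids
    )


def union_set(results: Sequence[pd.DataFrame]) -> pd.Index:
    """Genes called up or down at one or more time points.

    All inputs must share the same gene universe (same index).
    """
    if not results:
        raise ValueError("no differential results given")
    universe = results[0].index
    members = np.zeros(len(universe), dtype=bool)
    for r in results:
        if not r.index.equals(universe):
            raise ValueError("differential results have mismatched gene universes")
        members |= (r["call"] != "unchanged").to_numpy()
    return universe[members]


def hierarchical_order(m: ExpressionMatrix, genes: Iterable[str]) -> list[str]:
    """Leaf order of average-linkage clustering on 1 - Pearson r distance
    over per-gene time-mean profiles (the usual heat-map row order).

    Zero-variance profiles get distance 1 (uncorrelated) to everything.
    Fewer than two genes: the input order is returned.
    """
    genes = list(genes)
    if len(genes) < 2:
        return genes
    tm = m.time_means(genes).to_numpy(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = pdist(tm, metric="correlation")
    d = np.nan_to_num(d, nan=1.0)
    order = leaves_list(linkage(d, method="average"))
    return [genes[i] for i in order]


class DifferentialExpressionCaller(BaseEstimator):
    """Call differential genes at every non-zero time point vs day 0.

    Parameters
    ----------
    fc_threshold : float, default 2.0
        Minimum fold change (|log2FC| >= log2(fc_threshold), inclusive).
    fdr_threshold : float, default 0.05
        Maximum BH q-value (inclusive); adjusted within each time point.
    fc_only : bool, default False
        Allow pooled (single column per group) matrices, calling on fold
        change alone.

    Attributes
    ----------
    results_ : dict mapping time_day -> per-gene DataFrame
        (log2fc, p, q, call).
    union_ : pd.Index of genes called at >= 1 time point.
    table_ : wide per-gene DataFrame (biotype plus log2fc/q/call per day).
    """

    def __init__(
        self,
        fc_threshold: float = 2.0,
        fdr_threshold: float = 0.05,
        fc_only: bool = False,
    ):
        self.fc_threshold = fc_threshold
        self.fdr_threshold = fdr_threshold
        self.fc_only = fc_only

    def fit(self, X: ExpressionMatrix, y=None) -> "DifferentialExpressionCaller":
        days = [d for d in X.time_points if d != 0]
        if not days:
            raise ValueError("matrix has no non-zero time points")
        self.results_ = {
            day: call_differential(
                X, day, self.fc_threshold, self.fdr_threshold, self.fc_only
            )
            for day in days
        }
        self.union_ = union_set(list(self.results_.values()))
        wide = {"biotype": X.biotype}
        for day, r in self.results_.items():
            tag = f"d{day:g}"
            wide[f"log2fc_{tag}"] = r["log2fc"]
            wide[f"q_{tag}"] = r["q"]
            wide[f"call_{tag}"] = r["call"]
        self.table_ = pd.DataFrame(wide, index=X.gene_ids)
        self.table_.index.name = "gene_id"
        return self

    def heatmap_order(self, X: ExpressionMatrix) -> list[str]:
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "union_")
        return hierarchical_order(X, self.union_)
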