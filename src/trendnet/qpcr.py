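"""Relative qPCR quantification by the delta-delta-Ct method.

Per replicate, dCt = Ct(target) - Ct(reference); ddCt at a time point is
the mean dCt there minus the mean dCt at day 0, and the fold change is
2^-ddCt (amplification efficiency fixed at 2, the classic assumption).
Groups are compared with the pooled-variance Student t-test on the
replicate dCt values — the approximately normal scale — with p < 0.05
flagged.  A concordance report compares qPCR folds with microarray log2
fold changes per gene (sign agreement and Pearson r).
"""
from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .stats import student_t_two_sample

__all__ = [
    "read_ct_csv",
    "validate_ct_table",
    "delta_delta_ct",
    "quantify_all",
    "concordance",
    "DeltaDeltaCtQuantifier",
]

_CT_COLUMNS = ["gene_id", "time_day", "replicate", "ct_target", "ct_reference"]


def read_ct_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in _CT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return validate_ct_table(df)


def validate_ct_table(t: pd.DataFrame) -> pd.DataFrame:
    vals = t[["ct_target", "ct_reference"]].to_numpy(float)
    if not np.all(np.isfinite(vals)) or np.any(vals <= 0):
        raise ValueError("Ct values must be positive and finite")
    for gene, grp in t.groupby("gene_id"):
        if 0 not in set(grp["time_day"]):
            raise ValueError(f"gene {gene}: no day-0 rows (required baseline)")
    return t


def _delta_ct(t: pd.DataFrame, gene: str, time_day: float) -> np.ndarray:
    rows = t[(t["gene_id"] == gene) & (t["time_day"] == time_day)]
    if rows.empty:
        raise ValueError(f"gene {gene}: no rows at day {time_day:g}")
    return (rows["ct_target"] - rows["ct_reference"]).to_numpy(float)


def delta_delta_ct(t: pd.DataFrame, gene: str, time_day: float) -> dict:
    """Quantify one (gene, time point) against day 0.

    Returns delta_delta_ct, fold = 2^-ddCt, and the t-test p-value on the
    replicate dCt sets (None with fewer than 2 replicates in a group).
    """
    dct = _delta_ct(t, gene, time_day)
    dct0 = _delta_ct(t, gene, 0)
    ddct = float(dct.mean() - dct0.mean())
    fold = float(2.0 ** (-ddct))
    if len(dct) >= 2 and len(dct0) >= 2 and time_day != 0:
        p = student_t_two_sample(dct, dct0).pvalue
    elif time_day == 0:
        p = 1.0
    else:
        p = None
    return {
        "gene_id": gene,
        "time_day": time_day,
        "delta_delta_ct": ddct,
        "fold": fold,
        "t_p_value": p,
        "significant": (p is not None and p < 0.05),
    }


def quantify_all(t: pd.DataFrame) -> pd.DataFrame:
    """delta_delta_ct for every (gene, time point) in the table."""
    validate_ct_table(t)
    rows = [
        delta_delta_ct(t, gene, day)
        for gene in sorted(t["gene_id"].unique())
        for day in sorted(t.loc[t["gene_id"] == gene, "time_day"].unique())
    ]
    return pd.DataFrame(rows)


def concordance(qpcr: pd.DataFrame, array_fc: Mapping[tuple[str, float], float]) -> dict:
    """Compare qPCR folds with microarray log2 fold changes.

    ``array_fc`` maps (gene, time_day) -> array log2FC.  Per gene:
    sign-agreement fraction across shared non-zero time points and the
    Pearson r between log2(qPCR fold) and the array log2FC; plus the
    overall sign-agreement fraction.
    """
    shared = [
        row
        for row in qpcr.itertuples()
        if row.time_day != 0 and (row.gene_id, row.time_day) in array_fc
    ]
    if not shared:
        raise ValueError("no shared (gene, time) keys between qPCR and array results")
    per_gene: dict[str, dict] = {}
    agree_total = 0
    for row in shared:
        q_lfc = -row.delta_delta_ct  # log2 of qPCR fold
        a_lfc = array_fc[(row.gene_id, row.time_day)]
        agree = bool(q_lfc * a_lfc > 0 or (q_lfc == 0 and a_lfc == 0))
        agree_total += agree
        rec = per_gene.setdefault(row.gene_id, {"q": [], "a": [], "agree": []})
        rec["q"].append(q_lfc)
        rec["a"].append(a_lfc)
        rec["agree"].append(agree)
    gene_rows = []
    for gene, rec in sorted(per_gene.items()):
        q, a = np.array(rec["q"]), np.array(rec["a"])
        if len(q) >= 2 and q.std() > 0 and a.std() > 0:
            r = float(np.corrcoef(q, a)[0, 1])
        else:
            r = np.nan
        gene_rows.append(
            {
                "gene_id": gene,
                "n_times": len(q),
                "sign_agreement": float(np.mean(rec["agree"])),
                "pearson_r": r,
            }
        )
    return {
        "per_gene": pd.DataFrame(gene_rows),
        "overall_agreement": agree_total / len(shared),
        "n_comparisons": len(shared),
    }


class DeltaDeltaCtQuantifier(BaseEstimator):
    """Estimator wrapper around :func:`quantify_all` / :func:`concordance`.

    Attributes
    ----------
    quantification_ : tidy DataFrame (gene, time, ddCt, fold, p, significant).
    concordance_ : dict from :func:`concordance` when array fold changes
        were supplied to :meth:`fit`.
    """

    def fit(
        self,
        X: pd.DataFrame,
        y: Mapping[tuple[str, float], float] | None = None,
    ) -> "DeltaDeltaCtQuantifier":
        self.quantification_ = quantify_all(X)
        self.concordance_ = concordance(self.quantification_, y) if y else None
        return self
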