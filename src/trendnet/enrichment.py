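"""Term-enrichment analysis of a gene list against a background universe.

Generic over GO-like and pathway-like collections supplied in GMT format.
Each term is scored with a two-sided Fisher exact test (and a chi-square
test where the expected counts permit) on the 2x2 table of list/background
vs in-term/out-of-term membership, with BH q-values across terms.  The
significance gate is the raw Fisher p-value at 1e-4 by default, with the
q-value reported alongside.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .stats import TwoByTwoTable, bh_fdr, chi_square_2x2, fisher_exact_two_sided

__all__ = [
    "GeneSetCollection",
    "read_gmt",
    "write_gmt",
    "enrich",
    "TermEnrichment",
]

logger = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    """Named gene sets plus the background universe they are tested
    against (typically every gene on the array)."""

    sets: dict[str, tuple[str, frozenset[str]]]  # term_id -> (name, members)
    universe: frozenset[str]

    def __post_init__(self) -> None:
        self.universe = frozenset(self.universe)
        restricted = {}
        for tid, (name, members) in self.sets.items():
            kept = frozenset(members) & self.universe
            if kept:
                restricted[tid] = (name, kept)
        self.sets = restricted

    def __len__(self) -> int:
        return len(self.sets)

    @property
    def term_ids(self) -> list[str]:
        return list(self.sets)

    def members(self, term_id: str) -> frozenset[str]:
        return self.sets[term_id][1]

    def annotated_universe(self) -> frozenset[str]:
        out: set[str] = set()
        for _, members in self.sets.values():
            out |= members
        return frozenset(out)


def read_gmt(path: str | Path, universe: Iterable[str]) -> GeneSetCollection:
    """Read a standard GMT file (term, description, members, tab-separated)."""
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = (parts[1], frozenset(parts[2:]))
    return GeneSetCollection(sets, frozenset(universe))


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for tid, (name, members) in collection.sets.items():
            fh.write("\t".join([tid, name, *sorted(members)]) + "\n")


def enrich(
    genes: Iterable[str],
    sets: GeneSetCollection,
    p_threshold: float = 1e-4,
    annotated_only: bool = False,
) -> pd.DataFrame:
    """Score every term for over-representation in ``genes``.

    Returns one row per term — 2x2 counts, fisher_p, chisq_p (NaN when a
    margin is empty), BH ``fdr_q`` across terms, and the ``enriched`` flag
    (fisher_p < p_threshold) — sorted by fisher_p ascending, ties by
    term id.  Genes outside the universe are dropped with a logged count.
    """
    gene_set = set(genes)
    if not gene_set:
        raise ValueError("empty gene list")
    if len(sets) == 0:
        raise ValueError("empty gene-set collection")
    universe = sets.annotated_universe() if annotated_only else sets.universe
    dropped = gene_set - universe
    if dropped:
        logger.info("dropping %d genes outside the universe", len(dropped))
    gene_set &= universe
    if not gene_set:
        raise ValueError("no genes remain after restriction to the universe")
    n_list = len(gene_set)
    n_universe = len(universe)
    rows = []
    for tid in sorted(sets.term_ids):
        name, members = sets.sets[tid]
        members = members & universe
        if not members:
            continue
        a = len(gene_set & members)
        b = n_list - a
        c = len(members) - a
        d = n_universe - n_list - c
        table = TwoByTwoTable(a, b, c, d)
        fisher_p = fisher_exact_two_sided(table)
        arr = table.as_array()
        if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
            chisq_p = np.nan
        else:
            chisq_p = chi_square_2x2(table).pvalue
        rows.append((tid, name, a, b, c, d, fisher_p, chisq_p))
    df = pd.DataFrame(
        rows, columns=["term_id", "name", "a", "b", "c", "d", "fisher_p", "chisq_p"]
    )
    df["fdr_q"] = bh_fdr(df["fisher_p"].to_numpy())
    df["enriched"] = df["fisher_p"] < p_threshold
    df = df.sort_values(["fisher_p", "term_id"], kind="mergesort").reset_index(drop=True)
    return df


class TermEnrichment(BaseEstimator):
    """Estimator wrapper around :func:`enrich`.

    Parameters
    ----------
    p_threshold : float, default 1e-4
        Raw Fisher p-value gate for the ``enriched`` flag.
    annotated_only : bool, default False
        Restrict the background to genes appearing in at least one term.

    Attributes
    ----------
    results_ : DataFrame as returned by :func:`enrich`.
    enriched_terms_ : list of term ids passing the gate, best first.
    """

    def __init__(self, p_threshold: float = 1e-4, annotated_only: bool = False):
        self.p_threshold = p_threshold
        self.annotated_only = annotated_only

    def fit(self, X: Iterable[str], y: GeneSetCollection | None = None) -> "TermEnrichment":
        if y is None:
            raise ValueError("fit requires the GeneSetCollection as the second argument")
        self.results_ = enrich(X, y, self.p_threshold, self.annotated_only)
        self.enriched_terms_ = self.results_.loc[
            self.results_["enriched"], "term_id"
        ].tolist()
        return self
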