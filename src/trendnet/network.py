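"""Thresholded LncRNA–mRNA coexpression network with graph metrics.

Pairwise Pearson correlations are computed over per-gene time-mean
vectors (one value per time point, matching a design with one pooled
profile per group).  Gene pairs with |r| >= threshold (default 0.997,
boundary inclusive) become signed edges; in the default ``lncrna-mrna``
mode only cross-biotype pairs are tested, which makes the graph
bipartite.  Nodes are annotated with degree, core number (K-core) and
the local clustering coefficient.
"""
from __future__ import annotations

import warnings
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .matrix import BIOTYPES, ExpressionMatrix

__all__ = [
    "timecourse_correlation",
    "build_network",
    "annotate_metrics",
    "rank_hubs",
    "CoexpressionNetworkBuilder",
]


def timecourse_correlation(
    m: ExpressionMatrix, genes: Iterable[str] | None = None
) -> pd.DataFrame:
    """Pairwise Pearson r between per-gene time-mean vectors.

    Genes whose time-mean vector has zero variance are dropped with a
    warning (their correlation is undefined).
    """
    tm = m.time_means(genes)
    if tm.shape[1] < 2:
        raise ValueError("need >= 2 time points for correlations")
    arr = tm.to_numpy(float)
    usable = arr.var(axis=1) > 0
    if not usable.all():
        warnings.warn(
            f"dropping {(~usable).sum()} zero-variance genes from correlation",
            stacklevel=2,
        )
    if usable.sum() < 2:
        raise ValueError("fewer than 2 usable genes for correlation")
    kept = tm.index[usable]
    r = np.corrcoef(arr[usable])
    np.fill_diagonal(r, 1.0)
    return pd.DataFrame(r, index=kept, columns=kept)


def build_network(
    r: pd.DataFrame,
    biotypes: Mapping[str, str] | pd.Series,
    threshold: float = 0.997,
    mode: str = "lncrna-mrna",
) -> nx.Graph:
    """Build the coexpression graph from a correlation matrix.

    Edges where |r| >= threshold (inclusive); edge attributes ``r`` and
    ``sign`` ('+'/'-'); node attribute ``biotype``.  In ``lncrna-mrna``
    mode only LncRNA–mRNA pairs are tested; ``all-pairs`` tests every
    pair.  Isolated nodes are dropped.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    if mode not in ("lncrna-mrna", "all-pairs"):
        raise ValueError(f"unknown mode {mode!r}")
    genes = list(r.index)
    bt = {g: biotypes[g] for g in genes}
    bad = sorted(set(bt.values()) - set(BIOTYPES))
    if bad:
        raise ValueError(f"unknown biotype labels: {bad}; expected {BIOTYPES}")
    arr = r.to_numpy(float)
    iu, ju = np.triu_indices(len(genes), k=1)
    keep = np.abs(arr[iu, ju]) >= threshold
    g = nx.Graph()
    for i, j in zip(iu[keep], ju[keep]):
        a, b = genes[i], genes[j]
        if mode == "lncrna-mrna" and bt[a] == bt[b]:
            continue
        rv = float(arr[i, j])
        # deterministic orientation: smaller gene id first
        a, b = (a, b) if a <= b else (b, a)
        g.add_edge(a, b, r=rv, sign="+" if rv >= 0 else "-")
    nx.set_node_attributes(g, {v: bt[v] for v in g.nodes}, "biotype")
    return g


def annotate_metrics(net: nx.Graph) -> nx.Graph:
    """Fill degree, k_core and clustering_coefficient node attributes.

    Degree counts incident edges; the core number is the largest k such
    that the node survives iterative removal of nodes with degree < k;
    the clustering coefficient is 2*triangles / (deg*(deg-1)) and 0 for
    degree < 2.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("empty graph")
    nx.set_node_attributes(net, dict(net.degree()), "degree")
    nx.set_node_attributes(net, nx.core_number(net), "k_core")
    nx.set_node_attributes(net, nx.clustering(net), "clustering_coefficient")
    return net


def rank_hubs(net: nx.Graph, n: int) -> list[str]:
    """Top-n genes by (k_core desc, degree desc, gene id asc)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if "k_core" not in next(iter(net.nodes(data=True)))[1]:
        annotate_metrics(net)
    if n > net.number_of_nodes():
        warnings.warn(
            f"requested {n} hubs but the graph has {net.number_of_nodes()} nodes",
            stacklevel=2,
        )
    ranked = sorted(
        net.nodes,
        key=lambda v: (-net.nodes[v]["k_core"], -net.nodes[v]["degree"], v),
    )
    return ranked[:n]


def node_table(net: nx.Graph) -> pd.DataFrame:
    rows = [
        (
            v,
            d.get("biotype", ""),
            d.get("degree", 0),
            d.get("k_core", 0),
            d.get("clustering_coefficient", 0.0),
        )
        for v, d in sorted(net.nodes(data=True))
    ]
    return pd.DataFrame(
        rows, columns=["gene_id", "biotype", "degree", "k_core", "clustering_coefficient"]
    )


def edge_table(net: nx.Graph) -> pd.DataFrame:
    rows = sorted(
        (min(a, b), max(a, b), d["r"], d["sign"]) for a, b, d in net.edges(data=True)
    )
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "r", "sign"])


class CoexpressionNetworkBuilder(BaseEstimator):
    """Build and annotate the thresholded coexpression network.

    Parameters
    ----------
    threshold : float, default 0.997
        Minimum |Pearson r| for an edge (inclusive).
    mode : {'lncrna-mrna', 'all-pairs'}, default 'lncrna-mrna'
        Which gene pairs are eligible for edges.

    Attributes
    ----------
    graph_ : networkx.Graph with node metrics filled in.
    nodes_, edges_ : tidy DataFrames of the annotated graph.
    """

    def __init__(self, threshold: float = 0.997, mode: str = "lncrna-mrna"):
        self.threshold = threshold
        self.mode = mode

    def fit(
        self, X: ExpressionMatrix, y: Iterable[str] | None = None
    ) -> "CoexpressionNetworkBuilder":
        genes = list(y) if y is not None else None
        r = timecourse_correlation(X, genes)
        self.correlation_ = r
        self.graph_ = build_network(r, X.biotype, self.threshold, self.mode)
        if self.graph_.number_of_nodes() > 0:
            annotate_metrics(self.graph_)
        self.nodes_ = node_table(self.graph_)
        self.edges_ = edge_table(self.graph_)
        return self

    def hubs(self, n: int = 10) -> list[str]:
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "graph_")
        if self.graph_.number_of_nodes() == 0:
            return []
        return rank_hubs(self.graph_, n)
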