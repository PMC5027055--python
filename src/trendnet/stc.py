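"""Series test of cluster (STC) trend analysis.

Short gene-expression time courses are matched against an enumerated
catalogue of discrete model trend profiles: every sequence of unit changes
in {-c..+c} between consecutive time points, anchored at 0 at the first
time point.  With T = 5 time points, c = 1 and the flat profile excluded
this yields the classic 80 model profiles.  Each gene is assigned to the
profile its (anchored) time-course correlates with best; per-profile gene
counts are then tested against an independence null in which each gene's
time-point values are randomly permuted.  Under that null the count in a
profile is binomial, so profile significance is the upper binomial tail of
the observed count at the permutation-estimated expectation, BH-adjusted
across profiles.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .matrix import ExpressionMatrix
from .stats import bh_fdr, binomial_tail_geq

__all__ = [
    "TrendProfile",
    "ProfileAssignment",
    "enumerate_profiles",
    "discretize_gene",
    "assign_profiles",
    "profile_significance",
    "TrendProfileClusterer",
]


@dataclass(frozen=True)
class TrendProfile:
    """A discrete model trend: unit steps between consecutive time points
    and the cumulative value vector anchored at 0."""

    profile_id: int
    steps: tuple[int, ...]

    @property
    def values(self) -> tuple[int, ...]:
        return (0, *np.cumsum(self.steps).tolist())


@dataclass
class ProfileAssignment:
    """Best-matching profile per gene plus the genes that could not be
    scored (zero-variance time courses, where correlation is undefined)."""

    table: pd.DataFrame  # index gene_id, columns: profile_id, score
    unassignable: list[str]

    @property
    def n_assignable(self) -> int:
        return len(self.table)

    def counts(self, n_profiles: int) -> np.ndarray:
        return np.bincount(self.table["profile_id"].to_numpy(), minlength=n_profiles)


def enumerate_profiles(
    n_time_points: int, max_unit_change: int = 1, exclude_flat: bool = True
) -> list[TrendProfile]:
    """All (2c+1)^(T-1) step sequences in lexicographic order, optionally
    without the all-zero (flat) profile; profile_id is the position in
    this order."""
    if n_time_points < 2:
        raise ValueError("need at least 2 time points to define a trend")
    if max_unit_change < 1:
        raise ValueError("max_unit_change must be >= 1")
    c = max_unit_change
    profiles: list[TrendProfile] = []
    for steps in itertools.product(range(-c, c + 1), repeat=n_time_points - 1):
        if exclude_flat and all(s == 0 for s in steps):
            continue
        profiles.append(TrendProfile(len(profiles), steps))
    return profiles


def discretize_gene(time_means: Sequence[float]) -> np.ndarray:
    """Anchor a gene's per-time means at 0 at the first time point."""
    v = np.asarray(time_means, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("time means must be finite")
    return v - v[0]


def _profile_value_matrix(profiles: Sequence[TrendProfile]) -> np.ndarray:
    return np.array([p.values for p in profiles], dtype=float)


def _zscore_rows(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Center rows and scale to unit norm; returns (z, flat_mask).

    Rows with zero variance get all-zero z rows and flat_mask True — their
    correlation with anything is undefined.
    """
    centered = x - x.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    flat = norms == 0.0
    safe = np.where(flat, 1.0, norms)
    return centered / safe[:, None], flat


def _correlation_scores(z_genes: np.ndarray, z_profiles: np.ndarray, flat_profiles: np.ndarray) -> np.ndarray:
    scores = z_genes @ z_profiles.T
    # a flat profile (only possible when exclude_flat=False) can never win
    scores[:, flat_profiles] = -np.inf
    return scores


def _euclidean_scores(anchored: np.ndarray, profile_values: np.ndarray) -> np.ndarray:
    # negative distance so argmax picks the nearest profile
    d = np.linalg.norm(anchored[:, None, :] - profile_values[None, :, :], axis=2)
    return -d


def _best_profiles(
    time_mean_matrix: np.ndarray,
    profiles: Sequence[TrendProfile],
    metric: str = "pearson",
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(labels, scores, assignable_mask) for a genes x T array of time means.

    argmax breaks ties toward the lowest profile_id (numpy argmax returns
    the first maximum, and profiles are ordered by id).
    """
    pv = _profile_value_matrix(profiles)
    anchored = time_mean_matrix - time_mean_matrix[:, [0]]
    z_genes, flat_genes = _zscore_rows(anchored)
    if metric == "pearson":
        z_prof, flat_prof = _zscore_rows(pv)
        scores = _correlation_scores(z_genes, z_prof, flat_prof)
    elif metric == "euclidean":
        scores = _euclidean_scores(anchored, pv)
    else:
        raise ValueError(f"unknown metric {metric!r}; use 'pearson' or 'euclidean'")
    labels = scores.argmax(axis=1)
    best = scores[np.arange(len(labels)), labels]
    assignable = ~flat_genes if metric == "pearson" else np.ones(len(labels), bool)
    return labels, best, assignable


def _as_time_means(genes: ExpressionMatrix | pd.DataFrame) -> pd.DataFrame:
    if isinstance(genes, ExpressionMatrix):
        return genes.time_means()
    return pd.DataFrame(genes).astype(float)


def assign_profiles(
    genes: ExpressionMatrix | pd.DataFrame,
    profiles: Sequence[TrendProfile],
    metric: str = "pearson",
) -> ProfileAssignment:
    """Assign each gene to its best-matching model profile.

    ``genes`` is an ExpressionMatrix or a genes x T DataFrame of per-time
    means.  With the default Pearson metric the score is the correlation
    between the gene's anchored trend vector and the profile's value
    vector (in [-1, 1]); genes with a zero-variance trend are reported in
    ``unassignable``.
    """
    if not profiles:
        raise ValueError("profiles must be non-empty")
    tm = _as_time_means(genes)
    labels, scores, assignable = _best_profiles(tm.to_numpy(dtype=float), profiles, metric)
    table = pd.DataFrame(
        {"profile_id": labels[assignable], "score": scores[assignable]},
        index=tm.index[assignable],
    )
    table.index.name = "gene_id"
    return ProfileAssignment(table, tm.index[~assignable].tolist())


def _permutation_expected_counts(
    time_mean_matrix: np.ndarray,
    profiles: Sequence[TrendProfile],
    n_permutations: int,
    rng: np.random.Generator,
    metric: str = "pearson",
    chunk: int = 200,
) -> np.ndarray:
    """Mean per-profile assignment count when every gene's time-point
    values are independently permuted (the independence null)."""
    n_genes, t = time_mean_matrix.shape
    n_prof = len(profiles)
    totals = np.zeros(n_prof, dtype=np.int64)
    done = 0
    while done < n_permutations:
        b = min(chunk, n_permutations - done)
        # one random permutation of the T values per gene per permutation
        keys = rng.random((b, n_genes, t))
        order = np.argsort(keys, axis=2)
        permuted = np.take_along_axis(
            np.broadcast_to(time_mean_matrix, (b, n_genes, t)), order, axis=2
        ).reshape(b * n_genes, t)
        labels, _, assignable = _best_profiles(permuted, profiles, metric)
        totals += np.bincount(labels[assignable], minlength=n_prof)
        done += b
    return totals / n_permutations


def profile_significance(
    assignment: ProfileAssignment,
    genes: ExpressionMatrix | pd.DataFrame,
    profiles: Sequence[TrendProfile],
    n_permutations: int = 1000,
    seed: int | None = None,
    metric: str = "pearson",
) -> pd.DataFrame:
    """Score each profile's observed gene count against the permutation
    null.

    For each permutation every gene's T time-mean values are shuffled
    independently and genes are re-assigned; ``genes_expected`` is the mean
    count over permutations, the p-value is P(X >= genes_assigned) for
    X ~ Binomial(N_assignable, genes_expected / N_assignable), and adj_p is
    BH across profiles with significance at adj_p < 0.05.
    """
    if n_permutations < 100:
        raise ValueError("n_permutations must be >= 100")
    n_prof = len(profiles)
    n_assignable = assignment.n_assignable
    cols = ["profile_id", "genes_assigned", "genes_expected", "p", "adj_p", "significant"]
    if n_assignable == 0:
        import warnings

        warnings.warn("no assignable genes; empty significance table", stacklevel=2)
        return pd.DataFrame(columns=cols)
    tm = _as_time_means(genes).loc[assignment.table.index]
    rng = np.random.default_rng(seed)
    expected = _permutation_expected_counts(
        tm.to_numpy(dtype=float), profiles, n_permutations, rng, metric
    )
    observed = assignment.counts(n_prof)
    rates = expected / n_assignable
    p = np.array(
        [binomial_tail_geq(int(k), n_assignable, r) for k, r in zip(observed, rates)]
    )
    adj = bh_fdr(p)
    return pd.DataFrame(
        {
            "profile_id": np.arange(n_prof),
            "genes_assigned": observed,
            "genes_expected": expected,
            "p": p,
            "adj_p": adj,
            "significant": adj < 0.05,
        }
    )


class TrendProfileClusterer(BaseEstimator):
    """Cluster short expression time courses onto discrete model profiles
    and test per-profile gene counts against a permutation/binomial null.

    Parameters
    ----------
    max_unit_change : int, default 1
        Bound c on the per-step change; profiles enumerate steps in
        [-c, +c].  c=1 over 5 time points gives the classic 80 profiles.
    exclude_flat : bool, default True
        Drop the all-zero profile from the catalogue.
    metric : {'pearson', 'euclidean'}, default 'pearson'
        Gene-to-profile matching score.
    n_permutations : int, default 1000
        Permutations used to estimate the null expectation per profile.
    alpha : float, default 0.05
        BH-adjusted significance cut-off.
    random_state : int or None
        Seed for the permutation null.

    Attributes
    ----------
    profiles_ : list of TrendProfile
    assignment_ : ProfileAssignment
    labels_ : ndarray of assigned profile ids (assignable genes, input order)
    significance_ : DataFrame with genes_assigned / genes_expected / p /
        adj_p / significant per profile
    """

    def __init__(
        self,
        max_unit_change: int = 1,
        exclude_flat: bool = True,
        metric: str = "pearson",
        n_permutations: int = 1000,
        alpha: float = 0.05,
        random_state: int | None = None,
    ):
        self.max_unit_change = max_unit_change
        self.exclude_flat = exclude_flat
        self.metric = metric
        self.n_permutations = n_permutations
        self.alpha = alpha
        self.random_state = random_state

    def fit(self, X: ExpressionMatrix | pd.DataFrame, y=None) -> "TrendProfileClusterer":
        tm = _as_time_means(X)
        self.profiles_ = enumerate_profiles(
            tm.shape[1], self.max_unit_change, self.exclude_flat
        )
        self.assignment_ = assign_profiles(tm, self.profiles_, self.metric)
        self.labels_ = self.assignment_.table["profile_id"].to_numpy()
        self.significance_ = profile_significance(
            self.assignment_,
            tm,
            self.profiles_,
            n_permutations=self.n_permutations,
            seed=self.random_state,
            metric=self.metric,
        )
        if not self.significance_.empty and self.alpha != 0.05:
            self.significance_["significant"] = self.significance_["adj_p"] < self.alpha
        return self

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).labels_

    def predict(self, X: ExpressionMatrix | pd.DataFrame) -> np.ndarray:
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "profiles_")
        return assign_profiles(X, self.profiles_, self.metric).table["profile_id"].to_numpy()

    # serialisation helpers used by the CLI -------------------------------
    def profile_catalog(self) -> pd.DataFrame:
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "profiles_")
        return pd.DataFrame(
            {
                "profile_id": [p.profile_id for p in self.profiles_],
                "steps": [",".join(map(str, p.steps)) for p in self.profiles_],
                "values": [",".join(map(str, p.values)) for p in self.profiles_],
            }
        )
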