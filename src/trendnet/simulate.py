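"""Seeded synthetic expression studies with known ground truth.

Emulates the statistical structure of a 5-time-point (days 0/1/3/7/21)
microarray study of LncRNA and mRNA expression after injury: per-gene
log2 baselines in the typical microarray range, a planted fraction of
genes following discrete trend profiles scaled by an amplitude, Gaussian
noise per replicate, planted high-correlation LncRNA–mRNA pairs realised
by sharing a latent profile, planted enriched terms, and replicate Ct
tables with a stable reference gene.  Every downstream stage of the
pipeline is testable against the returned ground truth without any
download.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .enrichment import GeneSetCollection
from .matrix import ExpressionMatrix
from .stc import TrendProfile, enumerate_profiles

__all__ = [
    "ConfigurationError",
    "SimulationConfig",
    "GroundTruth",
    "generate_timecourse",
    "generate_gene_sets",
    "generate_ct_table",
]

# minimum squared norm (amplitude units) of a centered profile-value vector
# for a profile to host a planted coexpressed pair: weak profiles cannot
# push the pair's time-mean correlation to ~1 once noise is added
_PAIR_PROFILE_MIN_SS = 4.0


class ConfigurationError(ValueError):
    """Invalid simulation configuration; the message names the field."""

    def __init__(self, config_field: str, message: str):
        self.config_field = config_field
        super().__init__(f"{config_field}: {message}")


@dataclass
class SimulationConfig:
    """Parameters of a synthetic expression study.

    Defaults mirror the emulated design: five time points (days 0, 1, 3,
    7, 21), three replicates per group, log2 baselines in [4, 14], trend
    amplitude of one log2 unit per profile step and replicate noise of
    0.2 log2 units.
    """

    n_lncrna: int = 200
    n_mrna: int = 800
    time_points_days: tuple[float, ...] = (0, 1, 3, 7, 21)
    replicates_per_time: int = 3
    frac_trended: float = 0.3
    trend_amplitude: float = 1.0
    noise_sd: float = 0.2
    n_trend_profiles: int = 4
    n_planted_pairs: int = 20
    n_terms: int = 50
    n_planted_terms: int = 3
    planted_term_enrichment: float = 8.0
    max_unit_change: int = 1
    pooled: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.n_lncrna < 0 or self.n_mrna < 0 or self.n_lncrna + self.n_mrna == 0:
            raise ConfigurationError("n_lncrna/n_mrna", "need a positive total gene count")
        tp = tuple(self.time_points_days)
        if len(tp) < 2 or any(b <= a for a, b in zip(tp, tp[1:])):
            raise ConfigurationError(
                "time_points_days", "must be strictly increasing with >= 2 points"
            )
        if self.replicates_per_time < 1:
            raise ConfigurationError("replicates_per_time", "must be >= 1")
        if not 0.0 <= self.frac_trended <= 1.0:
            raise ConfigurationError("frac_trended", "must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd", "must be >= 0")
        if self.trend_amplitude < 0:
            raise ConfigurationError("trend_amplitude", "must be >= 0")
        if self.n_trend_profiles < 1:
            raise ConfigurationError("n_trend_profiles", "must be >= 1")
        if self.n_planted_pairs < 0:
            raise ConfigurationError("n_planted_pairs", "must be >= 0")
        if self.n_planted_pairs > min(self._n_trended_lnc, self._n_trended_mrna):
            raise ConfigurationError(
                "n_planted_pairs",
                "cannot exceed the number of trended genes of either biotype "
                f"({self._n_trended_lnc} LncRNA, {self._n_trended_mrna} mRNA trended)",
            )
        if self.n_terms < self.n_planted_terms:
            raise ConfigurationError(
                "n_terms", f"must be >= n_planted_terms ({self.n_planted_terms})"
            )
        if self.planted_term_enrichment <= 0:
            raise ConfigurationError("planted_term_enrichment", "must be > 0")

    @property
    def _n_trended_lnc(self) -> int:
        return int(round(self.frac_trended * self.n_lncrna))

    @property
    def _n_trended_mrna(self) -> int:
        return int(round(self.frac_trended * self.n_mrna))

    @property
    def n_time_points(self) -> int:
        return len(self.time_points_days)


@dataclass
class GroundTruth:
    """What was planted: the true profile per gene (None for untrended
    genes), the coexpressed LncRNA–mRNA pairs, and — once gene sets are
    generated — the enriched term ids."""

    true_profile: dict[str, int | None]
    planted_pairs: list[tuple[str, str]]
    planted_terms: list[str] = field(default_factory=list)

    @property
    def trended_genes(self) -> list[str]:
        return [g for g, p in self.true_profile.items() if p is not None]


def _pair_eligible_profiles(profiles: Sequence[TrendProfile]) -> np.ndarray:
    values = np.array([p.values for p in profiles], dtype=float)
    centered = values - values.mean(axis=1, keepdims=True)
    ss = (centered**2).sum(axis=1)
    return np.flatnonzero(ss >= _PAIR_PROFILE_MIN_SS)


def generate_timecourse(config: SimulationConfig) -> tuple[ExpressionMatrix, GroundTruth]:
    """Simulate the expression matrix and its ground truth.

    Trended genes follow ``baseline + trend_amplitude * profile_values``
    plus N(0, noise_sd^2) per replicate; untrended genes are baseline plus
    noise.  Members of a planted pair share the same latent profile, so
    at zero noise their time-mean correlation is exactly 1.  A single RNG
    stream with a fixed draw order makes the output byte-identical for a
    fixed config and seed.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_lnc, n_mrna = config.n_lncrna, config.n_mrna
    n_genes = n_lnc + n_mrna
    t = config.n_time_points
    reps = config.replicates_per_time

    gene_ids = [f"LNC{i + 1:05d}" for i in range(n_lnc)] + [
        f"MRNA{i + 1:05d}" for i in range(n_mrna)
    ]
    biotypes = ["LncRNA"] * n_lnc + ["mRNA"] * n_mrna

    profiles = enumerate_profiles(t, config.max_unit_change, exclude_flat=True)
    values = np.array([p.values for p in profiles], dtype=float)

    # fixed draw order: baselines, profile pool, trended genes, pair
    # profiles, remaining trend assignment, noise block
    baselines = rng.uniform(4.0, 14.0, size=n_genes)
    # the trend pool hosts every planted gene; its first member is drawn
    # from the high-variance profiles so planted pairs have a trajectory
    # strong enough to keep their correlation near 1 under noise
    eligible = _pair_eligible_profiles(profiles)
    n_pool = min(config.n_trend_profiles, len(profiles))
    anchor = rng.choice(eligible, size=1)
    others = np.setdiff1d(np.arange(len(profiles)), anchor)
    pool = np.concatenate([anchor, rng.choice(others, size=n_pool - 1, replace=False)])
    trended_lnc = rng.choice(n_lnc, size=config._n_trended_lnc, replace=False)
    trended_mrna = n_lnc + rng.choice(n_mrna, size=config._n_trended_mrna, replace=False)

    n_pairs = config.n_planted_pairs
    pair_pool = np.intersect1d(pool, eligible)
    pair_profiles = rng.choice(pair_pool, size=n_pairs, replace=True) if n_pairs else np.array([], dtype=int)

    true_profile = np.full(n_genes, -1, dtype=int)
    pair_lnc, pair_mrna = trended_lnc[:n_pairs], trended_mrna[:n_pairs]
    true_profile[pair_lnc] = pair_profiles
    true_profile[pair_mrna] = pair_profiles
    rest = np.concatenate([trended_lnc[n_pairs:], trended_mrna[n_pairs:]])
    if rest.size:
        true_profile[rest] = rng.choice(pool, size=rest.size, replace=True)

    signal = np.repeat(baselines[:, None], t, axis=1)
    trended_mask = true_profile >= 0
    signal[trended_mask] += config.trend_amplitude * values[true_profile[trended_mask]]

    data = np.repeat(signal, reps, axis=1)
    data = data + rng.normal(0.0, config.noise_sd, size=(n_genes, t * reps))

    matrix = ExpressionMatrix.from_arrays(
        gene_ids, biotypes, config.time_points_days, data, reps
    )
    if config.pooled:
        matrix = matrix.pooled()

    truth = GroundTruth(
        true_profile={
            g: (int(p) if p >= 0 else None) for g, p in zip(gene_ids, true_profile)
        },
        planted_pairs=[
            (gene_ids[i], gene_ids[j]) for i, j in zip(pair_lnc, pair_mrna)
        ],
    )
    return matrix, truth


def generate_gene_sets(config: SimulationConfig, truth: GroundTruth) -> GeneSetCollection:
    """Build ``n_terms`` gene sets over the simulated universe.

    The first ``n_planted_terms`` sets over-sample trended genes with odds
    ``planted_term_enrichment``; the rest sample uniformly.  The planted
    term ids are recorded in ``truth.planted_terms``.
    """
    config.validate()
    universe = list(truth.true_profile)
    if not universe:
        raise ConfigurationError("n_lncrna/n_mrna", "ground truth has no genes")
    rng = np.random.default_rng([config.seed, 1])
    trended = np.array([truth.true_profile[g] is not None for g in universe])
    n_genes = len(universe)
    # planted terms are sized like curated validation panels (30-50 genes):
    # large enough that the planted odds ratio is detectable by a Fisher
    # test at the pipeline's p < 1e-4 gate; background terms span 10-50
    hi = min(51, n_genes + 1)
    sizes = rng.integers(10, hi, size=config.n_terms)
    sizes[: config.n_planted_terms] = rng.integers(
        min(30, hi - 1), hi, size=config.n_planted_terms
    )
    weights = np.where(trended, config.planted_term_enrichment, 1.0)
    weights = weights / weights.sum()
    uniform = np.full(n_genes, 1.0 / n_genes)
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    planted: list[str] = []
    for i, size in enumerate(sizes):
        tid = f"TERM{i + 1:04d}"
        is_planted = i < config.n_planted_terms
        p = weights if is_planted else uniform
        members = rng.choice(n_genes, size=size, replace=False, p=p)
        label = "planted enriched term" if is_planted else "background term"
        sets[tid] = (label, frozenset(universe[j] for j in members))
        if is_planted:
            planted.append(tid)
    truth.planted_terms = planted
    return GeneSetCollection(sets, frozenset(universe))


def generate_ct_table(
    n_genes: int,
    time_points_days: Sequence[float],
    replicates: int,
    true_fold_changes: Mapping[tuple[str, float], float],
    seed: int,
    noise_sd: float = 0.1,
    gene_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Simulate a qPCR Ct table with a stable reference gene.

    The target-vs-reference delta-Ct of a gene shifts by ``-log2(fold)``
    relative to day 0, so the downstream 2^-ddCt quantification recovers
    ``true_fold_changes``; the reference Ct is time-invariant in
    expectation.  Columns: gene_id, time_day, replicate, ct_target,
    ct_reference.
    """
    if replicates < 2:
        raise ValueError("replicates must be >= 2 (the downstream t-test needs >= 2)")
    if gene_ids is None:
        gene_ids = [f"QG{i + 1:03d}" for i in range(n_genes)]
    elif len(gene_ids) != n_genes:
        raise ValueError("gene_ids length must equal n_genes")
    rng = np.random.default_rng([seed, 2])
    ref_base = 18.0
    base_dct = rng.uniform(2.0, 8.0, size=n_genes)
    rows = []
    for gi, gene in enumerate(gene_ids):
        for day in time_points_days:
            fold = float(true_fold_changes.get((gene, day), 1.0))
            if fold <= 0:
                raise ValueError(f"fold change for ({gene}, {day}) must be > 0")
            dct = base_dct[gi] - np.log2(fold)
            for rep in range(1, replicates + 1):
                ct_ref = ref_base + rng.normal(0.0, noise_sd)
                ct_tgt = ref_base + dct + rng.normal(0.0, noise_sd)
                rows.append((gene, day, rep, ct_tgt, ct_ref))
    return pd.DataFrame(
        rows, columns=["gene_id", "time_day", "replicate", "ct_target", "ct_reference"]
    )
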