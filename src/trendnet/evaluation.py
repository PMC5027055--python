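"""Self-calibration experiments on synthetic studies.

Each function simulates studies at the generator's stated conditions,
runs the relevant pipeline stage, and measures how well the planted
structure is recovered (or, on null data, how often the stage fires
falsely).  These are the quantitative checks behind the test suite and
the reproduction script.
"""
from __future__ import annotations

import numpy as np

from .diffexpr import DifferentialExpressionCaller
from .enrichment import enrich
from .network import timecourse_correlation
from .qpcr import quantify_all
from .simulate import SimulationConfig, generate_ct_table, generate_gene_sets, generate_timecourse
from .stc import assign_profiles, enumerate_profiles, profile_significance

__all__ = [
    "stc_null_positive_rate",
    "stc_recovery",
    "de_calibration",
    "network_pair_recall",
    "enrichment_power",
    "qpcr_fold_recovery",
]


def _seeds(base: int, n: int) -> list[int]:
    return [int(s) for s in ((base * 100_003 + np.arange(n)) % (2**31 - 1))]


def stc_null_positive_rate(
    n_seeds: int = 100,
    n_genes: int = 1000,
    n_permutations: int = 1000,
    base_seed: int = 0,
) -> float:
    """Mean fraction of profiles reaching adj_p < 0.05 on fully null data
    (no planted trends): the type-I behaviour of the trend test."""
    profiles = enumerate_profiles(5)
    fracs = []
    for seed in _seeds(base_seed, n_seeds):
        cfg = SimulationConfig(
            n_lncrna=n_genes // 5,
            n_mrna=n_genes - n_genes // 5,
            frac_trended=0.0,
            n_planted_pairs=0,
            seed=seed,
        )
        m, _ = generate_timecourse(cfg)
        asn = assign_profiles(m, profiles)
        sig = profile_significance(asn, m, profiles, n_permutations, seed=seed)
        fracs.append(sig["significant"].mean())
    return float(np.mean(fracs))


def stc_recovery(
    n_seeds: int = 5,
    n_permutations: int = 300,
    trend_amplitude: float = 1.0,
    noise_sd: float = 0.2,
    base_seed: int = 0,
) -> dict:
    """Fraction of planted genes assigned their true profile, and the
    fraction of planted profiles flagged significant."""
    profiles = enumerate_profiles(5)
    recoveries, planted_sig = [], []
    for seed in _seeds(base_seed, n_seeds):
        cfg = SimulationConfig(seed=seed, trend_amplitude=trend_amplitude, noise_sd=noise_sd)
        m, truth = generate_timecourse(cfg)
        asn = assign_profiles(m, profiles)
        correct = [
            asn.table.loc[g, "profile_id"] == truth.true_profile[g]
            for g in truth.trended_genes
            if g in asn.table.index
        ]
        recoveries.append(np.mean(correct))
        sig = profile_significance(asn, m, profiles, n_permutations, seed=seed)
        planted = sorted({p for p in truth.true_profile.values() if p is not None})
        flagged = sig.set_index("profile_id").loc[planted, "significant"]
        planted_sig.append(float(flagged.mean()))
    return {
        "recovery": float(np.mean(recoveries)),
        "planted_profiles_significant": float(np.mean(planted_sig)),
        "n_seeds": n_seeds,
    }


def de_calibration(
    n_seeds: int = 10,
    trend_amplitude: float = 2.0,
    noise_sd: float = 0.2,
    base_seed: int = 0,
) -> dict:
    """Sensitivity on planted trended genes (true |log2FC| >= amplitude at
    some time point) and the false-call rate on null genes, at the
    FC >= 2 / FDR <= 0.05 rule."""
    sens, fpr = [], []
    for seed in _seeds(base_seed, n_seeds):
        cfg = SimulationConfig(seed=seed, trend_amplitude=trend_amplitude, noise_sd=noise_sd)
        m, truth = generate_timecourse(cfg)
        de = DifferentialExpressionCaller().fit(m)
        trended = set(truth.trended_genes)
        union = set(de.union_)
        nulls = set(m.gene_ids) - trended
        sens.append(len(union & trended) / len(trended))
        fpr.append(len(union & nulls) / len(nulls))
    return {
        "sensitivity": float(np.mean(sens)),
        "false_call_rate": float(np.mean(fpr)),
        "n_seeds": n_seeds,
    }


def network_pair_recall(
    noise_sd: float,
    n_seeds: int = 10,
    threshold: float = 0.997,
    base_seed: int = 0,
) -> float:
    """Fraction of planted coexpressed LncRNA–mRNA pairs whose time-mean
    |Pearson r| clears the edge threshold."""
    recalls = []
    for seed in _seeds(base_seed, n_seeds):
        cfg = SimulationConfig(seed=seed, noise_sd=noise_sd)
        m, truth = generate_timecourse(cfg)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # zero-noise nulls are flat
            r = timecourse_correlation(m)
        hits = sum(
            a in r.index and b in r.index and abs(r.loc[a, b]) >= threshold
            for a, b in truth.planted_pairs
        )
        recalls.append(hits / len(truth.planted_pairs))
    return float(np.mean(recalls))


def enrichment_power(
    n_seeds: int = 5,
    odds: float = 8.0,
    base_seed: int = 0,
) -> dict:
    """How often every planted term ranks in the top 5 by Fisher p and
    clears the p < 1e-4 gate, with the trended genes as the DE list."""
    top5_ok, gate_ok = [], []
    for seed in _seeds(base_seed, n_seeds):
        cfg = SimulationConfig(seed=seed, n_terms=50, planted_term_enrichment=odds)
        _, truth = generate_timecourse(cfg)
        coll = generate_gene_sets(cfg, truth)
        res = enrich(truth.trended_genes, coll, p_threshold=1e-4)
        top5 = set(res["term_id"].head(5))
        enriched = set(res.loc[res["enriched"], "term_id"])
        top5_ok.append(set(truth.planted_terms) <= top5)
        gate_ok.append(set(truth.planted_terms) <= enriched)
    return {
        "planted_in_top5": float(np.mean(top5_ok)),
        "planted_pass_gate": float(np.mean(gate_ok)),
        "n_seeds": n_seeds,
    }


def qpcr_fold_recovery(
    n_seeds: int = 20,
    true_fold: float = 2.0,
    noise_sd: float = 0.1,
    base_seed: int = 0,
) -> dict:
    """Recovered 2^-ddCt fold for a planted fold, over seeds."""
    folds = []
    for seed in _seeds(base_seed, n_seeds):
        ct = generate_ct_table(
            1, [0, 7], 3, {("QG001", 7): true_fold}, seed=seed, noise_sd=noise_sd
        )
        folds.append(quantify_all(ct).set_index("time_day").loc[7, "fold"])
    folds = np.array(folds)
    return {
        "median_fold": float(np.median(folds)),
        "within_band": float(np.mean((folds >= 1.6) & (folds <= 2.5))),
        "n_seeds": n_seeds,
    }
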