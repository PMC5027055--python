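"""Differential calling vs day 0, union sets, heat-map ordering."""
import itertools

import numpy as np
import pandas as pd
import pytest

from trendnet.diffexpr import (
    DifferentialExpressionCaller,
    call_differential,
    hierarchical_order,
    log2_fold_change,
    union_set,
)
from trendnet.matrix import ExpressionMatrix

from conftest import make_matrix


class TestLog2FoldChange:
    def test_identical_values_give_zero(self):
        m = make_matrix({"g1": [6, 6, 6, 6, 6]})
        assert log2_fold_change(m, 7)["g1"] == pytest.approx(0.0, abs=1e-12)

    def test_difference_of_means(self):
        m = make_matrix({"g1": [6, 6, 6, 8, 6]})
        assert log2_fold_change(m, 7)["g1"] == pytest.approx(2.0, abs=1e-12)

    def test_antisymmetry_under_time_swap(self):
        m1 = make_matrix({"g1": [5, 0, 0, 9, 0]})
        m2 = make_matrix({"g1": [9, 0, 0, 5, 0]})
        assert log2_fold_change(m1, 7)["g1"] == pytest.approx(
            -log2_fold_change(m2, 7)["g1"], abs=1e-12
        )

    def test_missing_time_point_names_available(self):
        m = make_matrix({"g1": [6, 6, 6, 6, 6]})
        with pytest.raises(KeyError, match="available"):
            log2_fold_change(m, 5)


class TestCallDifferential:
    def test_boundary_fold_change_inclusive(self):
        # noiseless shift of exactly 1 log2 unit: q = 0, log2FC = 1.0 -> up
        m = make_matrix({"g1": [6, 6, 6, 7, 6], "g2": [6, 6, 6, 6.9, 6]})
        calls = call_differential(m, 7)
        assert calls.loc["g1", "call"] == "up"
        assert calls.loc["g2", "call"] == "unchanged"  # fails the FC rule

    def test_large_fc_but_poor_fdr_is_unchanged(self):
        rng = np.random.default_rng(0)
        genes = {f"n{i}": [8.0] * 5 for i in range(20)}
        m = make_matrix(genes, noise_sd=0.05, seed=1)
        # one gene with a big but extremely noisy shift at day 7
        vals = m.values.copy()
        vals.loc["n0", ["d7_r1", "d7_r2", "d7_r3"]] = [8 + 2.5 - 3.0, 8 + 2.5, 8 + 2.5 + 3.0]
        m2 = ExpressionMatrix(vals, m.biotype)
        calls = call_differential(m2, 7)
        assert calls.loc["n0", "log2fc"] > 1.0
        assert calls.loc["n0", "q"] > 0.05
        assert calls.loc["n0", "call"] == "unchanged"

    def test_down_calls_are_symmetric(self):
        m = make_matrix({"g1": [8, 8, 8, 6, 8], "g2": [8, 8, 8, 10, 8]})
        calls = call_differential(m, 7)
        assert calls.loc["g1", "call"] == "down"
        assert calls.loc["g2", "call"] == "up"

    def test_monotone_in_thresholds(self, flat_noise_matrix):
        vals = flat_noise_matrix.values.copy()
        rng = np.random.default_rng(5)
        vals.iloc[:10, 9:12] += rng.uniform(0.5, 2.5, (10, 3))  # day-7 shifts
        m = ExpressionMatrix(vals, flat_noise_matrix.biotype)
        strict = call_differential(m, 7, fc_threshold=2.0, fdr_threshold=0.05)
        loose = call_differential(m, 7, fc_threshold=1.3, fdr_threshold=0.2)
        called_strict = set(strict.index[strict["call"] != "unchanged"])
        called_loose = set(loose.index[loose["call"] != "unchanged"])
        assert called_strict <= called_loose

    def test_pooled_matrix_requires_fc_only(self):
        m = make_matrix({"g1": [6, 6, 6, 8, 6]}, replicates=1)
        with pytest.raises(ValueError, match="fc_only"):
            call_differential(m, 7)
        calls = call_differential(m, 7, fc_only=True)
        assert calls.loc["g1", "call"] == "up"
        assert np.isnan(calls.loc["g1", "p"])


class TestUnionSet:
    def _result(self, universe, called):
        return pd.DataFrame(
            {
                "log2fc": 0.0,
                "p": 1.0,
                "q": 1.0,
                "call": ["up" if g in called else "unchanged" for g in universe],
            },
            index=pd.Index(universe),
        )

    def test_set_union(self):
        u = ["a", "b", "c", "d"]
        res = union_set([self._result(u, {"a", "b"}), self._result(u, {"b", "c"})])
        assert set(res) == {"a", "b", "c"}

    def test_empty_union(self):
        u = ["a", "b"]
        assert len(union_set([self._result(u, set())])) == 0

    def test_superset_of_each_time_point(self):
        u = [f"g{i}" for i in range(10)]
        parts = [self._result(u, {"g1", "g2"}), self._result(u, {"g5"})]
        res = set(union_set(parts))
        for part, called in zip(parts, [{"g1", "g2"}, {"g5"}]):
            assert called <= res

    def test_mismatched_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            union_set([self._result(["a"], set()), self._result(["b"], set())])


def average_linkage_oracle(dist):
    """O(n^3) agglomeration: cluster distance = mean pairwise original
    distance; returns sorted merge heights."""
    n = dist.shape[0]
    clusters = {i: [i] for i in range(n)}
    heights = []
    while len(clusters) > 1:
        best = None
        for i, j in itertools.combinations(sorted(clusters), 2):
            d = np.mean([dist[a, b] for a in clusters[i] for b in clusters[j]])
            if best is None or d < best[0]:
                best = (d, i, j)
        d, i, j = best
        heights.append(d)
        clusters[i] = clusters[i] + clusters.pop(j)
    return sorted(heights)


class TestHierarchicalOrder:
    def test_identical_profiles_adjacent(self):
        m = make_matrix(
            {
                "a": [1, 2, 3, 4, 5],
                "b": [5, 4, 3, 2, 1],
                "a2": [2, 3, 4, 5, 6],  # perfectly correlated with a
            }
        )
        order = hierarchical_order(m, ["a", "b", "a2"])
        assert abs(order.index("a") - order.index("a2")) == 1

    def test_output_is_permutation_of_input(self, flat_noise_matrix):
        genes = list(flat_noise_matrix.gene_ids[:12])
        order = hierarchical_order(flat_noise_matrix, genes)
        assert sorted(order) == sorted(genes)

    def test_fewer_than_two_genes_returns_input(self, flat_noise_matrix):
        assert hierarchical_order(flat_noise_matrix, ["G001"]) == ["G001"]

    def test_merge_heights_match_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        genes = {f"g{i}": rng.normal(8, 1, 5) for i in range(10)}
        m = make_matrix(genes)
        tm = m.time_means().to_numpy()
        corr = np.corrcoef(tm)
        dist = 1 - corr
        from scipy.cluster.hierarchy import linkage
        from scipy.spatial.distance import squareform

        z = linkage(squareform(dist, checks=False), method="average")
        np.testing.assert_allclose(
            sorted(z[:, 2]), average_linkage_oracle(dist), atol=1e-9
        )
        # and the public function runs on the same genes deterministically
        assert hierarchical_order(m, list(genes)) == hierarchical_order(m, list(genes))


class TestCallerEstimator:
    def test_fit_populates_union_and_table(self):
        m = make_matrix(
            {"up7": [6, 6, 6, 8, 6], "down3": [8, 8, 6, 8, 8], "null": [7, 7, 7, 7, 7]},
            biotypes=["LncRNA", "mRNA", "mRNA"],
        )
        de = DifferentialExpressionCaller().fit(m)
        assert set(de.union_) == {"up7", "down3"}
        assert de.table_.loc["up7", "call_d7"] == "up"
        assert de.table_.loc["down3", "call_d3"] == "down"
        assert sorted(de.results_) == [1, 3, 7, 21]

    def test_get_params_roundtrip(self):
        de = DifferentialExpressionCaller(fc_threshold=1.5)
        assert DifferentialExpressionCaller(**de.get_params()).fc_threshold == 1.5
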