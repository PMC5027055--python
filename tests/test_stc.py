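"""Trend-profile enumeration, assignment and permutation/binomial null."""
import itertools

import numpy as np
import pandas as pd
import pytest

from trendnet.stc import (
    TrendProfileClusterer,
    assign_profiles,
    discretize_gene,
    enumerate_profiles,
    profile_significance,
)

from conftest import make_matrix


class TestEnumerateProfiles:
    @pytest.mark.parametrize(
        "t, c, exclude_flat, expected",
        [
            (5, 1, True, 80),  # 3^4 - 1: the classic catalogue
            (2, 1, True, 2),
            (3, 2, False, 25),
        ],
    )
    def test_counts(self, t, c, exclude_flat, expected):
        assert len(enumerate_profiles(t, c, exclude_flat)) == expected

    @pytest.mark.parametrize("t", [2, 3, 4, 5])
    @pytest.mark.parametrize("c", [1, 2])
    def test_matches_cartesian_enumeration(self, t, c):
        profs = enumerate_profiles(t, c, exclude_flat=True)
        brute = [
            s
            for s in itertools.product(range(-c, c + 1), repeat=t - 1)
            if any(x != 0 for x in s)
        ]
        assert [p.steps for p in profs] == brute
        assert [p.profile_id for p in profs] == list(range(len(brute)))

    def test_values_are_cumulative_and_anchored(self):
        for p in enumerate_profiles(5, 1):
            assert p.values[0] == 0
            assert all(
                p.values[t] - p.values[t - 1] == p.steps[t - 1]
                for t in range(1, len(p.values))
            )

    def test_rejects_degenerate_inputs(self):
        with pytest.raises(ValueError):
            enumerate_profiles(1)
        with pytest.raises(ValueError):
            enumerate_profiles(5, 0)


class TestDiscretize:
    def test_flat_and_ramp(self):
        np.testing.assert_array_equal(discretize_gene([5, 5, 5, 5, 5]), np.zeros(5))
        np.testing.assert_array_equal(discretize_gene([6, 7, 8, 9, 10]), [0, 1, 2, 3, 4])

    def test_shift_invariance(self):
        v = np.array([3.2, 1.1, 4.8, 2.0, 2.0])
        np.testing.assert_allclose(discretize_gene(v + 7.5), discretize_gene(v))

    def test_rejects_nonfinite(self):
        with pytest.raises(ValueError):
            discretize_gene([1.0, np.nan, 2.0, 3.0, 4.0])


class TestAssignProfiles:
    def test_exact_profile_match_scores_one(self, profiles5):
        p = profiles5[37]
        m = make_matrix({"g1": 8.0 + np.array(p.values, float)})
        asn = assign_profiles(m, profiles5)
        assert asn.table.loc["g1", "profile_id"] == 37
        assert asn.table.loc["g1", "score"] == pytest.approx(1.0, abs=1e-12)

    def test_mirrored_trend_goes_to_mirrored_profile(self, profiles5):
        p = profiles5[37]
        mirrored_steps = tuple(-s for s in p.steps)
        mirror_id = next(q.profile_id for q in profiles5 if q.steps == mirrored_steps)
        m = make_matrix({"g1": 8.0 - np.array(p.values, float)})
        asn = assign_profiles(m, profiles5)
        assert asn.table.loc["g1", "profile_id"] == mirror_id
        assert asn.table.loc["g1", "score"] == pytest.approx(1.0, abs=1e-12)

    def test_flat_gene_is_unassignable(self, profiles5):
        m = make_matrix({"flat": [8, 8, 8, 8, 8], "up": [6, 7, 8, 9, 10]})
        asn = assign_profiles(m, profiles5)
        assert asn.unassignable == ["flat"]
        assert list(asn.table.index) == ["up"]

    def test_row_permutation_equivariance(self, profiles5):
        rng = np.random.default_rng(2)
        genes = {f"g{i}": rng.normal(8, 1, 5) for i in range(30)}
        m = make_matrix(genes)
        asn = assign_profiles(m, profiles5)
        shuffled = list(genes)[::-1]
        asn2 = assign_profiles(m.restrict(shuffled), profiles5)
        pd.testing.assert_frame_equal(
            asn.table.sort_index(), asn2.table.sort_index()
        )

    def test_euclidean_metric_recovers_exact_match(self, profiles5):
        p = profiles5[10]
        m = make_matrix({"g1": 5.0 + np.array(p.values, float)})
        asn = assign_profiles(m, profiles5, metric="euclidean")
        assert asn.table.loc["g1", "profile_id"] == 10

    def test_empty_profiles_rejected(self):
        m = make_matrix({"g1": [6, 7, 8, 9, 10]})
        with pytest.raises(ValueError):
            assign_profiles(m, [])


class TestProfileSignificance:
    def test_expected_counts_conserve_total(self, profiles5, flat_noise_matrix):
        asn = assign_profiles(flat_noise_matrix, profiles5)
        sig = profile_significance(asn, flat_noise_matrix, profiles5, 100, seed=0)
        assert sig["genes_expected"].sum() == pytest.approx(asn.n_assignable, abs=1e-9)
        assert sig["genes_assigned"].sum() == asn.n_assignable

    def test_reproducible_with_fixed_seed(self, profiles5, flat_noise_matrix):
        asn = assign_profiles(flat_noise_matrix, profiles5)
        a = profile_significance(asn, flat_noise_matrix, profiles5, 100, seed=5)
        b = profile_significance(asn, flat_noise_matrix, profiles5, 100, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_planted_profile_reaches_significance(self, profiles5):
        rng = np.random.default_rng(8)
        target = profiles5[14]
        genes = {}
        for i in range(60):  # planted cluster
            genes[f"p{i}"] = 8.0 + np.array(target.values, float) + rng.normal(0, 0.1, 5)
        for i in range(140):  # background noise
            genes[f"n{i}"] = 8.0 + rng.normal(0, 0.3, 5)
        m = make_matrix(genes, replicates=1, days=(0, 1, 3, 7, 21))
        asn = assign_profiles(m, profiles5)
        sig = profile_significance(asn, m, profiles5, 150, seed=1).set_index("profile_id")
        assert sig.loc[14, "adj_p"] < 1e-6
        assert bool(sig.loc[14, "significant"])

    def test_requires_minimum_permutations(self, profiles5, flat_noise_matrix):
        asn = assign_profiles(flat_noise_matrix, profiles5)
        with pytest.raises(ValueError, match="100"):
            profile_significance(asn, flat_noise_matrix, profiles5, 50, seed=0)

    def test_zero_assignable_genes_warns_and_returns_empty(self, profiles5):
        m = make_matrix({"flat1": [8] * 5, "flat2": [3] * 5})
        asn = assign_profiles(m, profiles5)
        with pytest.warns(UserWarning):
            sig = profile_significance(asn, m, profiles5, 100, seed=0)
        assert sig.empty


class TestClustererEstimator:
    def test_fit_populates_attributes(self, flat_noise_matrix):
        clus = TrendProfileClusterer(n_permutations=100, random_state=0).fit(
            flat_noise_matrix
        )
        assert len(clus.profiles_) == 80
        assert len(clus.labels_) == clus.assignment_.n_assignable
        assert set(clus.significance_.columns) >= {"genes_assigned", "adj_p", "significant"}

    def test_predict_matches_fit_labels(self, flat_noise_matrix):
        clus = TrendProfileClusterer(n_permutations=100, random_state=0).fit(
            flat_noise_matrix
        )
        np.testing.assert_array_equal(clus.predict(flat_noise_matrix), clus.labels_)

    def test_sklearn_params_roundtrip(self):
        clus = TrendProfileClusterer(max_unit_change=2, n_permutations=300)
        clone = TrendProfileClusterer(**clus.get_params())
        assert clone.max_unit_change == 2 and clone.n_permutations == 300
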