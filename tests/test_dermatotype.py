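import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import jensenshannon, pdist, squareform
from sklearn.metrics import adjusted_rand_score, calinski_harabasz_score

import dermengraft as dg
from dermengraft.dermatotype import (
    ch_index,
    jsd_distance,
    jsd_matrix,
    pam,
    pcoa,
    select_dermatotypes,
    silhouette,
)


def brute_force_pam_objective(d, k):
    n = d.shape[0]
    return min(d[:, m].min(axis=1).sum() for m in itertools.combinations(range(n), k))


class TestJSD:
    def test_identity_of_indiscernibles(self):
        assert jsd_distance([40.0, 60.0], [40.0, 60.0]) == 0.0

    def test_disjoint_supports_hit_one(self):
        assert jsd_distance([100.0, 0.0], [0.0, 100.0]) == pytest.approx(1.0)

    def test_closed_form_spot_value(self):
        # sqrt(1 - H2(0.75)) in bits; agrees with scipy's jensenshannon
        assert jsd_distance([75, 25], [25, 75]) == pytest.approx(0.4344213111, abs=1e-9)

    def test_agrees_with_scipy(self, rng):
        for _ in range(50):
            p, q = rng.dirichlet(np.ones(6)) * 100, rng.dirichlet(np.ones(6)) * 100
            assert jsd_distance(p, q) == pytest.approx(
                jensenshannon(p, q, base=2), abs=1e-12)

    def test_metric_properties_on_random_triples(self, rng):
        for _ in range(200):
            p, q, r = (rng.dirichlet(np.full(5, 0.6)) for _ in range(3))
            dpq, dqr, dpr = jsd_distance(p, q), jsd_distance(q, r), jsd_distance(p, r)
            assert dpq == pytest.approx(jsd_distance(q, p), abs=1e-12)
            assert dpr <= dpq + dqr + 1e-10
            assert 0.0 <= dpq <= 1.0

    def test_mismatched_taxa_raise(self):
        p = pd.Series([50.0, 50.0], index=["A", "B"])
        q = pd.Series([50.0, 50.0], index=["A", "C"])
        with pytest.raises(ValueError, match="mismatched"):
            jsd_distance(p, q)

    def test_matrix_matches_pairwise_scalar(self, rng):
        P = pd.DataFrame(rng.dirichlet(np.ones(5), size=12) * 100)
        D = jsd_matrix(P)
        for i, j in [(0, 1), (3, 7), (10, 11)]:
            assert D.iloc[i, j] == pytest.approx(
                jsd_distance(P.iloc[i], P.iloc[j]), abs=1e-10)
        assert np.allclose(D, D.T) and np.allclose(np.diag(D), 0)


class TestPAM:
    def test_two_point_clouds_split_perfectly(self):
        d = np.ones((8, 8))
        d[:4, :4] = 0.0
        d[4:, 4:] = 0.0
        np.fill_diagonal(d, 0.0)
        labels, medoids, obj = pam(d, 2)
        assert obj == 0.0
        assert len(set(labels[:4])) == 1 and len(set(labels[4:])) == 1
        assert labels[0] != labels[4]

    def test_matches_exhaustive_enumeration_small(self, rng):
        for _ in range(60):
            n = int(rng.integers(4, 9))
            k = int(rng.integers(2, n))
            x = rng.random((n, 2))
            d = squareform(pdist(x))
            _, _, obj = pam(d, k)
            assert obj == pytest.approx(brute_force_pam_objective(d, k), abs=1e-9)

    def test_heuristic_path_never_beats_and_nearly_matches_optimum(self, rng):
        # force BUILD+SWAP by disabling the exact-enumeration shortcut
        for _ in range(30):
            n = int(rng.integers(6, 9))
            k = int(rng.integers(2, 4))
            d = squareform(pdist(rng.random((n, 2))))
            _, _, obj = pam(d, k, exact_limit=0)
            best = brute_force_pam_objective(d, k)
            assert obj >= best - 1e-9
            assert obj <= best * 1.15 + 1e-9

    def test_k_bounds_enforced(self):
        d = squareform(pdist(np.random.default_rng(0).random((5, 2))))
        for bad_k in (1, 5, 6):
            with pytest.raises(ValueError):
                pam(d, bad_k)

    def test_deterministic(self, rng):
        d = squareform(pdist(rng.random((30, 2))))
        a = pam(d, 3, exact_limit=0)
        b = pam(d, 3, exact_limit=0)
        assert np.array_equal(a[0], b[0]) and a[2] == b[2]


class TestCH:
    def test_hand_computed_toy(self):
        X = np.array([[0, 0], [1, 0], [0, 1], [5, 5], [6, 5], [5, 6]], dtype=float)
        d = squareform(pdist(X))
        labels = [0, 0, 0, 1, 1, 1]
        # W = 8/3, B = 75  ->  CH = (75/1) / ((8/3)/4) = 112.5
        assert ch_index(d, labels) == pytest.approx(112.5, rel=1e-9)
        assert ch_index(d, labels) == pytest.approx(
            calinski_harabasz_score(X, labels), rel=1e-9)

    def test_w_zero_sentinel(self):
        d = np.zeros((6, 6))
        assert ch_index(d, [0, 0, 0, 1, 1, 1]) == np.inf

    def test_true_split_beats_wrong_k_on_blobs(self, rng):
        a = rng.normal(0.0, 0.01, size=(15, 2))
        b = rng.normal(1.0, 0.01, size=(15, 2))
        X = np.vstack([a, b])
        d = squareform(pdist(X))
        true = [0] * 15 + [1] * 15
        labels3, _, _ = pam(d, 3)
        assert ch_index(d, true) > ch_index(d, labels3)


class TestSilhouette:
    def test_ideal_separation(self):
        d = np.ones((6, 6))
        d[:3, :3] = 0.0
        d[3:, 3:] = 0.0
        np.fill_diagonal(d, 0.0)
        widths, mean = silhouette(d, [0, 0, 0, 1, 1, 1])
        np.testing.assert_allclose(widths, 1.0)
        assert mean == 1.0

    def test_hand_computed_four_points(self):
        d = np.array([
            [0, 1, 4, 5],
            [1, 0, 3, 6],
            [4, 3, 0, 2],
            [5, 6, 2, 0],
        ], dtype=float)
        widths, mean = silhouette(d, [0, 0, 1, 1])
        expected = [3.5 / 4.5, 3.5 / 4.5, 1.5 / 3.5, 3.5 / 5.5]
        np.testing.assert_allclose(widths, expected, atol=1e-12)
        assert mean == pytest.approx(np.mean(expected))

    def test_needs_two_clusters(self):
        with pytest.raises(ValueError):
            silhouette(np.zeros((3, 3)), [0, 0, 0])


class TestPCoA:
    def test_collinear_points_one_axis(self):
        x = np.array([[0.0], [1.0], [2.5], [4.0]])
        res = pcoa(squareform(pdist(x)))
        assert res.explained_fraction[0] == pytest.approx(1.0)

    def test_round_trip_of_euclidean_configuration(self, rng):
        X = rng.random((15, 2))
        d = squareform(pdist(X))
        res = pcoa(d)
        d2 = squareform(pdist(res.coordinates.to_numpy()))
        assert np.abs(d2 - d).max() < 1e-8

    def test_sqrt_jsd_distances_reproduced(self, rng):
        P = pd.DataFrame(rng.dirichlet(np.ones(6), size=18) * 100)
        d = jsd_matrix(P)
        res = pcoa(d)
        if res.negative_eigenvalue_magnitude < 1e-9:
            d2 = squareform(pdist(res.coordinates.to_numpy()))
            assert np.abs(d2 - d.to_numpy()).max() < 1e-6

    def test_axes_ordered_by_explained_fraction(self, rng):
        d = squareform(pdist(rng.random((12, 4))))
        res = pcoa(d)
        assert (np.diff(res.explained_fraction) <= 1e-12).all()


class TestSelectDermatotypes:
    def test_recovers_five_slst_archetypes(self, archetypes):
        abund, labels = dg.sample_archetype_profiles(archetypes.slst, 30, seed=11)
        res = select_dermatotypes(abund)
        assert res.k_selected == 5
        assert adjusted_rand_score(labels, res.labels) >= 0.9
        assert res.k_selected == max(res.ch_by_k, key=lambda k: (res.ch_by_k[k], -k))

    def test_recovers_three_genus_archetypes(self, archetypes):
        abund, labels = dg.sample_archetype_profiles(archetypes.genus, 30, seed=11)
        res = select_dermatotypes(abund)
        assert res.k_selected == 3
        assert adjusted_rand_score(labels, res.labels) >= 0.9

    def test_permutation_invariant_up_to_relabeling(self, archetypes, rng):
        abund, _ = dg.sample_archetype_profiles(archetypes.genus, 15, seed=2)
        res = select_dermatotypes(abund)
        perm = rng.permutation(len(abund))
        res2 = select_dermatotypes(abund.iloc[perm])
        joined = pd.concat([res.labels.rename("a"), res2.labels.rename("b")], axis=1)
        assert adjusted_rand_score(joined["a"], joined["b"]) == pytest.approx(1.0)

    def test_identical_profiles_degenerate(self):
        abund = pd.DataFrame([[60.0, 40.0]] * 10,
                             index=[f"s{i}" for i in range(10)], columns=["A", "B"])
        with pytest.raises(ValueError, match="identical"):
            select_dermatotypes(abund)

    def test_clusters_numbered_by_decreasing_size(self, archetypes):
        abund, _ = dg.sample_archetype_profiles(archetypes.genus, 20, seed=5)
        res = select_dermatotypes(abund)
        sizes = res.labels.value_counts().sort_index()
        assert (sizes.diff().dropna() <= 0).all()
        # medoids carry their own cluster's label
        for dt, mid in enumerate(res.medoid_ids, start=1):
            assert res.labels[mid] == dt
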