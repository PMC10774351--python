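"""Outlier handling, paired-t maps, cluster formation and permutation null."""

import numpy as np
import pytest
from scipy import stats

from mindseye.cluster import (
    AdjacencySpec,
    ClusterPermutationTest,
    cluster_permutation_test,
    condition_mean_psd,
    form_clusters,
    outlier_interpolate,
    paired_t_map,
    rating_correlation,
)
from mindseye.montage import delaunay_adjacency, standard_montage

from oracles import flood_fill_components, paired_t_formula, signflip_null_enumeration


def ring_adjacency(n):
    adj = np.zeros((n, n), bool)
    for i in range(n):
        adj[i, (i + 1) % n] = adj[(i + 1) % n, i] = True
    return adj


class TestAdjacency:
    def test_delaunay_is_symmetric_and_irreflexive(self):
        adj = delaunay_adjacency(standard_montage(32))
        assert (adj == adj.T).all()
        assert not adj.diagonal().any()
        assert adj.any(axis=1).all()  # nobody is isolated

    def test_asymmetric_matrix_rejected(self):
        bad = np.zeros((3, 3), bool)
        bad[0, 1] = True
        with pytest.raises(ValueError, match="symmetric"):
            AdjacencySpec(sensor=bad)

    def test_self_adjacency_rejected(self):
        with pytest.raises(ValueError, match="diagonal"):
            AdjacencySpec(sensor=np.eye(3, dtype=bool))


class TestOutlierInterpolation:
    def test_clean_data_unchanged(self, rng):
        x = rng.normal(size=(12, 4, 6))
        adj = AdjacencySpec(ring_adjacency(4))
        np.testing.assert_array_equal(outlier_interpolate(x, adj), x)

    def test_planted_outlier_replaced_by_neighbour_mean(self, rng):
        x = rng.normal(size=(12, 4, 6))
        adj = AdjacencySpec(ring_adjacency(4))
        mu, sd = x[:, 2, 3].mean(), x[:, 2, 3].std(ddof=1)
        x[5, 2, 3] = mu + 10 * sd
        out = outlier_interpolate(x, adj)
        # ring neighbours of sensor 2 are sensors 1 and 3, same freq
        assert out[5, 2, 3] == pytest.approx((x[5, 1, 3] + x[5, 3, 3]) / 2)
        untouched = np.ones_like(x, bool)
        untouched[5, 2, 3] = False
        np.testing.assert_array_equal(out[untouched], x[untouched])

    def test_outlier_with_no_finite_neighbours_becomes_nan(self, rng):
        x = rng.normal(size=(12, 4, 6))
        mu, sd = x[:, 2, 3].mean(), x[:, 2, 3].std(ddof=1)
        x[5, 2, 3] = mu + 12 * sd
        x[5, 1, 3] = x[5, 3, 3] = np.nan
        out = outlier_interpolate(x, AdjacencySpec(ring_adjacency(4)))
        assert np.isnan(out[5, 2, 3])


class TestPairedT:
    def test_identical_conditions_give_zero_t(self, rng):
        a = rng.normal(size=(8, 3, 4))
        t, p = paired_t_map(a, a.copy())
        np.testing.assert_allclose(t, 0.0)
        np.testing.assert_allclose(p, 1.0)

    def test_constant_difference_gives_infinite_t(self):
        a = np.zeros((5, 2, 2))
        t, p = paired_t_map(a + 1.0, a)
        assert np.isposinf(t).all()
        np.testing.assert_allclose(p, 0.0)

    def test_matches_textbook_formula(self, rng):
        a = rng.normal(size=(10, 3, 4))
        b = rng.normal(size=(10, 3, 4))
        t, p = paired_t_map(a, b)
        for s in range(3):
            for f in range(4):
                expected = paired_t_formula(a[:, s, f], b[:, s, f])
                assert t[s, f] == pytest.approx(expected)
                assert p[s, f] == pytest.approx(
                    2 * stats.t.sf(abs(expected), 9)
                )

    def test_nan_pairs_dropped_and_small_n_is_nan(self, rng):
        a = rng.normal(size=(5, 1, 2))
        b = rng.normal(size=(5, 1, 2))
        a[2:, 0, 0] = np.nan  # only 2 complete pairs left
        a[1:, 0, 1] = np.nan  # only 1 complete pair
        t, p = paired_t_map(a, b)
        assert np.isfinite(t[0, 0])
        assert t[0, 0] == pytest.approx(paired_t_formula(a[:2, 0, 0], b[:2, 0, 0]))
        assert np.isnan(t[0, 1]) and np.isnan(p[0, 1])


class TestClusterFormation:
    def test_empty_threshold_map_gives_no_clusters(self):
        adj = AdjacencySpec(ring_adjacency(4))
        assert form_clusters(np.zeros((4, 6), bool), np.zeros((4, 6)), adj) == []

    def test_frequency_neighbours_merge(self):
        adj = AdjacencySpec(ring_adjacency(4))
        t = np.zeros((4, 40))
        thr = np.zeros((4, 40), bool)
        t[1, 8] = t[1, 9] = 3.0  # same sensor, 9 and 10 Hz
        thr[1, 8] = thr[1, 9] = True
        clusters = form_clusters(thr, t, adj)
        assert len(clusters) == 1
        assert sorted(clusters[0].points) == [(1, 8), (1, 9)]
        assert clusters[0].mass == pytest.approx(6.0)
        assert clusters[0].freq_range == (9, 10)

    def test_signs_cluster_separately(self):
        adj = AdjacencySpec(ring_adjacency(3))
        t = np.array([[3.0, -3.0, 3.0]]).T.repeat(2, axis=1)
        thr = np.abs(t) > 2
        clusters = form_clusters(thr, t, adj)
        signs = sorted(c.sign for c in clusters)
        assert len(clusters) >= 2 and signs[0] == -1

    def test_matches_flood_fill_oracle(self, rng):
        sensor_adj = delaunay_adjacency(standard_montage(8))
        adj = AdjacencySpec(sensor_adj)
        t = rng.normal(size=(8, 40))
        thr = np.abs(t) > 1.2
        clusters = form_clusters(thr, t, adj)
        got = sorted(sorted(c.points) for c in clusters)
        expected = []
        for sign in (1, -1):
            mask = thr & ((t > 0) if sign > 0 else (t < 0))
            expected.extend(flood_fill_components(mask, sensor_adj))
        assert got == sorted(expected)
        # masses match the sum over members
        for c in clusters:
            assert c.mass == pytest.approx(sum(t[s, f] for s, f in c.points))


class TestPermutationTest:
    def test_exact_null_matches_enumeration_oracle(self, rng):
        sensor_adj = ring_adjacency(4)
        a = rng.normal(size=(3, 4, 6))
        b = rng.normal(size=(3, 4, 6))
        res = cluster_permutation_test(
            a, b, AdjacencySpec(sensor_adj), exact=True
        )
        oracle = signflip_null_enumeration(a - b, sensor_adj)
        np.testing.assert_allclose(np.sort(res.null_max_mass), np.sort(oracle))
        assert res.n_permutations == 8
        # p-values equal the enumeration proportion
        for c in res.clusters:
            assert c.p == pytest.approx(np.mean(oracle >= abs(c.mass)))

    def test_swapping_conditions_negates_masses_keeps_p(self, rng):
        a = rng.normal(size=(6, 4, 8))
        b = rng.normal(size=(6, 4, 8))
        adj = AdjacencySpec(ring_adjacency(4))
        r1 = cluster_permutation_test(a, b, adj, exact=True)
        r2 = cluster_permutation_test(b, a, adj, exact=True)
        np.testing.assert_allclose(r2.t_map, -r1.t_map, atol=1e-12)
        m1 = sorted(c.mass for c in r1.clusters)
        m2 = sorted(-c.mass for c in r2.clusters)
        np.testing.assert_allclose(m2, m1)
        p1 = sorted(c.p for c in r1.clusters)
        p2 = sorted(c.p for c in r2.clusters)
        np.testing.assert_allclose(p2, p1)

    def test_planted_effect_monotonicity(self, rng):
        adj = AdjacencySpec(ring_adjacency(4))
        b = rng.normal(size=(10, 4, 8))
        noise = rng.normal(size=(10, 4, 8))  # measurement noise on a
        masses = []
        for effect in (0.3, 2.0):
            a = b + noise + effect * (np.arange(8) < 3)  # boost freqs 1-3
            res = cluster_permutation_test(a, b, adj, n_permutations=50, rng=3)
            masses.append(max(abs(c.mass) for c in res.clusters))
        assert masses[1] > masses[0]


def test_condition_mean_psd_is_nan_aware(small_psd):
    means = condition_mean_psd(small_psd, "rest")
    assert means.shape == (6, 8, 40)
    i = 0
    sel = small_psd.conditions[i] == "rest"
    np.testing.assert_allclose(
        means[i], np.nanmean(small_psd.power[i, sel], axis=0)
    )


def test_model_wrapper_runs_outlier_path(small_psd):
    adj = AdjacencySpec.from_montage(standard_montage(8))
    res = ClusterPermutationTest(small_psd, "rest", "visual", adj).fit(
        n_permutations=30, rng=5
    )
    frame = res.to_frame()
    assert (frame["p"] > 0).all() and (frame["p"] <= 1).all()


class TestRatingCorrelation:
    def test_identical_vectors(self):
        r, p = rating_correlation([1, 2, 3, 4.0], [1, 2, 3, 4.0])
        assert r == pytest.approx(1.0)

    def test_exact_negatives(self):
        r, _ = rating_correlation([1, 2, 3, 4.0], [-1, -2, -3, -4.0])
        assert r == pytest.approx(-1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            rating_correlation([1, 1, 1.0], [1, 2, 3.0])
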