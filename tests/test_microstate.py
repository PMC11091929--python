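"""Tests for GFP, peak extraction, GEV and polarity-invariant k-means."""

import itertools

import numpy as np
import pytest

from oscistate.containers import SensorRecording
from oscistate.microstate import (
    find_gfp_peaks,
    gev,
    global_field_power,
    modified_kmeans,
    polarity_invariant_similarity,
    spatial_correlation,
)
from oscistate.synthetic import make_topographies


def principal_map(members: np.ndarray) -> np.ndarray:
    """Independent eigenvector-centroid used by the brute-force oracle."""
    w, v = np.linalg.eigh(members.T @ members)
    m = v[:, -1]
    return m * (np.sign(m[np.argmax(np.abs(m))]) or 1.0)


def brute_force_best_gev(X: np.ndarray, K: int) -> float:
    """Maximal GEV over all label assignments with eigenvector centroids."""
    n = X.shape[0]
    best = -np.inf
    for assign in itertools.product(range(K), repeat=n):
        labels = np.asarray(assign)
        if len(set(assign)) < K:
            continue
        maps = np.stack([principal_map(X[labels == k]) for k in range(K)])
        best = max(best, gev(maps, X, labels))
    return best


class TestGlobalFieldPower:
    def test_equal_channels_give_zero(self):
        rec = SensorRecording(np.ones((4, 10)), 250.0)
        assert np.all(global_field_power(rec).values == 0)

    def test_two_channel_closed_form(self):
        rec = SensorRecording(np.array([[1.0], [-1.0]]), 250.0)
        assert global_field_power(rec).values[0] == pytest.approx(1.0)

    def test_homogeneity_under_scaling(self):
        rng = np.random.default_rng(0)
        data = rng.standard_normal((6, 50))
        g1 = global_field_power(SensorRecording(data, 250.0)).values
        g2 = global_field_power(SensorRecording(-3.0 * data, 250.0)).values
        np.testing.assert_allclose(g2, 3.0 * g1)

    def test_single_channel_rejected(self):
        with pytest.raises(ValueError, match="2 channels"):
            global_field_power(SensorRecording(np.ones((1, 10)), 250.0))


class TestFindGfpPeaks:
    @pytest.mark.parametrize(
        "trace, expected",
        [
            ([0, 1, 0, 2, 0], [1, 3]),
            ([0, 1, 2, 3, 4], []),  # monotone: no interior maximum
            ([0, 1, 1, 0], []),  # plateau excluded under the strict rule
            ([5, 1, 2, 1, 5], [2]),  # endpoints never count
        ],
    )
    def test_strict_local_maxima(self, trace, expected):
        assert find_gfp_peaks(np.asarray(trace, float)).tolist() == expected

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError, match="length >= 3"):
            find_gfp_peaks(np.array([1.0, 2.0]))


class TestPolaritySimilarity:
    def test_polarity_invariance(self):
        m = np.array([1.0, 2.0, -1.0])
        assert polarity_invariant_similarity(m, m) == pytest.approx(1.0)
        assert polarity_invariant_similarity(m, -m) == pytest.approx(1.0)

    def test_orthogonal_vectors(self):
        assert polarity_invariant_similarity([1, 0], [0, 1]) == pytest.approx(0.0)

    def test_closed_form(self):
        got = polarity_invariant_similarity([1.0, 1.0, 0.0], [1.0, 0.0, 0.0])
        assert got == pytest.approx(1.0 / np.sqrt(2.0))

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError, match="zero vector"):
            polarity_invariant_similarity([0.0, 0.0], [1.0, 0.0])


class TestGev:
    def test_collinear_assignment_explains_everything(self):
        maps = make_topographies(8, 2, 0.0, seed=1)
        scale = np.array([2.0, 0.5, 1.0, 3.0])
        labels = np.array([0, 1, 0, 1])
        data = scale[:, None] * maps[labels] * np.array([1, -1, 1, -1])[:, None]
        assert gev(maps, data, labels) == pytest.approx(1.0, abs=1e-9)

    def test_two_channel_toy_value(self):
        # samples (2,0) and (0,1) on the map (1,0): with two channels every
        # spatial correlation is +-1, so the fit is perfect
        data = np.array([[2.0, 0.0], [0.0, 1.0]])
        maps = np.array([[1.0, 0.0]])
        assert gev(maps, data, np.zeros(2, int)) == pytest.approx(1.0)

    def test_three_channel_hand_computed_value(self):
        # hand evaluation of the GFP-weighted squared-correlation formula:
        # samples (1,2,3),(1,0,1), map (1,1,2)/sqrt(6), both labelled 0
        # -> GEV = (0.5 + 1/18) / (8/9) = 0.625
        data = np.array([[1.0, 2.0, 3.0], [1.0, 0.0, 1.0]])
        maps = np.array([[1.0, 1.0, 2.0]]) / np.sqrt(6.0)
        assert gev(maps, data, np.zeros(2, int)) == pytest.approx(0.625, abs=1e-12)

    def test_orthogonal_maps_explain_nothing(self):
        # demeaned-orthogonal map: correlation 0 for every sample
        data = np.array([[1.0, -1.0, 0.0], [2.0, -2.0, 0.0]])
        maps = np.array([[1.0, 1.0, -2.0]]) / np.sqrt(6.0)
        assert gev(maps, data, np.zeros(2, int)) == pytest.approx(0.0, abs=1e-12)

    def test_zero_data_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            gev(np.eye(2), np.zeros((3, 2)), np.zeros(3, int))


class TestModifiedKmeans:
    def _separable(self, seed=0, n_per=4, noise=0.0):
        rng = np.random.default_rng(seed)
        topo = make_topographies(12, 4, 0.0, seed=seed)
        labels = np.repeat(np.arange(4), n_per)
        signs = rng.choice([-1.0, 1.0], size=labels.size)
        amps = rng.uniform(0.5, 2.0, size=labels.size)
        X = signs[:, None] * amps[:, None] * topo[labels]
        if noise:
            X = X + noise * rng.standard_normal(X.shape)
        return X, topo, labels

    def test_recovers_separable_clusters(self):
        X, topo, labels = self._separable(seed=3)
        model = modified_kmeans(X, K=4, n_restarts=10, seed=0)
        assert model.gev == pytest.approx(1.0, abs=1e-6)
        # recovered maps match planted ones up to sign and permutation
        corr = np.abs(model.maps @ topo.T)
        assert np.allclose(np.sort(corr.max(axis=1)), 1.0, atol=1e-6)
        # labels consistent: same planted cluster -> same recovered label
        for k in range(4):
            assert len(set(model.peak_labels[labels == k])) == 1

    def test_matches_brute_force_on_small_instance(self):
        rng = np.random.default_rng(42)
        X = rng.standard_normal((8, 5))
        model = modified_kmeans(X, K=2, n_restarts=20, seed=1)
        assert model.gev == pytest.approx(brute_force_best_gev(X, 2), abs=1e-9)

    def test_polarity_invariance_exact(self):
        X, _, _ = self._separable(seed=5, noise=0.05)
        flip = np.ones(X.shape[0])
        flip[::3] = -1.0
        a = modified_kmeans(X, K=4, n_restarts=5, seed=2)
        b = modified_kmeans(flip[:, None] * X, K=4, n_restarts=5, seed=2)
        np.testing.assert_array_equal(a.peak_labels, b.peak_labels)
        assert a.gev == pytest.approx(b.gev, abs=1e-12)
        np.testing.assert_allclose(np.abs(a.maps), np.abs(b.maps), atol=1e-9)

    def test_chosen_restart_has_maximal_gev(self):
        X, _, _ = self._separable(seed=7, noise=0.3)
        model = modified_kmeans(X, K=4, n_restarts=8, seed=3)
        assert model.gev == pytest.approx(np.max(model.restart_gevs), abs=1e-12)
        assert model.restart_gevs.size == 8

    def test_gev_nondecreasing_in_k_with_warm_start(self):
        X, _, _ = self._separable(seed=9, noise=0.4)
        prev = modified_kmeans(X, K=2, n_restarts=6, seed=4)
        extra = X[np.argmin(np.max(np.abs(X @ prev.maps.T), axis=1))]
        init = np.vstack([prev.maps, extra / np.linalg.norm(extra)])
        nxt = modified_kmeans(X, K=3, n_restarts=6, seed=4, init_maps=init)
        assert nxt.gev >= prev.gev - 1e-9

    def test_sample_order_invariance_up_to_relabeling(self):
        X, _, labels = self._separable(seed=11)
        perm = np.random.default_rng(0).permutation(X.shape[0])
        a = modified_kmeans(X, K=4, n_restarts=10, seed=5)
        b = modified_kmeans(X[perm], K=4, n_restarts=10, seed=6)
        # the induced partitions agree after undoing the permutation
        pa = a.peak_labels
        pb_undone = np.empty_like(pa)
        pb_undone[perm] = b.peak_labels
        mapping = {}
        for x, y in zip(pa, pb_undone):
            assert mapping.setdefault(x, y) == y

    def test_k_larger_than_samples_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            modified_kmeans(np.eye(3), K=4)
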