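"""Ward HCA against a brute-force agglomeration oracle, plus map utilities."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from ramanpath.cluster import (
    DEFAULT_HCA_PALETTE,
    cluster_mean_spectra,
    hca,
    render_hca_map,
)
from ramanpath.core import HyperMap, SpectralAxis
from ramanpath.synthgen import RegionLayout, SyntheticTissueSpec, generate_tissue_map


def brute_force_ward(X):
    """O(n^3) greedy Ward agglomeration.

    At each step merges the pair of clusters with the smallest increase in
    within-cluster sum of squares; reported merge height is
    sqrt(2 * delta-ESS), the same scale scipy uses for Euclidean input.
    Returns a list of (frozenset_a, frozenset_b, height) merges.
    """
    X = np.asarray(X, dtype=float)
    clusters = [frozenset([i]) for i in range(len(X))]
    merges = []
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                ia, ib = sorted(clusters[a]), sorted(clusters[b])
                na, nb = len(ia), len(ib)
                mu_a, mu_b = X[ia].mean(axis=0), X[ib].mean(axis=0)
                cost = na * nb / (na + nb) * np.sum((mu_a - mu_b) ** 2)
                if best is None or cost < best[0]:
                    best = (cost, a, b)
        cost, a, b = best
        merges.append((clusters[a], clusters[b], np.sqrt(2.0 * cost)))
        merged = clusters[a] | clusters[b]
        clusters = [c for i, c in enumerate(clusters) if i not in (a, b)] + [merged]
    return merges


def linkage_to_merges(Z, n):
    """scipy linkage matrix -> list of (leafset_a, leafset_b, height)."""
    sets = {i: frozenset([i]) for i in range(n)}
    merges = []
    for row_idx, (a, b, h, _) in enumerate(Z):
        sa, sb = sets[int(a)], sets[int(b)]
        merges.append((sa, sb, h))
        sets[n + row_idx] = sa | sb
    return merges


def _map_from_matrix(X):
    X = np.asarray(X, dtype=float)
    if X.shape[1] == 1:
        # pad 1-D "spectra" with a zero channel; Euclidean geometry unchanged
        X = np.column_stack([X, np.zeros(len(X))])
    n, p = X.shape
    axis = SpectralAxis(np.linspace(600.0, 600.0 + 2.0 * (p - 1), p))
    return HyperMap(axis=axis, cube=X.reshape(n, 1, p))


class TestWardLinkage:
    def test_two_groups_of_identical_spectra(self):
        A, B = np.zeros(5), np.full(5, 3.0)
        X = np.vstack([A, A, A, B, B])
        res = hca(_map_from_matrix(X), k=2)
        labels = res.labels.ravel()
        assert len(set(labels[:3])) == 1
        assert len(set(labels[3:])) == 1
        assert labels[0] != labels[3]

    def test_k_equals_one_single_cluster(self, rng):
        X = rng.normal(0, 1, (10, 8))
        res = hca(_map_from_matrix(X), k=1)
        assert set(res.labels.ravel()) == {1}

    def test_one_dimensional_two_group_example(self):
        X = np.array([[0.0], [0.1], [0.2], [10.0], [10.1], [10.2]])
        res = hca(_map_from_matrix(X), k=2)
        labels = res.labels.ravel()
        assert len(set(labels[:3])) == 1 and len(set(labels[3:])) == 1
        oracle = brute_force_ward(X)
        ours = linkage_to_merges(res.linkage, len(X))
        for (oa, ob, oh), (ma, mb, mh) in zip(oracle, ours):
            assert {oa, ob} == {ma, mb}
            assert oh == pytest.approx(mh, rel=1e-10)

    def test_merge_heights_nondecreasing(self, rng):
        X = rng.normal(0, 1, (30, 12))
        res = hca(_map_from_matrix(X), k=3)
        heights = res.linkage[:, 2]
        assert np.all(np.diff(heights) >= -1e-12)

    def test_matches_brute_force_oracle_on_random_data(self, rng):
        for _ in range(5):
            n = int(rng.integers(5, 20))
            X = rng.normal(0, 1, (n, 6))
            oracle = brute_force_ward(X)
            res = hca(_map_from_matrix(X), k=1)
            ours = linkage_to_merges(res.linkage, n)
            for (oa, ob, oh), (ma, mb, mh) in zip(oracle, ours):
                assert {oa, ob} == {ma, mb}
                assert oh == pytest.approx(mh, rel=1e-8)

    def test_bad_k_and_empty_map_rejected(self, rng):
        m = _map_from_matrix(rng.normal(0, 1, (5, 4)))
        with pytest.raises(ValueError):
            hca(m, k=0)
        with pytest.raises(ValueError):
            hca(m, k=6)


class TestClusterMeans:
    def test_mean_of_identical_spectra_is_that_spectrum(self):
        X = np.tile(np.arange(6.0), (4, 1))
        m = _map_from_matrix(X)
        means = cluster_mean_spectra(m, np.ones((4, 1), dtype=int))
        assert np.allclose(means[1].intensities, X[0])

    def test_mean_of_two_constant_spectra(self):
        X = np.vstack([np.zeros(5), np.full(5, 2.0)])
        means = cluster_mean_spectra(_map_from_matrix(X), np.ones((2, 1), dtype=int))
        assert np.allclose(means[1].intensities, 1.0)

    def test_empty_cluster_warns(self):
        X = np.vstack([np.zeros(5), np.ones(5)])
        labels = np.array([[1], [3]])
        with pytest.warns(UserWarning):
            means = cluster_mean_spectra(_map_from_matrix(X), labels)
        assert set(means) == {1, 3}

    def test_nuclei_cluster_mean_shows_dna_bands(self, axis):
        layout = RegionLayout(
            fractions={"nucleus": 0.3, "cytoplasm": 0.7, "stroma": 0.0, "water": 0.0},
            water_background=0.0,
        )
        spec = SyntheticTissueSpec(
            map_width=14, map_height=14, class_name="cPDAC", layout=layout,
            baseline_coeffs=(0.0, 0.0, 0.0, 0.0), noise_sd=0.0, seed=0,
        )
        hmap = generate_tissue_map(spec)
        res = hca(hmap, k=2)
        wn = axis.wavenumbers
        dna = ((wn >= 1080) & (wn <= 1100)) | ((wn >= 1340) & (wn <= 1360))

        def dna_intensity(s):
            return s.intensities[dna].sum()

        scores = {c: dna_intensity(m) for c, m in res.cluster_means.items()}
        nuclei_cluster = max(scores, key=scores.get)
        mask = res.labels == nuclei_cluster
        assert np.all(hmap.role_labels[mask] == 0)  # nucleus role index


class TestGroundTruthRecovery:
    def _map(self, noise):
        spec = SyntheticTissueSpec(
            map_width=20, map_height=20, class_name="cPDAC",
            baseline_coeffs=(0.0, 0.0, 0.0, 0.0), noise_sd=noise, seed=4,
        )
        return generate_tissue_map(spec)

    def test_noise_free_four_cluster_cut_recovers_roles_exactly(self):
        hmap = self._map(0.0)
        res = hca(hmap, k=4)
        ari = adjusted_rand_score(hmap.role_labels.ravel(), res.labels.ravel())
        assert ari == pytest.approx(1.0)

    def test_default_noise_recovery_stays_high(self):
        hmap = self._map(0.02)
        res = hca(hmap, k=4)
        ari = adjusted_rand_score(hmap.role_labels.ravel(), res.labels.ravel())
        assert ari >= 0.8


class TestRenderMap:
    def test_two_cluster_rows(self):
        img = render_hca_map(np.array([[1, 1], [2, 2]]))
        assert img.shape == (2, 2, 3)
        assert np.array_equal(img[0, 0], img[0, 1])
        assert not np.array_equal(img[0, 0], img[1, 0])

    def test_seven_clusters_seven_distinct_colors(self):
        labels = np.arange(1, 8).reshape(7, 1)
        img = render_hca_map(labels)
        colors = {tuple(px) for px in img.reshape(-1, 3)}
        assert len(colors) == 7

    def test_palette_too_small_raises(self):
        with pytest.raises(ValueError):
            render_hca_map(np.arange(1, 11).reshape(10, 1), DEFAULT_HCA_PALETTE[:3])
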