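from itertools import permutations, product

import numpy as np
import pytest

from neoms.epoch import EEGEpoch
from neoms.microstates import (
    MapSet,
    global_field_power,
    gfp_peaks,
    group_maps,
    match_map_order,
    modified_kmeans,
    select_k_kl,
    spatial_correlation,
)


def avg_ref_epoch(data, fs=100.0):
    data = data - data.mean(axis=0, keepdims=True)
    names = tuple(f"ch{i}" for i in range(data.shape[0]))
    return EEGEpoch(data=data, fs=fs, channel_names=names, reference="common_average")


class TestGFP:
    def test_spatially_constant_sample_has_zero_gfp(self):
        ep = avg_ref_epoch(np.ones((4, 10)))
        assert np.allclose(global_field_power(ep), 0.0)

    def test_two_channel_closed_form(self):
        ep = avg_ref_epoch(np.array([[1.0], [-1.0]]))
        assert np.allclose(global_field_power(ep), 1.0)

    def test_homogeneity(self):
        rng = np.random.default_rng(0)
        ep = avg_ref_epoch(rng.standard_normal((6, 50)))
        g = global_field_power(ep)
        ep5 = avg_ref_epoch(5.0 * ep.data)
        assert np.allclose(global_field_power(ep5), 5.0 * g)

    def test_rejects_unreferenced(self):
        names = ("a", "b", "c")
        ep = EEGEpoch(np.ones((3, 10)) * [[1.0], [2.0], [3.0]], 100.0, names)
        with pytest.raises(ValueError):
            global_field_power(ep)


class TestGFPPeaks:
    def test_enumerated_series(self):
        assert list(gfp_peaks(np.array([0, 1, 0, 2, 0.0]))) == [1, 3]

    def test_monotone_has_no_peaks(self):
        assert gfp_peaks(np.arange(10.0)).size == 0

    def test_plateau_credits_onset(self):
        assert list(gfp_peaks(np.array([0, 1, 1, 0.0]))) == [1]

    def test_matches_bruteforce_plateau_scan(self):
        rng = np.random.default_rng(1)
        g = np.round(rng.random(200), 1)  # coarse values force plateaus
        got = set(gfp_peaks(g))
        expect = {
            i for i in range(1, len(g) - 1) if g[i - 1] < g[i] and g[i] >= g[i + 1]
        }
        assert got == expect


class TestSpatialCorrelation:
    def test_self_correlation_is_one(self):
        a = np.array([1.0, -2.0, 0.5, 0.5])
        assert spatial_correlation(a, a) == pytest.approx(1.0)

    def test_polarity_ignored(self):
        a = np.array([1.0, -2.0, 0.5, 0.5])
        assert spatial_correlation(a, -a, polarity_invariant=True) == pytest.approx(1.0)
        assert spatial_correlation(a, -a, polarity_invariant=False) == pytest.approx(-1.0)

    def test_orthogonal_zero_mean_vectors(self):
        a = np.array([1.0, -1.0, 1.0, -1.0])
        b = np.array([1.0, 1.0, -1.0, -1.0])
        assert spatial_correlation(a, b) == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            spatial_correlation(np.ones(4), np.arange(4.0))


def _exhaustive_best_ev(samples, k):
    """Oracle: max explained variance over all sample-to-cluster assignments.

    For a fixed assignment the optimal map of each cluster is the
    principal eigenvector of the cluster scatter, so the explained
    variance is the sum of leading eigenvalues over clusters.
    """
    samples = samples - samples.mean(axis=1, keepdims=True)
    total = np.einsum("ij,ij->", samples, samples)
    best = 0.0
    n = samples.shape[0]
    for assign in product(range(k), repeat=n):
        assign = np.asarray(assign)
        ev = 0.0
        for j in range(k):
            members = samples[assign == j]
            if len(members) == 0:
                continue
            ev += np.linalg.eigvalsh(members.T @ members)[-1]
        best = max(best, ev / total)
    return best


class TestModifiedKmeans:
    def test_recovers_two_exact_clusters_with_sign_flips(self):
        rng = np.random.default_rng(2)
        m1 = np.array([1.0, -1.0, 1.0, -1.0, 0.0])
        m2 = np.array([1.0, 1.0, -1.0, -1.0, 0.0])
        m1 /= np.linalg.norm(m1)
        m2 /= np.linalg.norm(m2)
        signs = rng.choice([-1.0, 1.0], size=40)
        samples = np.vstack(
            [s * (m1 if i % 2 else m2) for i, s in enumerate(signs)]
        )
        res = modified_kmeans(samples, 2, seed=0)
        corr = np.abs(res.mapset.maps @ np.vstack([m1, m2]).T)
        assert np.allclose(corr.max(axis=0), 1.0, atol=1e-6)
        assert res.gev == pytest.approx(1.0, abs=1e-9)

    def test_saturated_model_explains_everything(self):
        rng = np.random.default_rng(3)
        samples = rng.standard_normal((5, 6))
        res = modified_kmeans(samples, 5, n_restarts=50, seed=0)
        assert res.gev == pytest.approx(1.0, abs=1e-9)

    def test_fewer_samples_than_k_rejected(self):
        with pytest.raises(ValueError):
            modified_kmeans(np.random.default_rng(0).standard_normal((3, 5)), 4)

    def test_matches_exhaustive_assignment_oracle(self):
        # three noisy clusters, 8 samples, k=3: global optimum by enumeration
        rng = np.random.default_rng(4)
        base = rng.standard_normal((3, 6))
        base -= base.mean(axis=1, keepdims=True)
        base /= np.linalg.norm(base, axis=1, keepdims=True)
        samples = np.vstack(
            [
                base[i % 3] * rng.choice([-1, 1]) + 0.15 * rng.standard_normal(6)
                for i in range(8)
            ]
        )
        oracle = _exhaustive_best_ev(samples, 3)
        res = modified_kmeans(samples, 3, n_restarts=64, seed=0)
        assert res.gev == pytest.approx(oracle, abs=1e-9)

    def test_polarity_invariance_of_clustering(self, synth):
        from neoms.microstates import global_field_power, gfp_peaks

        pp = synth["prepped"]
        peaks = gfp_peaks(global_field_power(pp))[:300]
        samples = pp.data[:, peaks].T
        rng = np.random.default_rng(5)
        flipped = samples * rng.choice([-1.0, 1.0], size=(len(samples), 1))
        a = modified_kmeans(samples, 4, seed=7)
        b = modified_kmeans(flipped, 4, seed=7)
        corr = np.abs(a.mapset.maps @ b.mapset.maps.T)
        assert np.allclose(np.sort(corr.max(axis=1)), 1.0, atol=1e-9)

    def test_scale_invariance_of_labels(self, synth):
        from neoms.microstates import global_field_power, gfp_peaks

        pp = synth["prepped"]
        peaks = gfp_peaks(global_field_power(pp))[:300]
        samples = pp.data[:, peaks].T
        a = modified_kmeans(samples, 4, seed=8)
        b = modified_kmeans(samples * 5.0, 4, seed=8)
        assert np.array_equal(a.peak_labels, b.peak_labels)


class TestKLSelection:
    def test_three_noiseless_clusters_select_three(self):
        rng = np.random.default_rng(6)
        base = rng.standard_normal((3, 9))
        base -= base.mean(axis=1, keepdims=True)
        base /= np.linalg.norm(base, axis=1, keepdims=True)
        amps = rng.gamma(3.0, 1.0, size=400)
        picks = rng.integers(3, size=400)
        samples = base[picks] * amps[:, None] * rng.choice([-1, 1], size=(400, 1))
        samples += 0.02 * rng.standard_normal(samples.shape)
        k_opt, kl, disp = select_k_kl(samples, 2, 6, seed=0, n_restarts=10)
        assert k_opt == 3

    def test_dispersion_non_increasing(self, synth):
        from neoms.microstates import global_field_power, gfp_peaks

        pp = synth["prepped"]
        peaks = gfp_peaks(global_field_power(pp))
        samples = pp.data[:, peaks].T
        _, _, disp = select_k_kl(samples, 3, 8, seed=1)
        vals = [disp[k] for k in sorted(disp)]
        assert all(vals[i] >= vals[i + 1] - 1e-9 for i in range(len(vals) - 1))

    def test_invalid_range_rejected(self):
        samples = np.random.default_rng(0).standard_normal((50, 9))
        with pytest.raises(ValueError):
            select_k_kl(samples, 3, 4)


class TestGroupMaps:
    def test_identical_mapsets_pool_to_themselves(self, true_maps):
        pooled = group_maps([true_maps] * 5, 4, seed=0)
        corr = np.abs(pooled.maps @ true_maps.maps.T)
        assert np.allclose(np.sort(corr.max(axis=1)), 1.0, atol=1e-9)

    def test_perturbed_mapsets_recover_ground_truth(self, true_maps):
        rng = np.random.default_rng(7)
        sets = []
        for _ in range(12):
            noisy = true_maps.maps + 0.05 * rng.standard_normal(true_maps.maps.shape)
            sets.append(MapSet(noisy))
        pooled = group_maps(sets, 4, seed=0)
        corr = np.abs(pooled.maps @ true_maps.maps.T)
        assert np.all(corr.max(axis=1) >= 0.99)

    def test_pooling_is_permutation_invariant(self, true_maps):
        rng = np.random.default_rng(8)
        sets = [
            MapSet(true_maps.maps + 0.05 * rng.standard_normal(true_maps.maps.shape))
            for _ in range(6)
        ]
        a = group_maps(sets, 4, seed=3)
        b = group_maps(sets[::-1], 4, seed=3)
        corr = np.abs(a.maps @ b.maps.T)
        assert np.allclose(np.sort(corr.max(axis=1)), 1.0, atol=1e-6)


class TestMatchMapOrder:
    def test_cyclic_shift_recovered(self, true_maps):
        shifted = MapSet(np.roll(true_maps.maps, 1, axis=0))
        reordered, perms = match_map_order(true_maps, [shifted])
        corr = np.abs(
            np.einsum("ij,ij->i", reordered[0].maps, true_maps.maps)
        )
        assert np.allclose(corr, 1.0, atol=1e-9)

    def test_sign_flips_give_identity_permutation(self, true_maps):
        flipped = MapSet(true_maps.maps * np.array([[1], [-1], [1], [-1]]))
        _, perms = match_map_order(true_maps, [flipped])
        assert list(perms[0]) == [0, 1, 2, 3]

    def test_matches_bruteforce_permutation_oracle(self):
        rng = np.random.default_rng(9)
        ref = MapSet(rng.standard_normal((4, 9)))
        other = MapSet(rng.standard_normal((4, 9)))
        _, perms = match_map_order(ref, [other])
        corr = np.abs(ref.maps @ other.maps.T)
        best = max(
            permutations(range(4)),
            key=lambda p: sum(corr[i, p[i]] for i in range(4)),
        )
        assert tuple(perms[0]) == best

    def test_mismatched_k_rejected(self, true_maps):
        with pytest.raises(ValueError):
            match_map_order(true_maps, [MapSet(np.random.default_rng(0).standard_normal((3, 9)))])
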