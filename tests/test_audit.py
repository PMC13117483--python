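"""Feature extraction, whitening and multivariate two-sample tests."""

import numpy as np
import pytest
from skimage.feature import graycomatrix, graycoprops

from mriwave.audit import (
    energy_distance,
    extract_features,
    feature_names,
    frequency_features,
    glcm_features,
    intensity_features,
    median_heuristic_bandwidth,
    mmd_rbf,
    permutation_pvalue,
    pooled_whiten,
    sliced_wasserstein,
    tissue_mask,
)
from mriwave import generate_phantom_volume, zscore_normalize


class TestTissueMask:
    def test_exact_zero_background_excluded(self):
        v = generate_phantom_volume(2, (32, 64, 64), noise_sd=0.0, bias_amp=0.0)
        sl = v.voxels[16]
        mask = tissue_mask(sl)
        assert mask.dtype == bool and mask.shape == sl.shape
        assert not np.any(mask & (sl == 0))

    def test_constant_slice_gives_empty_mask(self):
        assert not tissue_mask(np.ones((32, 32))).any()

    def test_largest_component_retained(self):
        sl = np.zeros((32, 32))
        sl[2:4, 2:4] = 5.0     # small island
        sl[10:30, 10:30] = 5.0  # big component
        mask = tissue_mask(sl)
        assert mask[15, 15] and not mask[2, 2]


class TestFeatures:
    def test_histogram_bins_sum_to_one(self, rng):
        sl = rng.normal(10, 3, size=(64, 64))
        f = intensity_features(sl, np.ones((64, 64), bool))
        hist = f[11:]  # 4 moments + 7 percentiles
        assert hist.shape == (64,)
        assert hist.sum() == pytest.approx(1.0)

    def test_constant_slice_frequency_ratios_are_zero(self):
        f = frequency_features(np.full((32, 32), 5.0))
        assert f[4] == pytest.approx(0.0, abs=1e-9)  # detail/approx
        assert f[5] == pytest.approx(0.0, abs=1e-9)  # high/low

    def test_checkerboard_is_high_frequency(self):
        board = (np.indices((64, 64)).sum(axis=0) % 2) * 2.0 - 1.0
        f = frequency_features(board)
        assert f[5] >= 10.0

    def test_feature_vector_dimensionality_is_fixed(self, rng):
        names = feature_names()
        for seed in range(3):
            v = generate_phantom_volume(40 + seed, (32, 64, 64))
            f = extract_features(zscore_normalize(v).voxels[16])
            assert f is not None and f.shape == (len(names),)
            assert np.all(np.isfinite(f))


class TestGLCM:
    def test_constant_slice_degenerate_values(self):
        f = glcm_features(np.full((16, 16), 3.0))
        contrast, homogeneity, energy, correlation, dissimilarity = f
        assert contrast == 0.0 and dissimilarity == 0.0
        assert homogeneity == 1.0 and energy == 1.0
        assert abs(correlation) < 1e-6  # epsilon-guarded

    def test_two_by_two_matches_hand_enumeration(self):
        img = np.array([[0.0, 0.0], [1.0, 1.0]])
        f = glcm_features(img, levels=2)
        # offsets (0,1): pairs (0,0),(1,1); (1,1): (0,1); (1,0): (0,1)x2; (1,-1): (0,1)
        # symmetrized and normalized per orientation, then averaged:
        # P_0   = [[.5,0],[0,.5]]       P_45  = [[0,.5],[.5,0]]
        # P_90  = [[0,.5],[.5,0]]       P_135 = [[0,.5],[.5,0]]
        P = (np.array([[0.5, 0], [0, 0.5]]) + 3 * np.array([[0, 0.5], [0.5, 0]])) / 4
        ii, jj = np.meshgrid([0, 1], [0, 1], indexing="ij")
        assert f[0] == pytest.approx(((ii - jj) ** 2 * P).sum())          # contrast
        assert f[1] == pytest.approx((P / (1 + abs(ii - jj))).sum())      # homogeneity
        assert f[2] == pytest.approx((P**2).sum())                        # energy
        assert f[4] == pytest.approx((abs(ii - jj) * P).sum())            # dissimilarity

    def test_transpose_invariance_under_orientation_averaging(self, rng):
        img = rng.normal(size=(32, 32))
        assert np.allclose(glcm_features(img), glcm_features(img.T), atol=1e-12)

    def test_agrees_with_skimage_on_shared_conventions(self, rng):
        img = rng.integers(0, 8, size=(32, 32)).astype(float)
        mine = glcm_features(img, levels=8)
        q = np.clip((img - img.min()) / (img.max() - img.min()) * 8, 0, 7).astype(np.uint8)
        G = graycomatrix(q, [1], [0, np.pi / 4, np.pi / 2, 3 * np.pi / 4],
                         levels=8, symmetric=True, normed=True)
        # contrast and dissimilarity are linear in P, so averaging per-angle
        # skimage values equals the value of the orientation-averaged matrix
        for pos, prop in ((0, "contrast"), (4, "dissimilarity")):
            ref = np.mean([graycoprops(G, prop)[0, a] for a in range(4)])
            assert mine[pos] == pytest.approx(ref, abs=1e-10)
        # correlation of the averaged matrix, recomputed independently
        P = G[:, :, 0, :].mean(axis=-1)
        P = P / P.sum()
        lv = np.arange(8)
        px, py = P.sum(axis=1), P.sum(axis=0)
        mx, my = lv @ px, lv @ py
        sx = np.sqrt(((lv - mx) ** 2) @ px)
        sy = np.sqrt(((lv - my) ** 2) @ py)
        ii, jj = np.meshgrid(lv, lv, indexing="ij")
        ref_corr = ((ii - mx) * (jj - my) * P).sum() / (sx * sy)
        assert mine[3] == pytest.approx(ref_corr, abs=1e-8)


class TestWhitening:
    def test_pooled_identity_covariance_and_zero_mean(self, rng):
        X = rng.normal(size=(80, 6)) @ rng.normal(size=(6, 6)) + 5
        Y = rng.normal(size=(40, 6)) @ rng.normal(size=(6, 6)) - 2
        Xw, Yw = pooled_whiten(X, Y, ridge=0.0)
        pool = np.vstack([Xw, Yw])
        assert np.abs(pool.mean(axis=0)).max() < 1e-10
        cov = np.cov(pool, rowvar=False, bias=True)
        assert np.abs(cov - np.eye(6)).max() < 1e-6

    def test_zero_variance_feature_rejected(self, rng):
        X = rng.normal(size=(20, 3))
        X[:, 1] = 7.0
        Y = X.copy()
        with pytest.raises(ValueError, match="ridge"):
            pooled_whiten(X, Y, ridge=0.0)

    def test_rank_deficient_with_ridge_is_finite(self, rng):
        X = rng.normal(size=(30, 4))
        X[:, 3] = X[:, 0] + X[:, 1]  # exact linear dependence
        Y = rng.normal(size=(10, 4))
        Y[:, 3] = Y[:, 0] + Y[:, 1]
        Xw, Yw = pooled_whiten(X, Y, ridge=1e-6)
        assert np.all(np.isfinite(Xw)) and np.all(np.isfinite(Yw))


class TestEnergyDistance:
    def test_identical_samples_give_zero(self, rng):
        X = rng.normal(size=(20, 5))
        assert abs(energy_distance(X, X)) < 1e-12

    def test_single_point_formula_collapse(self):
        assert energy_distance(np.array([[0.0]]), np.array([[5.0]])) == pytest.approx(10.0)

    def test_matches_double_loop_oracle(self, rng):
        X = rng.normal(size=(20, 5))
        Y = rng.normal(1.0, 1.0, size=(20, 5))
        xy = np.mean([np.linalg.norm(x - y) for x in X for y in Y])
        xx = np.mean([np.linalg.norm(a - b) for a in X for b in X])
        yy = np.mean([np.linalg.norm(a - b) for a in Y for b in Y])
        assert energy_distance(X, Y) == pytest.approx(2 * xy - xx - yy, abs=1e-10)


class TestMMD:
    def test_identical_multisets_give_zero(self, rng):
        X = rng.normal(size=(10, 3))
        assert abs(mmd_rbf(X, X.copy())) < 1e-12

    def test_median_heuristic_enumeration(self):
        X = np.array([[0.0], [0.0]])
        Y = np.array([[1.0], [1.0]])
        # pooled pairwise distances: {0, 1, 1, 1, 1, 0} -> median 1
        assert median_heuristic_bandwidth(np.vstack([X, Y])) == pytest.approx(1.0)

    def test_matches_double_loop_oracle(self, rng):
        X = rng.normal(size=(15, 4))
        Y = rng.normal(0.5, 1.0, size=(12, 4))
        sigma = median_heuristic_bandwidth(np.vstack([X, Y]))
        k = lambda a, b: np.exp(-np.sum((a - b) ** 2) / (2 * sigma**2))
        n, m = len(X), len(Y)
        xx = sum(k(X[i], X[j]) for i in range(n) for j in range(n) if i != j) / (n * (n - 1))
        yy = sum(k(Y[i], Y[j]) for i in range(m) for j in range(m) if i != j) / (m * (m - 1))
        xy = np.mean([k(x, y) for x in X for y in Y])
        assert mmd_rbf(X, Y) == pytest.approx(xx + yy - 2 * xy, abs=1e-12)

    def test_degenerate_pool_rejected(self):
        X = np.zeros((3, 2))
        with pytest.raises(ValueError):
            mmd_rbf(X, X)


class TestSlicedWasserstein:
    def test_identical_equal_size_samples_give_zero(self, rng):
        X = rng.normal(size=(25, 4))
        assert sliced_wasserstein(X, X.copy(), n_directions=20, seed=0) < 1e-12

    def test_one_dimensional_reduces_to_sorted_difference(self, rng):
        X = rng.normal(size=(30, 1))
        Y = rng.normal(2.0, 1.0, size=(30, 1))
        expected = np.mean(np.abs(np.sort(X[:, 0]) - np.sort(Y[:, 0])))
        # in 1-D every unit direction is +/-1 and |.| removes the sign
        assert sliced_wasserstein(X, Y, n_directions=50, seed=1) == pytest.approx(expected)

    def test_estimate_stable_across_seeds(self, rng):
        X = rng.normal(size=(100, 5))
        Y = rng.normal(1.0, 1.0, size=(100, 5))
        vals = [sliced_wasserstein(X, Y, n_directions=500, seed=s) for s in range(8)]
        assert np.std(vals) < 0.10 * np.mean(vals)


class TestPermutationTest:
    def test_extreme_statistic_attains_add_one_bound(self, rng):
        X = rng.normal(size=(15, 3))
        Y = rng.normal(50.0, 1.0, size=(15, 3))  # overwhelming separation
        strata = np.zeros(15)
        res = permutation_pvalue(energy_distance, X, Y, strata, strata, n_perm=99, seed=0)
        assert res.p_value == pytest.approx(1.0 / 100.0)

    def test_per_stratum_counts_preserved(self, rng):
        X = rng.normal(size=(12, 2))
        Y = rng.normal(size=(8, 2))
        sx = np.array([0] * 6 + [1] * 6)
        sy = np.array([0] * 3 + [1] * 5)
        seen = []

        def spy(A, B):
            seen.append((A.shape[0], B.shape[0]))
            return energy_distance(A, B)

        permutation_pvalue(spy, X, Y, sx, sy, n_perm=20, seed=0)
        assert all(a == 12 and b == 8 for a, b in seen)

    def test_stratum_missing_from_one_partition_rejected(self, rng):
        X = rng.normal(size=(6, 2))
        Y = rng.normal(size=(6, 2))
        with pytest.raises(ValueError, match="strata"):
            permutation_pvalue(energy_distance, X, Y,
                               np.array([0] * 6), np.array([0] * 3 + [1] * 3),
                               n_perm=10, seed=0)
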