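"""Profile normalization, FFT distances, DISTATIS and aggregation."""

import numpy as np
import pandas as pd
import pytest

from lamorg import metrics
from lamorg.profiles import ProfileMatrix


def make_pm(values, sections=None, timepoints=None, names=None):
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    meta = pd.DataFrame(
        {
            "window": range(n),
            "section": sections if sections is not None else ["s0"] * n,
            "timepoint": timepoints if timepoints is not None else [0] * n,
        }
    )
    names = names or [f"f{i}" for i in range(values.shape[2])]
    return ProfileMatrix(values, meta, names)


class TestNormalizeProfiles:
    def test_single_group_is_identity_up_to_scaling(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(2, 1, (5, 50, 1))
        pm = metrics.normalize_profiles(make_pm(vals))
        # scaling to [0,1] is monotone; ranks preserved within each window
        for i in range(5):
            assert np.array_equal(
                np.argsort(vals[i, :, 0]), np.argsort(pm.values[i, :, 0])
            )
        assert pm.values.min() >= 0 and pm.values.max() <= 1

    def test_identical_windows_identical_outputs(self):
        rng = np.random.default_rng(1)
        prof = rng.normal(size=50)
        vals = np.stack([prof, prof.copy(), rng.normal(size=50)])[:, :, None]
        pm = metrics.normalize_profiles(make_pm(vals))
        np.testing.assert_array_equal(pm.values[0], pm.values[1])

    def test_group_stats_preserved_pre_scaling(self):
        """Reverse z-scoring preserves pooled group mean/sd, checked by an
        independent accumulation of the intermediate values."""
        rng = np.random.default_rng(2)
        vals = rng.normal(3, 2, (6, 40, 1))
        sections = ["a"] * 3 + ["b"] * 3
        pm_in = make_pm(vals, sections=sections)
        groups = {"a": range(3), "b": range(3, 6)}
        for g, idx in groups.items():
            block = vals[list(idx), :, 0]
            gmu, gsd = block.mean(), block.std()
            inter = np.stack(
                [(p - p.mean()) / p.std() * gsd + gmu for p in block]
            )
            assert abs(inter.mean() - gmu) < 1e-9
            # per-window sd equals the group sd after reverse z-scoring
            assert np.allclose([p.std() for p in inter], gsd, atol=1e-9)

    def test_constant_feature_set_to_half(self):
        vals = np.full((4, 30, 1), 2.0)
        pm = metrics.normalize_profiles(make_pm(vals))
        assert np.all(pm.values == 0.5)
        assert "f0" in pm.flags["constant_features"]


class TestSmoothDownsample:
    def test_constant_profile_unchanged_half_length(self):
        vals = np.full((2, 100, 1), 1.5)
        out = metrics.smooth_downsample(make_pm(vals), mean_window=20, factor=2)
        assert out.n_positions == 50
        assert np.allclose(out.values, 1.5)

    def test_thousand_positions_become_five_hundred(self):
        vals = np.random.default_rng(3).normal(size=(1, 1000, 1))
        out = metrics.smooth_downsample(make_pm(vals), 20, 2)
        assert out.n_positions == 500

    def test_impulse_matches_direct_convolution(self):
        """Impulse response equals the truncated-window moving mean computed
        by direct convolution."""
        vals = np.zeros((1, 1000, 1))
        vals[0, 500, 0] = 1.0
        out = metrics.smooth_downsample(make_pm(vals), 20, 1)
        kernel = np.ones(20)
        direct = np.convolve(vals[0, :, 0], kernel, mode="same")
        counts = np.convolve(np.ones(1000), kernel, mode="same")
        np.testing.assert_allclose(out.values[0, :, 0], direct / counts, atol=1e-12)
        interior = out.values[0, 480:510, 0]
        assert np.isclose(interior.max(), 1 / 20)

    def test_window_longer_than_profile_raises(self):
        with pytest.raises(ValueError, match="mean_window"):
            metrics.smooth_downsample(make_pm(np.zeros((1, 10, 1))), 20, 2)

    def test_missing_values_imputed(self):
        vals = np.full((1, 60, 1), 2.0)
        vals[0, 10:14, 0] = np.nan
        out = metrics.smooth_downsample(make_pm(vals), 10, 2)
        assert np.all(np.isfinite(out.values))
        assert np.allclose(out.values, 2.0)


class TestFFTDistance:
    def test_identical_profiles_distance_zero(self):
        prof = np.random.default_rng(4).normal(size=50)
        vals = np.stack([prof, prof.copy()])[:, :, None]
        ds = metrics.fft_distance(make_pm(vals), n_components=10)
        assert ds.matrices[0, 0, 1] == 0.0

    def test_symmetry_and_zero_diagonal(self):
        vals = np.random.default_rng(5).normal(size=(6, 64, 2))
        ds = metrics.fft_distance(make_pm(vals), n_components=10)
        for f in range(2):
            np.testing.assert_array_equal(ds.matrices[f], ds.matrices[f].T)
            np.testing.assert_array_equal(np.diag(ds.matrices[f]), 0.0)

    def test_matches_naive_dft(self):
        """Pairwise distances agree with an O(n^2) DFT to 1e-8 relative."""
        rng = np.random.default_rng(6)
        vals = rng.normal(size=(5, 500, 1))
        ds = metrics.fft_distance(make_pm(vals), n_components=10)
        n = 500
        ks = np.arange(10)
        # naive DFT: F_k = sum_t x_t exp(-2i pi k t / n)
        F = np.zeros((5, 10), complex)
        for i in range(5):
            for k in ks:
                F[i, k] = np.sum(
                    vals[i, :, 0] * np.exp(-2j * np.pi * k * np.arange(n) / n)
                )
        for i in range(5):
            for j in range(5):
                expect = np.sqrt(np.sum(np.abs(F[i] - F[j]) ** 2))
                got = ds.matrices[0, i, j]
                assert abs(got - expect) <= 1e-8 * max(expect, 1)

    def test_scaling_linearity_against_zero_profile(self):
        rng = np.random.default_rng(7)
        prof = rng.normal(size=64)
        for c in (2.0, 5.0):
            vals = np.stack([prof, np.zeros(64)])[:, :, None]
            d1 = metrics.fft_distance(make_pm(vals), 8).matrices[0, 0, 1]
            vals_c = np.stack([c * prof, np.zeros(64)])[:, :, None]
            dc = metrics.fft_distance(make_pm(vals_c), 8).matrices[0, 0, 1]
            assert np.isclose(dc, c * d1)

    def test_too_many_components_raises(self):
        with pytest.raises(ValueError, match="n_components"):
            metrics.fft_distance(make_pm(np.zeros((2, 10, 1))), n_components=10)


def random_distance_matrix(rng, n):
    """Euclidean distance matrix of random points (guaranteed PSD-consistent)."""
    X = rng.normal(size=(n, 3))
    from scipy.spatial.distance import pdist, squareform

    return squareform(pdist(X))


class TestDistatis:
    def test_identical_tables_uniform_alpha_and_proportional_compromise(self):
        rng = np.random.default_rng(8)
        D = random_distance_matrix(rng, 6)
        K = 4
        ds = metrics.FeatureDistanceSet(
            np.stack([D] * K), [f"f{i}" for i in range(K)]
        )
        cd = metrics.distatis(ds)
        np.testing.assert_allclose(cd.alpha, np.full(K, 1 / K), atol=1e-12)
        # compromise proportional to the input: equal after undoing the
        # eigenvalue normalization analytically
        S = metrics._double_center(D)
        ev = np.linalg.eigvalsh(S)[-1]
        np.testing.assert_allclose(cd.D_plus, D / np.sqrt(ev), atol=1e-8)

    def test_small_toy_matches_independent_eigen_oracle(self):
        """4x4 two-feature case computed end-to-end by an independent,
        loop-based eigendecomposition oracle."""
        rng = np.random.default_rng(9)
        D1 = random_distance_matrix(rng, 4)
        D2 = random_distance_matrix(rng, 4)
        ds = metrics.FeatureDistanceSet(np.stack([D1, D2]), ["a", "b"])
        cd = metrics.distatis(ds)

        # oracle: explicit loops, scipy.linalg.eigh
        from scipy.linalg import eigh

        W = 4
        S_t = []
        for D in (D1, D2):
            S = np.zeros((W, W))
            D2m = D**2
            rm = D2m.mean(axis=1)
            cm = D2m.mean(axis=0)
            gm = D2m.mean()
            for i in range(W):
                for j in range(W):
                    S[i, j] = -0.5 * (D2m[i, j] - rm[i] - cm[j] + gm)
            lam = eigh(S, eigvals_only=True)[-1]
            S_t.append(S / lam)
        R = np.zeros((2, 2))
        for i in range(2):
            for j in range(2):
                R[i, j] = np.sum(S_t[i] * S_t[j]) / np.sqrt(
                    np.sum(S_t[i] ** 2) * np.sum(S_t[j] ** 2)
                )
        w_, v_ = eigh(R)
        alpha = v_[:, -1]
        alpha = alpha / alpha.sum()
        S_plus = alpha[0] * S_t[0] + alpha[1] * S_t[1]
        D_expect = np.zeros((W, W))
        for i in range(W):
            for j in range(W):
                D_expect[i, j] = np.sqrt(
                    max(S_plus[i, i] + S_plus[j, j] - 2 * S_plus[i, j], 0)
                )
        np.testing.assert_allclose(cd.alpha, alpha, atol=1e-6)
        np.testing.assert_allclose(cd.D_plus, D_expect, atol=1e-6)

    def test_rv_matrix_in_unit_range(self):
        rng = np.random.default_rng(10)
        mats = np.stack([random_distance_matrix(rng, 5) for _ in range(3)])
        cd = metrics.distatis(metrics.FeatureDistanceSet(mats, list("abc")))
        assert np.all(cd.rv_matrix >= 0) and np.all(cd.rv_matrix <= 1 + 1e-12)
        np.testing.assert_allclose(np.diag(cd.rv_matrix), 1.0, atol=1e-12)

    def test_alpha_permutation_equivariance(self):
        rng = np.random.default_rng(11)
        mats = np.stack([random_distance_matrix(rng, 5) for _ in range(3)])
        cd = metrics.distatis(metrics.FeatureDistanceSet(mats, list("abc")))
        perm = [2, 0, 1]
        cd_p = metrics.distatis(
            metrics.FeatureDistanceSet(mats[perm], [chr(97 + i) for i in perm])
        )
        np.testing.assert_allclose(cd_p.alpha, cd.alpha[perm], atol=1e-9)
        np.testing.assert_allclose(cd_p.D_plus, cd.D_plus, atol=1e-9)

    def test_triangle_inequality_on_random_instances(self):
        rng = np.random.default_rng(12)
        for _ in range(50):
            mats = np.stack([random_distance_matrix(rng, 5) for _ in range(2)])
            D = metrics.distatis(metrics.FeatureDistanceSet(mats, list("ab"))).D_plus
            for i in range(5):
                for j in range(5):
                    for k in range(5):
                        assert D[i, j] <= D[i, k] + D[k, j] + 1e-9

    def test_asymmetric_input_raises(self):
        bad = np.array([[0, 1.0], [2.0, 0]])
        with pytest.raises(ValueError, match="symmetric"):
            metrics.distatis(
                metrics.FeatureDistanceSet(np.stack([bad, bad]), list("ab"))
            )

    def test_single_feature_raises(self):
        D = random_distance_matrix(np.random.default_rng(0), 4)
        with pytest.raises(ValueError, match="at least 2"):
            metrics.distatis(metrics.FeatureDistanceSet(D[None], ["a"]))


class TestAggregateLogDistance:
    def test_single_zero_feature_gives_zero_matrix(self):
        D = np.zeros((1, 3, 3))
        out = metrics.aggregate_log_distance(metrics.FeatureDistanceSet(D, ["a"]))
        np.testing.assert_array_equal(out, np.zeros((3, 3)))

    def test_matches_hand_computation_on_toy(self):
        D1 = np.array([[0, 9, 99], [9, 0, 9], [99, 9, 0]], float)
        D2 = np.array([[0, 99, 9], [99, 0, 99], [9, 99, 0]], float)
        out = metrics.aggregate_log_distance(
            metrics.FeatureDistanceSet(np.stack([D1, D2]), list("ab"))
        )
        # log10(9+1)=1, log10(99+1)=2; mean of (1,2) = 1.5
        expected = np.array([[0, 1.5, 1.5], [1.5, 0, 1.5], [1.5, 1.5, 0]])
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_monotone_in_entries(self):
        rng = np.random.default_rng(13)
        D = random_distance_matrix(rng, 4)
        ds = metrics.FeatureDistanceSet(D[None], ["a"])
        base = metrics.aggregate_log_distance(ds)
        D2 = D.copy()
        D2[1, 2] = D2[2, 1] = D2[1, 2] + 5
        bigger = metrics.aggregate_log_distance(
            metrics.FeatureDistanceSet(D2[None], ["a"])
        )
        assert bigger[1, 2] > base[1, 2]
        mask = ~np.eye(4, dtype=bool)
        assert np.all(bigger[mask] >= base[mask] - 1e-12)
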