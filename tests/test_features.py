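"""Feature extractors: CSP, PSD, wavelets, Riemannian geometry, MI, FBCSP."""

import numpy as np
import pytest
import pywt

from miadapt import (
    csp_features,
    csp_fit,
    fbcsp_features,
    mutual_information,
    psd_features,
    riemann_distance,
    riemann_features,
    riemann_mean,
    tangent_map,
    wavelet_features,
)
from miadapt.features import (
    FBCSPFeatures,
    SpatialFilters,
    _sym_pow,
    epoch_covariances,
    wpd_leaf_selection,
)


def epochs_with_cov(C, n_epochs=20, n_samples=2000, seed=0):
    """Epochs whose sample covariance converges to C."""
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(C)
    return np.stack(
        [L @ rng.standard_normal((C.shape[0], n_samples)) for _ in range(n_epochs)]
    )


class TestCSP:
    def test_identical_classes_give_half_eigenvalues(self):
        X = epochs_with_cov(np.diag([2.0, 1.0]), seed=1)
        filt = csp_fit(X, X, n_pairs=1)
        assert np.allclose(filt.eigenvalues, 0.5, atol=1e-12)

    def test_axis_aligned_closed_form(self):
        Xa = epochs_with_cov(np.diag([4.0, 1.0]), seed=2)
        Xb = epochs_with_cov(np.diag([1.0, 4.0]), seed=3)
        filt = csp_fit(Xa, Xb, n_pairs=1)
        # population eigenvalues 4/5 and 1/5; sample estimate nearby
        assert abs(filt.eigenvalues[0] - 0.8) < 0.05
        assert abs(filt.eigenvalues[1] - 0.2) < 0.05
        # filters essentially axis aligned
        for col in filt.W.T:
            assert np.abs(col / np.abs(col).max()).min() < 0.2

    def test_whitening_constraint(self, rng):
        Xa = epochs_with_cov(np.array([[2.0, 0.5], [0.5, 1.0]]), seed=4)
        Xb = epochs_with_cov(np.array([[1.0, -0.3], [-0.3, 3.0]]), seed=5)
        filt = csp_fit(Xa, Xb, n_pairs=1)
        C1 = epoch_covariances(Xa).mean(axis=0)
        C2 = epoch_covariances(Xb).mean(axis=0)
        assert np.allclose(filt.W.T @ (C1 + C2) @ filt.W, np.eye(2), atol=1e-6)

    def test_features_scale_invariant_and_normalized(self):
        Xa = epochs_with_cov(np.diag([4.0, 1.0]), n_epochs=6, seed=6)
        Xb = epochs_with_cov(np.diag([1.0, 4.0]), n_epochs=6, seed=7)
        filt = csp_fit(Xa, Xb, n_pairs=1)
        f1 = csp_features(Xa, filt).values
        f2 = csp_features(10.0 * Xa, filt).values
        assert np.allclose(f1, f2, atol=1e-10)
        assert np.allclose(np.exp(f1).sum(axis=1), 1.0, atol=1e-10)
        assert f1.shape[1] == 2

    def test_zero_variance_rejected(self):
        filt = SpatialFilters(np.eye(2), np.array([0.5, 0.5]))
        with pytest.raises(ValueError, match="variance"):
            csp_features(np.zeros((3, 2, 100)), filt)


class TestPSD:
    def test_dimension_contract(self, epochs_70):
        fm = psd_features(epochs_70)
        assert fm.shape == (70, 21)

    def test_sinusoid_peak_location(self):
        from mne.time_frequency import psd_array_multitaper

        fs, f = 250.0, 20.0
        t = np.arange(750) / fs
        X = np.sin(2 * np.pi * f * t)[None, None, :]
        psd, freqs = psd_array_multitaper(X, fs, fmin=8, fmax=30, bandwidth=4,
                                          verbose="error")
        assert abs(freqs[np.argmax(psd[0, 0])] - f) < 2.0

    def test_white_noise_level(self, rng):
        """Flat spectrum: band-mean density approximates sigma^2 / (fs/2)."""
        fs, sigma = 250.0, 2.0
        X = sigma * rng.standard_normal((40, 1, 750))
        from miadapt.features import PSDFeatures

        vals = PSDFeatures(fs=fs).transform(X)
        expected = sigma**2 / (fs / 2)
        assert abs(vals.mean() - expected) / expected < 0.2

    def test_band_above_nyquist_rejected(self, small_epochs):
        with pytest.raises(ValueError, match="Nyquist"):
            psd_features(small_epochs, band=(8.0, 200.0), channels=("C3",))


class TestWavelet:
    def test_dimension_contract(self, epochs_70):
        fm = wavelet_features(epochs_70)
        assert fm.shape == (70, 36)
        assert len(set(fm.feature_names)) == 36

    def test_constant_signal_zero_detail_sd(self, small_epochs):
        X = np.ones((3, 2, 512))
        from miadapt.features import WaveletFeatures

        tr = WaveletFeatures(fs=250.0, mother="haar")
        vals = tr.transform(X)
        names = tr.feature_names()
        sds = [v for v, n in zip(vals[0], names) if n.endswith("_sd") and "_D" in n]
        assert np.allclose(sds, 0.0, atol=1e-12)

    def test_haar_step_oracle(self):
        """Hand-computed Haar transform of [1, 1, -1, -1]: the step lives
        entirely in the level-2 detail."""
        cA2, cD2, cD1 = pywt.wavedec([1.0, 1.0, -1.0, -1.0], "haar", level=2)
        assert np.allclose(cA2, [0.0])
        assert np.allclose(cD2, [2.0])
        assert np.allclose(cD1, [0.0, 0.0])

    def test_leaf_selection_frequency_overlap(self):
        # at 250 Hz, level-3 leaves are 15.625 Hz wide: only leaves 0 and 1
        # overlap 8-30 Hz; remaining picks fill in ascending order
        assert wpd_leaf_selection(250.0, 3, (8.0, 30.0)) == [0, 1, 2, 3, 4, 5]
        # at 128 Hz leaves are 8 Hz wide: leaves 1-3 overlap fully/partially
        sel = wpd_leaf_selection(128.0, 3, (8.0, 30.0))
        assert set((1, 2, 3)) <= set(sel) and len(sel) == 6

    def test_unknown_wavelet_lists_families(self, small_epochs):
        with pytest.raises(ValueError, match="Coiflets"):
            wavelet_features(small_epochs, mother="mexh", channels=("C3",))


class TestRiemann:
    def rand_spd(self, rng, p=3):
        A = rng.standard_normal((p, p))
        return A @ A.T + p * np.eye(p)

    def test_mean_of_identical_is_identity_map(self, rng):
        A = self.rand_spd(rng)
        M = riemann_mean([A, A])
        assert np.allclose(M, A, atol=1e-8)

    def test_commuting_pair_geometric_mean(self):
        M = riemann_mean([np.diag([1.0, 1.0]), np.diag([4.0, 4.0])])
        assert np.allclose(M, np.diag([2.0, 2.0]), atol=1e-8)

    def test_two_matrix_closed_form(self, rng):
        """Karcher mean of two matrices equals the geodesic midpoint
        A^(1/2) (A^(-1/2) B A^(-1/2))^(1/2) A^(1/2)."""
        for _ in range(5):
            A, B = self.rand_spd(rng), self.rand_spd(rng)
            A_sqrt, A_isqrt = _sym_pow(A, 0.5), _sym_pow(A, -0.5)
            midpoint = A_sqrt @ _sym_pow(A_isqrt @ B @ A_isqrt, 0.5) @ A_sqrt
            assert np.allclose(riemann_mean([A, B]), midpoint, atol=1e-6)

    def test_congruence_equivariance(self, rng):
        A, B = self.rand_spd(rng), self.rand_spd(rng)
        G = rng.standard_normal((3, 3)) + 3 * np.eye(3)
        lhs = riemann_mean([G @ A @ G.T, G @ B @ G.T])
        rhs = G @ riemann_mean([A, B]) @ G.T
        assert np.allclose(lhs, rhs, atol=1e-6)

    def test_distance_closed_forms(self):
        A = np.diag([2.0, 3.0])
        assert riemann_distance(A, A) == pytest.approx(0.0, abs=1e-9)
        d = riemann_distance(np.eye(2), np.diag([np.e**2, np.e**2]))
        assert d == pytest.approx(2 * np.sqrt(2), abs=1e-12)

    def test_tangent_map_properties(self, rng):
        ref = self.rand_spd(rng)
        assert np.allclose(tangent_map([ref], ref)[0], 0.0, atol=1e-9)
        C = self.rand_spd(rng)
        vec = tangent_map([C], ref)[0]
        assert len(vec) == 3 * 4 // 2
        # isometry: vector norm equals the Riemannian distance
        assert np.linalg.norm(vec) == pytest.approx(riemann_distance(C, ref), abs=1e-8)

    def test_feature_dimension_contract(self, epochs_70):
        fm = riemann_features(epochs_70)
        assert fm.shape == (70, 12)

    def test_non_symmetric_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            riemann_distance(np.array([[1.0, 2.0], [0.0, 1.0]]), np.eye(2))


class TestMutualInformation:
    def test_perfect_separation_is_one_bit(self):
        f = np.r_[np.zeros(35), np.ones(35)]
        y = np.r_[np.zeros(35), np.ones(35)]
        assert mutual_information(f, y) == pytest.approx(1.0, abs=1e-9)

    def test_independent_feature_near_zero(self, rng):
        y = np.r_[np.zeros(35), np.ones(35)]
        mis = [mutual_information(rng.standard_normal(70), y) for _ in range(20)]
        assert np.median(mis) < 0.05

    def test_monotone_rescaling_invariance(self, rng):
        f = rng.standard_normal(70)
        y = (f + 0.5 * rng.standard_normal(70)) > 0
        assert mutual_information(f, y) == pytest.approx(
            mutual_information(np.exp(3 * f), y), abs=1e-12
        )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="classes"):
            mutual_information(np.arange(10.0), np.zeros(10))


class TestFBCSP:
    def test_dimension_contract(self, epochs_70):
        fm, report = fbcsp_features(epochs_70)
        assert fm.shape == (70, 24)
        assert len(report) == 6
        assert all(v >= 0 for v in report.values())

    def test_single_band_reduces_to_csp(self, small_epochs):
        fm, _ = fbcsp_features(small_epochs, bank=((8.0, 12.0),), n_pairs=2)
        assert fm.shape == (16, 4)

    def test_band_permutation_permutes_columns(self, small_epochs):
        bank = ((8.0, 12.0), (12.0, 16.0))
        fm_ab, _ = fbcsp_features(small_epochs, bank=bank, n_pairs=1)
        fm_ba, _ = fbcsp_features(small_epochs, bank=bank[::-1], n_pairs=1)
        assert np.allclose(fm_ab.values[:, :2], fm_ba.values[:, 2:])
        assert np.allclose(fm_ab.values[:, 2:], fm_ba.values[:, :2])

    def test_spatial_discrimination_on_distinct_patterns(self, small_epochs):
        """Top CSP filter separates classes whose band power differs
        spatially: between-class variance ratio of the projection > 2."""
        X, y = small_epochs.data, small_epochs.labels
        fb = FBCSPFeatures(fs=small_epochs.fs, bank=((8.0, 30.0),), n_pairs=1).fit(X, y)
        csp = fb.csp_[0]
        proj = np.einsum("cf,ecs->efs", csp.filters_, X)
        var = proj.var(axis=2)
        classes = np.unique(y)
        v1 = var[y == classes[0]].mean(axis=0)
        v2 = var[y == classes[1]].mean(axis=0)
        ratio = max(v1[0] / v2[0], v2[0] / v1[0])
        assert ratio > 2
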