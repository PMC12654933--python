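import numpy as np
import pytest

from crossdecomp import (
    between_system_spectrum,
    anatomical_spectrum,
    cvpca_spectrum,
    evaluate_test_spectrum,
    fit_cross_basis,
    make_folds,
    normalize_by_channels,
    offdiagonal_mass,
    pca_spectrum,
    within_system_spectrum,
    zscore_channels,
)
from crossdecomp.core import FoldSpectrum

from conftest import make_response_set


def brute_force_basis(train_a, train_b):
    """Independent oracle: explicit centered cross-covariance and full SVD."""
    a = train_a - train_a.mean(axis=0)
    b = train_b - train_b.mean(axis=0)
    C = a.T @ b / len(a)
    U, s, Vt = np.linalg.svd(C, full_matrices=False)
    return U, s, Vt.T


class TestFitCrossBasis:
    def test_self_decomposition_recovers_axis_variances(self):
        # centered columns orthogonal with variances 4 and 1
        col1 = np.array([-2.0, 2.0, -2.0, 2.0])
        col2 = np.array([1.0, 1.0, -1.0, -1.0])
        X = np.column_stack([col1, col2])
        basis = fit_cross_basis(X, X)
        assert np.allclose(basis.sigma_train, [4.0, 1.0])
        assert np.allclose(np.abs(basis.U), np.eye(2), atol=1e-12)
        assert np.allclose(basis.U, basis.V)

    def test_matches_brute_force_svd(self, rng):
        a = rng.standard_normal((12, 3))
        b = rng.standard_normal((12, 4))
        basis = fit_cross_basis(a, b)
        U, s, V = brute_force_basis(a, b)
        K = basis.K
        assert K == 3
        assert np.allclose(basis.sigma_train, s[:K], atol=1e-10)
        # compare up to the joint sign fixed by the implementation
        for k in range(K):
            sign = np.sign(np.dot(basis.U[:, k], U[:, k]))
            assert np.allclose(basis.U[:, k], sign * U[:, k], atol=1e-10)
            assert np.allclose(basis.V[:, k], sign * V[:, k], atol=1e-10)

    def test_column_permutation_equivariance(self, rng):
        a = rng.standard_normal((15, 4))
        perm = rng.permutation(4)
        basis_self = fit_cross_basis(a, a)
        basis_perm = fit_cross_basis(a, a[:, perm])
        assert np.allclose(basis_perm.sigma_train, basis_self.sigma_train, atol=1e-10)
        assert np.allclose(basis_perm.V, basis_perm.U[perm], atol=1e-10)

    def test_orthonormal_columns_and_rank_cap(self, rng):
        a = rng.standard_normal((5, 8))
        b = rng.standard_normal((5, 6))
        basis = fit_cross_basis(a, b)
        assert basis.K == 4  # n_train - 1
        assert np.allclose(basis.U.T @ basis.U, np.eye(4), atol=1e-8)
        assert np.allclose(basis.V.T @ basis.V, np.eye(4), atol=1e-8)
        assert np.all(np.diff(basis.sigma_train) <= 1e-12)

    def test_zero_cross_covariance_is_not_an_error(self):
        a = np.column_stack([np.arange(4.0)])
        b = np.ones((4, 2)) * 3.14
        basis = fit_cross_basis(a, b)
        assert np.allclose(basis.sigma_train, 0.0)

    def test_single_training_row_rejected(self):
        with pytest.raises(ValueError):
            fit_cross_basis(np.ones((1, 3)), np.ones((1, 3)))


class TestEvaluateTestSpectrum:
    def test_in_sample_identity(self, rng):
        a = rng.standard_normal((20, 5))
        b = rng.standard_normal((20, 4))
        basis = fit_cross_basis(a, b)
        spec = evaluate_test_spectrum(basis, a, b)
        assert np.allclose(spec.values, basis.sigma_train, atol=1e-10)

    def test_matches_direct_assembly(self, rng):
        basis = fit_cross_basis(rng.standard_normal((30, 6)), rng.standard_normal((30, 5)))
        ta = rng.standard_normal((20, 6))
        tb = rng.standard_normal((20, 5))
        spec = evaluate_test_spectrum(basis, ta, tb)
        ca = ta - ta.mean(axis=0)
        cb = tb - tb.mean(axis=0)
        C_test = ca.T @ cb / 20
        assert np.allclose(spec.values, np.diag(basis.U.T @ C_test @ basis.V), atol=1e-10)

    def test_oracle_equivalence_many_instances(self, rng):
        """Fit + evaluate equals brute-force SVD and diag(U' C V), 50 instances."""
        for _ in range(50):
            n_tr = int(rng.integers(8, 20))
            n_te = int(rng.integers(4, 12))
            dx = int(rng.integers(2, 7))
            dy = int(rng.integers(2, 7))
            tr_a, tr_b = rng.standard_normal((n_tr, dx)), rng.standard_normal((n_tr, dy))
            te_a, te_b = rng.standard_normal((n_te, dx)), rng.standard_normal((n_te, dy))
            basis = fit_cross_basis(tr_a, tr_b)
            U, s, V = brute_force_basis(tr_a, tr_b)
            assert np.allclose(basis.sigma_train, s[: basis.K], atol=1e-10)
            ca = te_a - te_a.mean(axis=0)
            cb = te_b - te_b.mean(axis=0)
            C = ca.T @ cb / n_te
            got = evaluate_test_spectrum(basis, te_a, te_b).values
            want = np.diag(basis.U.T @ C @ basis.V)
            assert np.allclose(got, want, atol=1e-10)

    def test_shuffled_test_rows_have_zero_mean_spectrum(self, rng):
        basis = fit_cross_basis(rng.standard_normal((40, 4)), rng.standard_normal((40, 4)))
        ta = rng.standard_normal((16, 4))
        tb = rng.standard_normal((16, 4))
        draws = np.array(
            [
                evaluate_test_spectrum(basis, ta, tb[rng.permutation(16)]).values
                for _ in range(1000)
            ]
        )
        z = draws.mean(axis=0) / (draws.std(axis=0) / np.sqrt(len(draws)))
        assert np.all(np.abs(z) < 3)

    def test_scale_equivariance(self, rng):
        a = rng.standard_normal((24, 5))
        b = rng.standard_normal((24, 5))
        ta, tb = rng.standard_normal((10, 5)), rng.standard_normal((10, 5))
        base = evaluate_test_spectrum(fit_cross_basis(a, b), ta, tb).values
        scaled = evaluate_test_spectrum(fit_cross_basis(a * 3.5, b), ta * 3.5, tb).values
        assert np.allclose(scaled, 3.5 * base, atol=1e-9)

    def test_shape_mismatch_rejected(self, rng):
        basis = fit_cross_basis(rng.standard_normal((10, 3)), rng.standard_normal((10, 3)))
        with pytest.raises(ValueError, match="column counts"):
            evaluate_test_spectrum(basis, rng.standard_normal((5, 4)), rng.standard_normal((5, 3)))


class TestOffdiagonalMass:
    def test_zero_in_sample(self, rng):
        a = rng.standard_normal((20, 4))
        b = rng.standard_normal((20, 4))
        basis = fit_cross_basis(a, b)
        assert offdiagonal_mass(basis, a, b) < 1e-10

    def test_decreases_with_sample_size(self):
        rng = np.random.default_rng(7)
        d = 6
        scale = np.linspace(2.0, 0.5, d)
        ratios = []
        for n in (100, 400, 1600):
            latents = rng.standard_normal((2 * n, d)) * scale
            x = latents + 0.3 * rng.standard_normal((2 * n, d))
            y = latents + 0.3 * rng.standard_normal((2 * n, d))
            basis = fit_cross_basis(x[:n], y[:n])
            ratios.append(offdiagonal_mass(basis, x[n:], y[n:]))
        assert ratios[2] < ratios[0]

    def test_independent_test_side_near_one(self, rng):
        basis = fit_cross_basis(rng.standard_normal((50, 8)), rng.standard_normal((50, 8)))
        ratio = offdiagonal_mass(basis, rng.standard_normal((40, 8)), rng.standard_normal((40, 8)))
        assert ratio > 0.8


class TestNormalizeByChannels:
    def test_equal_channel_counts(self):
        spec = FoldSpectrum(fold_index=0, values=np.array([10.0, 5.0]))
        out = normalize_by_channels(spec, 5, 5)
        assert np.allclose(out.values, [2.0, 1.0])
        assert out.normalized

    def test_geometric_mean_of_unequal_counts(self):
        spec = FoldSpectrum(fold_index=0, values=np.array([400.0]))
        assert np.allclose(normalize_by_channels(spec, 100, 400).values, [2.0])

    def test_double_normalization_rejected(self):
        spec = FoldSpectrum(fold_index=0, values=np.ones(2), normalized=True)
        with pytest.raises(ValueError, match="already"):
            normalize_by_channels(spec, 2, 2)

    def test_zscored_training_spectrum_sums_to_one(self, rng):
        rs = zscore_channels(make_response_set(rng.standard_normal((100, 30))))
        basis = fit_cross_basis(rs.values, rs.values)
        total = basis.sigma_train.sum() / np.sqrt(rs.n_channels * rs.n_channels)
        assert abs(total - 1.0) < 1e-9


class TestEstimatorVariants:
    def test_self_crossdecomp_reproduces_pca_eigenvalues(self, rng):
        rs = make_response_set(rng.standard_normal((30, 6)))
        basis = fit_cross_basis(rs.values, rs.values)
        assert np.allclose(basis.sigma_train, pca_spectrum(rs), atol=1e-10)

    def test_pca_matches_eigen_oracle(self, rng):
        rs = make_response_set(rng.standard_normal((10, 4)))
        centered = rs.values - rs.values.mean(axis=0)
        eig = np.sort(np.linalg.eigvalsh(centered.T @ centered / 10))[::-1]
        assert np.allclose(pca_spectrum(rs), eig, atol=1e-10)

    def test_noise_free_trials_make_all_estimators_agree(self, rng):
        rs = make_response_set(rng.standard_normal((40, 5)))
        pca = pca_spectrum(rs)
        cv = cvpca_spectrum(rs, rs).values
        basis = fit_cross_basis(rs.values, rs.values)
        assert np.allclose(pca, cv, atol=1e-10)
        assert np.allclose(pca, basis.sigma_train, atol=1e-10)

    def test_estimator_ordering_under_noise(self):
        """PCA >= cvPCA at low ranks; cvPCA >= cross-decomposition at high ranks."""
        rng = np.random.default_rng(21)
        n, d = 400, 24
        signal = rng.standard_normal((n, d)) @ np.diag(np.linspace(2, 0.2, d))
        t1 = make_response_set(signal + rng.standard_normal((n, d)))
        t2 = make_response_set(signal + rng.standard_normal((n, d)))
        pca = pca_spectrum(t1)
        cv = cvpca_spectrum(t1, t2).values
        folds = make_folds(t1.stimulus_ids, 4, seed=0)
        xd_folds = within_system_spectrum(t1, t2, folds)
        K = min(len(s.values) for s in xd_folds)
        xd = np.mean([s.values[:K] for s in xd_folds], axis=0) * d  # undo normalization
        low = slice(0, 5)
        assert np.all(pca[low] >= cv[low] - 1e-9)
        high = slice(K - 8, K)
        assert cv[high].mean() > xd[high].mean()

    def test_rotation_invariance_of_functional_estimator(self, small_ensemble, small_folds):
        _, sets, _ = small_ensemble
        (x1, x2), (y1, y2) = sets
        base = between_system_spectrum(x1, x2, y1, y2, small_folds)
        Q = np.linalg.qr(np.random.default_rng(0).standard_normal((48, 48)))[0]
        import dataclasses

        rot = [dataclasses.replace(rs, values=rs.values @ Q) for rs in (y1, y2)]
        rotated = between_system_spectrum(x1, x2, rot[0], rot[1], small_folds)
        for s0, s1 in zip(base, rotated):
            assert np.allclose(s0.values, s1.values, atol=1e-8)

    def test_between_reduces_to_within_for_identical_copies(self, small_ensemble, small_folds):
        _, sets, _ = small_ensemble
        x1, x2 = sets[0]
        within = within_system_spectrum(x1, x2, small_folds)
        between = between_system_spectrum(x1, x2, x1, x2, small_folds)
        for w, b in zip(within, between):
            assert np.allclose(w.values, b.values, atol=1e-12)

    def test_between_symmetric_under_trial_swap(self, small_ensemble, small_folds):
        _, sets, _ = small_ensemble
        (x1, x2), (y1, y2) = sets
        a = between_system_spectrum(x1, x2, y1, y2, small_folds)
        b = between_system_spectrum(x2, x1, y1, y2, small_folds)
        for s0, s1 in zip(a, b):
            assert np.allclose(s0.values, s1.values, atol=1e-12)

    def test_noise_free_rotated_subjects_between_equals_within(self):
        from crossdecomp import SyntheticConfig, generate_ensemble

        cfg = SyntheticConfig(
            n_subjects=2, n_stimuli=96, n_channels=24, n_latent=24,
            shared_fraction=1.0, noise_sd=0.0, zscore=False, seed=4,
        )
        sets, _ = generate_ensemble(cfg)
        (x1, x2), (y1, y2) = sets
        folds = make_folds(x1.stimulus_ids, 4, seed=0)
        within = within_system_spectrum(x1, x2, folds)
        between = between_system_spectrum(x1, x2, y1, y2, folds)
        for w, b in zip(within, between):
            assert np.allclose(w.values, b.values, atol=1e-8)


class TestAnatomicalSpectrum:
    def test_identity_embeddings_match_functional(self, rng):
        n, d = 80, 12
        signal = rng.standard_normal((n, d))
        x1 = make_response_set(signal, subject="x")
        x2 = make_response_set(signal.copy(), subject="x")
        y1 = make_response_set(signal.copy(), subject="y")
        y2 = make_response_set(signal.copy(), subject="y")
        folds = make_folds(x1.stimulus_ids, 4, seed=1)
        anat = anatomical_spectrum(x1, x2, y1, y2, folds)
        func = between_system_spectrum(x1, x2, y1, y2, folds)
        for a, f in zip(anat, func):
            assert np.allclose(a.values, f.values, atol=1e-8)

    def test_channel_permutation_kills_anatomical_not_functional(self, rng):
        import dataclasses

        n, d = 320, 64
        Q = np.linalg.qr(rng.standard_normal((d, d)))[0]
        signal = rng.standard_normal((n, d)) @ np.diag(np.linspace(2, 0.5, d)) @ Q
        noise = lambda: 0.2 * rng.standard_normal((n, d))
        x1 = make_response_set(signal + noise(), subject="x")
        x2 = make_response_set(signal + noise(), subject="x", trial=2)
        # y is a channel-permuted copy of x: same data, shuffled channel axes
        perm = rng.permutation(d)
        y1 = dataclasses.replace(x1, values=x1.values[:, perm], subject_id="y")
        y2 = dataclasses.replace(x2, values=x2.values[:, perm], subject_id="y")
        folds = make_folds(x1.stimulus_ids, 4, seed=2)
        func_base = np.mean(
            [s.values for s in between_system_spectrum(x1, x2, x1, x2, folds)], axis=0
        )
        anat = np.mean([s.values for s in anatomical_spectrum(x1, x2, y1, y2, folds)], axis=0)
        func = np.mean([s.values for s in between_system_spectrum(x1, x2, y1, y2, folds)], axis=0)
        # functional alignment absorbs the channel permutation exactly
        assert np.allclose(func, func_base, atol=1e-8)
        # anatomical correspondence is destroyed
        assert func[:4].sum() > 10 * abs(anat[:4].sum())

    def test_mismatched_channel_space_rejected(self, small_ensemble, small_folds, rng):
        _, sets, _ = small_ensemble
        (x1, x2), (y1, y2) = sets
        import dataclasses

        y1 = dataclasses.replace(y1, channel_ids=np.array([f"other{i}" for i in range(48)]))
        with pytest.raises(ValueError, match="common channel space"):
            anatomical_spectrum(x1, x2, y1, y2, small_folds)
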