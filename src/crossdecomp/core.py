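"""Cross-validated cross-decomposition of shared covariance spectra.

The estimator characterizes the spectrum of reliable stimulus-related
variance shared between two high-dimensional response sets X (n × d_X) and
Y (n × d_Y).  On a training split it computes the SVD of the cross-covariance

    cov(X_train, Y_train) = (1/n) X_trainᵀ Y_train = U Σ_train Vᵀ,

which is the Procrustes / PLS-SVD alignment used by hyperalignment: U and V
rotate each system into a shared latent space.  On held-out stimuli the
covariance is re-evaluated along those fixed latent dimensions,

    Σ̂_k(X, Y) = diag( cov(X_test U, Y_test V) ),

giving a *signed* spectrum: a latent dimension whose training covariance
does not generalize has expected test value 0, which is what makes
permutation-null calibration possible.

All covariances use the 1/n convention.  The test-stage quantity is the
sample covariance of the projections (their column means are subtracted), so
a permutation of the held-out stimulus correspondence has a null
distribution centered *exactly* at zero, and the expected spectrum under
independent test sides is exactly zero as well.

Comparison estimators (plain PCA and cross-validated PCA) are provided for
contrast; they answer different statistical questions (total variance, and
repeat reliability without generalization to new stimuli, respectively) and
their spectral decays are not directly comparable to cross-decomposition.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .data_io import FoldPlan, ResponseSet

__all__ = [
    "AlignedBasis",
    "FoldSpectrum",
    "fit_cross_basis",
    "evaluate_test_spectrum",
    "offdiagonal_mass",
    "normalize_by_channels",
    "within_system_spectrum",
    "between_system_spectrum",
    "anatomical_spectrum",
    "pca_spectrum",
    "cvpca_spectrum",
]


@dataclasses.dataclass
class AlignedBasis:
    """Rotation pair (U, V) and training singular values from one train split."""

    U: np.ndarray  # (d_X, K), orthonormal columns
    V: np.ndarray  # (d_Y, K), orthonormal columns
    sigma_train: np.ndarray  # (K,), nonnegative, nonincreasing
    mean_a: np.ndarray  # (d_X,) train column means of side A
    mean_b: np.ndarray  # (d_Y,) train column means of side B
    n_train: int
    K: int


@dataclasses.dataclass
class FoldSpectrum:
    """Signed spectrum evaluated on one held-out fold, ranks 1..K."""

    fold_index: int
    values: np.ndarray  # (K,)
    normalized: bool = False


def fit_cross_basis(train_a: np.ndarray, train_b: np.ndarray) -> AlignedBasis:
    """Learn the shared latent basis from a training split.

    Both matrices are centered by their own column means; the SVD of the
    1/n-scaled cross-covariance is truncated to
    ``K = min(d_X, d_Y, n_train − 1)`` (centering removes one degree of
    freedom).  Signs are fixed jointly per (u_k, v_k) pair so training
    singular values stay nonnegative and the largest-magnitude element of
    u_k is positive.
    """
    train_a = np.asarray(train_a, dtype=np.float64)
    train_b = np.asarray(train_b, dtype=np.float64)
    n = train_a.shape[0]
    if train_b.shape[0] != n:
        raise ValueError("training matrices must have equal row counts")
    if n < 2:
        raise ValueError("need at least 2 training rows")
    mean_a = train_a.mean(axis=0)
    mean_b = train_b.mean(axis=0)
    cross = (train_a - mean_a).T @ (train_b - mean_b) / n
    U, sigma, Vt = np.linalg.svd(cross, full_matrices=False)
    K = min(train_a.shape[1], train_b.shape[1], n - 1)
    U, sigma, V = U[:, :K], sigma[:K], Vt[:K].T
    # joint sign convention: flipping (u_k, v_k) together leaves sigma >= 0
    flip = np.sign(U[np.abs(U).argmax(axis=0), np.arange(K)])
    flip[flip == 0] = 1.0
    return AlignedBasis(
        U=U * flip,
        V=V * flip,
        sigma_train=sigma,
        mean_a=mean_a,
        mean_b=mean_b,
        n_train=n,
        K=K,
    )


def _projections(
    basis: AlignedBasis,
    test_a: np.ndarray,
    test_b: np.ndarray,
    swap_projections: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Center test rows with train means and project into the latent space."""
    test_a = np.asarray(test_a, dtype=np.float64)
    test_b = np.asarray(test_b, dtype=np.float64)
    if test_a.shape[1] != basis.U.shape[0] or test_b.shape[1] != basis.V.shape[0]:
        raise ValueError(
            f"test column counts ({test_a.shape[1]}, {test_b.shape[1]}) do not "
            f"match basis ({basis.U.shape[0]}, {basis.V.shape[0]})"
        )
    if test_a.shape[0] != test_b.shape[0] or test_a.shape[0] < 2:
        raise ValueError("test matrices need equal row counts >= 2")
    proj_a, proj_b = (basis.V, basis.U) if swap_projections else (basis.U, basis.V)
    A = (test_a - basis.mean_a) @ proj_a
    B = (test_b - basis.mean_b) @ proj_b
    # sample covariance of the projections: subtract their own column means,
    # which centers the permutation null exactly at zero
    return A - A.mean(axis=0), B - B.mean(axis=0)


def evaluate_test_spectrum(
    basis: AlignedBasis,
    test_a: np.ndarray,
    test_b: np.ndarray,
    fold_index: int = 0,
    swap_projections: bool = False,
) -> FoldSpectrum:
    """Signed held-out spectrum: diagonal of cov(X_test U, Y_test V).

    The covariance is the 1/n sample covariance of the two projection
    matrices.  In-sample (test = train) this reproduces the training
    singular values exactly; on independent test sides every entry has
    expectation zero.  With ``swap_projections=True`` the rotations are exchanged at test time
    (X_test projected onto V and Y_test onto U) — the anatomical-alignment
    variant, meaningful only when the two channel spaces correspond.
    """
    A, B = _projections(basis, test_a, test_b, swap_projections)
    values = (A * B).sum(axis=0) / A.shape[0]
    return FoldSpectrum(fold_index=fold_index, values=values)


def offdiagonal_mass(basis: AlignedBasis, test_a, test_b) -> float:
    """Diagnostic: off-diagonal Frobenius mass of the projected covariance.

    Returns ‖offdiag‖_F / ‖full‖_F for cov(X_test U, Y_test V); 0 when the
    projected covariance is exactly diagonal (e.g. in-sample), near 1 when
    the diagonal carries no special mass.
    """
    A, B = _projections(basis, test_a, test_b)
    M = A.T @ B / A.shape[0]
    total = np.linalg.norm(M)
    if total == 0:
        return 0.0
    off = M - np.diag(np.diag(M))
    return float(np.linalg.norm(off) / total)


def normalize_by_channels(spec: FoldSpectrum, d_x: int, d_y: int) -> FoldSpectrum:
    """Divide the spectrum by the geometric mean sqrt(d_X · d_Y).

    After this normalization the training spectrum of fully z-scored data
    cumulatively sums to 1, making spectra comparable across regions of
    different channel counts.
    """
    if spec.normalized:
        raise ValueError("spectrum is already channel-normalized")
    scale = float(np.sqrt(d_x * d_y))
    return FoldSpectrum(
        fold_index=spec.fold_index, values=spec.values / scale, normalized=True
    )


def _check_paired(*sets: ResponseSet) -> np.ndarray:
    first = sets[0].stimulus_ids
    for rs in sets[1:]:
        if not np.array_equal(rs.stimulus_ids, first):
            raise ValueError(
                "response sets must be paired on an identical ordered stimulus list"
            )
    return first


def _fold_spectra_pair(
    a: ResponseSet,
    b: ResponseSet,
    folds: FoldPlan,
    swap_projections: bool = False,
) -> list[FoldSpectrum]:
    stim = _check_paired(a, b)
    out = []
    for fold in range(1, folds.n_folds + 1):
        test = folds.test_mask(stim, fold)
        basis = fit_cross_basis(a.values[~test], b.values[~test])
        spec = evaluate_test_spectrum(
            basis, a.values[test], b.values[test], fold_index=fold,
            swap_projections=swap_projections,
        )
        out.append(normalize_by_channels(spec, a.n_channels, b.n_channels))
    return out


def within_system_spectrum(
    trial1: ResponseSet, trial2: ResponseSet, folds: FoldPlan
) -> list[FoldSpectrum]:
    """Cross-validated spectrum between two trials of the same system.

    For each fold, the basis is learned on the remaining folds of the two
    trial repetitions and evaluated on the held-out fold, so the estimate
    reflects variance that is reliable across repeats *and* generalizes to
    new stimuli.  Returns one channel-normalized :class:`FoldSpectrum` per
    fold.
    """
    return _fold_spectra_pair(trial1, trial2, folds)


def _average_fold_lists(
    lists: list[list[FoldSpectrum]]
) -> list[FoldSpectrum]:
    out = []
    for specs in zip(*lists):
        K = min(len(s.values) for s in specs)
        values = np.mean([s.values[:K] for s in specs], axis=0)
        out.append(
            FoldSpectrum(
                fold_index=specs[0].fold_index,
                values=values,
                normalized=specs[0].normalized,
            )
        )
    return out


def _order_trials(t1: ResponseSet, t2: ResponseSet) -> tuple[ResponseSet, ResponseSet]:
    """Canonical trial order (by trial_index), so argument order is irrelevant."""
    if t1.trial_index != t2.trial_index:
        return (t1, t2) if t1.trial_index < t2.trial_index else (t2, t1)
    return t1, t2


def between_system_spectrum(
    x1: ResponseSet,
    x2: ResponseSet,
    y1: ResponseSet,
    y2: ResponseSet,
    folds: FoldPlan,
) -> list[FoldSpectrum]:
    """Symmetrized between-system spectrum.

    Trial ordering within a system is arbitrary, so the spectrum is the
    average over the two cross-trial pairings:
    Σ̂_k(X,Y) = ½ [Σ̂_k(X1,Y2) + Σ̂_k(X2,Y1)].  Trials are put in canonical
    order by their ``trial_index`` first, making the result insensitive to
    swapping the trial arguments of either system.  The same estimator
    serves between-subject and between-region comparisons.
    """
    _check_paired(x1, x2, y1, y2)
    x1, x2 = _order_trials(x1, x2)
    y1, y2 = _order_trials(y1, y2)
    return _average_fold_lists(
        [_fold_spectra_pair(x1, y2, folds), _fold_spectra_pair(x2, y1, folds)]
    )


def anatomical_spectrum(
    x1: ResponseSet,
    x2: ResponseSet,
    y1: ResponseSet,
    y2: ResponseSet,
    folds: FoldPlan,
) -> list[FoldSpectrum]:
    """Between-system spectrum under assumed channel-for-channel alignment.

    Identical to :func:`between_system_spectrum` except the rotation
    matrices are exchanged at test time: if channels truly correspond across
    systems, one system's latent dimensions should generalize to the other.
    Requires both systems to live in the same ordered channel space.
    """
    if x1.n_channels != y1.n_channels or not (
        np.array_equal(x1.channel_ids, y1.channel_ids)
    ):
        raise ValueError(
            "anatomical mode requires a common channel space: both systems must "
            "have identical, identically ordered channel ids"
        )
    _check_paired(x1, x2, y1, y2)
    x1, x2 = _order_trials(x1, x2)
    y1, y2 = _order_trials(y1, y2)
    return _average_fold_lists(
        [
            _fold_spectra_pair(x1, y2, folds, swap_projections=True),
            _fold_spectra_pair(x2, y1, folds, swap_projections=True),
        ]
    )


def pca_spectrum(x: ResponseSet) -> np.ndarray:
    """Eigenvalues of the self-covariance (signal plus noise), descending.

    Plain PCA has no cross-validation: it reports *all* variance along each
    principal axis, which is why its spectrum decays more slowly than the
    cross-validated estimators on noisy data.
    """
    centered = x.values - x.values.mean(axis=0)
    n = x.n_stimuli
    sigma = np.linalg.svd(centered / np.sqrt(n), compute_uv=False)
    K = min(x.n_channels, n - 1)
    return (sigma**2)[:K]


def cvpca_spectrum(x1: ResponseSet, x2: ResponseSet) -> FoldSpectrum:
    """Cross-validated PCA: repeat reliability along trial-1 principal axes.

    Eigenvectors are learned from the trial-1 covariance over the *full*
    stimulus set and the spectrum is the diagonal of the covariance between
    both trials' projections on the same stimuli.  This measures reliability
    across repetitions but — by construction — not generalization to new
    stimuli, which is what distinguishes it from cross-decomposition.
    """
    _check_paired(x1, x2)
    a = x1.values - x1.values.mean(axis=0)
    b = x2.values - x2.values.mean(axis=0)
    n = a.shape[0]
    _, _, Wt = np.linalg.svd(a / np.sqrt(n), full_matrices=False)
    K = min(x1.n_channels, n - 1)
    W = Wt[:K].T
    values = ((a @ W) * (b @ W)).sum(axis=0) / n
    return FoldSpectrum(fold_index=0, values=values)
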