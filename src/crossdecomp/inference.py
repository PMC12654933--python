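"""Permutation-null calibration of cross-validated spectra.

Because a latent dimension with no generalizing shared variance has expected
test covariance 0, an empirical null is obtained by shuffling the stimulus
correspondence of the *held-out* rows only: the basis (U, V) is learned
exactly as in the observed analysis, but Y_test's rows are permuted before
projection,

    Σ_permuted(X, Y) = cov(X_test U, Y_test^permuted V).

Repeating this (default N = 5000) and passing each permuted spectrum through
the identical binning/fold-averaging pipeline yields a null ensemble whose
68th/95th/99th percentile curves calibrate how far the observed spectrum
lies above chance, and per-bin one-sided p-values with the add-one
convention p = (1 + #{null ≥ observed}) / (N + 1).
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .core import AlignedBasis, FoldSpectrum, _projections, fit_cross_basis
from .data_io import FoldPlan, ResponseSet
from .spectra import BinnedSpectrum, BinScheme, bin_spectrum

__all__ = [
    "NullEnsemble",
    "permuted_spectrum",
    "build_null_ensemble",
    "flag_significance",
]

PERCENTILES = (68.0, 95.0, 99.0)


@dataclasses.dataclass
class NullEnsemble:
    """Permutation distribution of binned, fold-averaged spectra."""

    n_perms: int
    seed: int
    bin_center: np.ndarray
    spectra: np.ndarray  # (n_perms, n_bins) fold-averaged binned null spectra
    percentiles: dict[float, np.ndarray]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"bin_center": self.bin_center})
        for q in sorted(self.percentiles):
            df[f"p{q:g}"] = self.percentiles[q]
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def permuted_spectrum(
    basis: AlignedBasis,
    test_a: np.ndarray,
    test_b: np.ndarray,
    permutation: np.ndarray,
    fold_index: int = 0,
) -> FoldSpectrum:
    """Held-out spectrum with ``test_b``'s rows reordered by ``permutation``."""
    permutation = np.asarray(permutation)
    n = np.asarray(test_b).shape[0]
    if sorted(permutation.tolist()) != list(range(n)):
        raise ValueError("permutation must be a bijection on test rows")
    A, B = _projections(basis, test_a, test_b)
    values = (A * B[permutation]).sum(axis=0) / n
    return FoldSpectrum(fold_index=fold_index, values=values)


def build_null_ensemble(
    pairs: list[tuple[ResponseSet, ResponseSet]],
    folds: FoldPlan,
    scheme: BinScheme,
    n_perms: int = 5000,
    seed: int = 0,
    normalize: bool = True,
    swap_projections: bool = False,
    chunk: int = 500,
) -> NullEnsemble:
    """Null ensemble for the pipeline defined by ``pairs``/``folds``/``scheme``.

    ``pairs`` lists the (A, B) trial pairs averaged by the observed estimator:
    one pair for a within-system analysis, two for the symmetrized
    between-system analysis.  For each permutation, every held-out fold of
    every pair gets an independent row shuffle of side B; the permuted
    spectra then follow the identical binning and fold/pair averaging as the
    observed spectrum.  Deterministic given ``seed``.
    """
    if n_perms < 100:
        warnings.warn(
            f"n_perms={n_perms} < 100: percentile estimates will be unstable",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    accum = None  # (n_perms, n_bins) running sum over pairs and folds
    n_terms = 0
    centers = None
    for a, b in pairs:
        stim = a.stimulus_ids
        norm = np.sqrt(a.n_channels * b.n_channels) if normalize else 1.0
        for fold in range(1, folds.n_folds + 1):
            test = folds.test_mask(stim, fold)
            basis = fit_cross_basis(a.values[~test], b.values[~test])
            A, B = _projections(
                basis, a.values[test], b.values[test], swap_projections
            )
            n_test = A.shape[0]
            perms = np.array([rng.permutation(n_test) for _ in range(n_perms)])
            fold_binned = []
            for start in range(0, n_perms, chunk):
                block = perms[start : start + chunk]
                # (P, K) signed spectra for this fold, all permutations at once
                S = np.einsum("ik,pik->pk", A, B[block]) / n_test / norm
                spec = FoldSpectrum(fold_index=fold, values=S[0])
                c, _, _ = bin_spectrum(spec, scheme)
                members = _member_matrix(scheme, S.shape[1])
                fold_binned.append(S @ members)
                if centers is None:
                    centers = c
            fold_binned = np.vstack(fold_binned)
            if accum is None:
                accum = np.zeros((n_perms, fold_binned.shape[1]))
            nb = min(accum.shape[1], fold_binned.shape[1])
            accum = accum[:, :nb] + fold_binned[:, :nb]
            n_terms += 1
    spectra = accum / n_terms
    percentiles = {
        q: np.percentile(spectra, q, axis=0) for q in PERCENTILES
    }
    return NullEnsemble(
        n_perms=n_perms,
        seed=seed,
        bin_center=centers[: spectra.shape[1]],
        spectra=spectra,
        percentiles=percentiles,
    )


def _member_matrix(scheme: BinScheme, K: int) -> np.ndarray:
    """(K, n_bins) averaging matrix mapping rank values to bin means."""
    members = scheme.members(K)
    M = np.zeros((K, len(members)))
    for j, m in enumerate(members):
        M[m - 1, j] = 1.0 / len(m)
    return M


def flag_significance(
    observed: BinnedSpectrum, null: NullEnsemble, alpha: float = 0.001
) -> BinnedSpectrum:
    """Per-bin one-sided permutation p-values and significance flags.

    p = (1 + #{null mean ≥ observed mean}) / (n_perms + 1); a bin is
    significant iff p < alpha.  Raises if alpha is unattainable for the
    ensemble size (alpha < 1/(n_perms+1)).
    """
    if alpha < 1.0 / (null.n_perms + 1):
        raise ValueError(
            f"alpha={alpha} unattainable with n_perms={null.n_perms}; "
            f"minimum possible p is {1.0 / (null.n_perms + 1):.2e}"
        )
    nb = min(observed.n_bins, len(null.bin_center))
    if not np.allclose(observed.bin_center[:nb], null.bin_center[:nb]):
        raise ValueError("observed spectrum and null ensemble bin schemes differ")
    exceed = (null.spectra[:, :nb] >= observed.mean[:nb]).sum(axis=0)
    p = np.full(observed.n_bins, np.nan)
    p[:nb] = (1.0 + exceed) / (null.n_perms + 1.0)
    return dataclasses.replace(
        observed, p_value=p, significant=p < alpha
    )
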