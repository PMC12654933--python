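"""Log-binning, fold aggregation, power-law fits, and spectral correlation.

High-rank latent dimensions are individually noisy; averaging spectra within
rank bins of exponentially increasing width trades spectral resolution for
signal-to-noise and is what allows scale-free behavior to be detected over
several orders of magnitude.  The default scheme spans ranks 1..10^4 with 11
bins (≈ 3 bins per decade).  Each fold's spectrum is binned first, then bins
are averaged across folds; dispersion across folds gives the error bars.

The spectral correlation coefficient

    r_k(X, Y) = Σ_k(X, Y) / [Σ_k(X1, X2)^{1/2} · Σ_k(Y1, Y2)^{1/2}]

normalizes the between-system spectrum by the geometric mean of the two
within-system spectra, giving the fraction of each system's reliable
variance at rank k that is shared with the other.  Being a ratio it is
noisier than the spectra themselves and is aggregated over wider bins
(default 2 per decade).
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .core import FoldSpectrum

__all__ = [
    "BinScheme",
    "BinnedSpectrum",
    "SpectralCorrelation",
    "PowerLawFit",
    "make_log_bins",
    "default_bins",
    "wide_bins",
    "bin_spectrum",
    "aggregate_folds",
    "binned_spectrum",
    "spectral_correlation",
    "fit_power_law",
]


@dataclasses.dataclass
class BinScheme:
    """Geometric rank bins.

    Rank ``k`` belongs to bin ``j`` iff ``edges[j] <= k < edges[j+1]``; the
    last bin is right-inclusive.  Bins that contain no integer rank over the
    construction range have been dropped.
    """

    edges: np.ndarray  # strictly increasing, edges[0] == k_min

    @property
    def n_bins(self) -> int:
        return len(self.edges) - 1

    def members(self, k_max: int) -> list[np.ndarray]:
        """Integer ranks per bin, truncated at ``k_max``; empty bins dropped."""
        ranks = np.arange(1, k_max + 1)
        out = []
        for j in range(self.n_bins):
            lo, hi = self.edges[j], self.edges[j + 1]
            if j == self.n_bins - 1:
                mask = (ranks >= lo) & (ranks <= hi)
            else:
                mask = (ranks >= lo) & (ranks < hi)
            if mask.any():
                out.append(ranks[mask])
        return out


@dataclasses.dataclass
class BinnedSpectrum:
    """Fold-averaged log-binned spectrum with per-bin dispersion."""

    bin_center: np.ndarray  # geometric mean of member ranks
    mean: np.ndarray  # average over folds of per-fold bin means
    sd: np.ndarray  # population sd across folds
    n_ranks: np.ndarray  # member ranks per bin
    fold_values: np.ndarray  # (n_folds, n_bins) per-fold bin means
    p_value: np.ndarray | None = None
    significant: np.ndarray | None = None

    @property
    def n_bins(self) -> int:
        return len(self.bin_center)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "bin_center": self.bin_center,
                "mean": self.mean,
                "sd": self.sd,
                "n_ranks": self.n_ranks,
            }
        )
        df["p_value"] = self.p_value if self.p_value is not None else np.nan
        df["significant"] = (
            self.significant if self.significant is not None else pd.NA
        )
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclasses.dataclass
class SpectralCorrelation:
    """Per-(wide-)bin spectral correlation r with validity and dispersion."""

    bin_center: np.ndarray
    r: np.ndarray  # nan where invalid
    valid: np.ndarray  # both within-denominators strictly positive
    sd: np.ndarray  # across-fold dispersion of per-fold r
    low_signal: np.ndarray  # between-mean < 3 fold-sds above zero

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_center": self.bin_center,
                "r": self.r,
                "valid": self.valid,
                "sd": self.sd,
                "low_signal": self.low_signal,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclasses.dataclass
class PowerLawFit:
    """Log-log OLS fit: mean ≈ amplitude · bin_center^exponent."""

    exponent: float
    amplitude: float
    fit_range: tuple[float, float]
    n_points: int


def make_log_bins(k_min: int, k_max: int, per_decade: float) -> BinScheme:
    """Geometrically spaced bins spanning ranks ``k_min..k_max``.

    The number of bins is ``round(per_decade · log10(k_max/k_min))``; edges
    are geometric between the end points.  Edges whose bin would contain no
    integer rank are dropped with a warning.
    """
    if not (1 <= k_min < k_max):
        raise ValueError("need 1 <= k_min < k_max")
    if per_decade <= 0:
        raise ValueError("per_decade must be positive")
    n_bins = max(1, round(per_decade * np.log10(k_max / k_min)))
    edges = np.geomspace(k_min, k_max, n_bins + 1)
    # drop edges that create integer-empty bins
    keep = [0]
    ranks = np.arange(k_min, k_max + 1)
    for j in range(1, len(edges)):
        lo = edges[keep[-1]]
        hi = edges[j]
        inclusive = j == len(edges) - 1
        mask = (ranks >= lo) & ((ranks <= hi) if inclusive else (ranks < hi))
        if mask.any():
            keep.append(j)
        else:
            warnings.warn(
                f"dropping empty bin [{lo:.3g}, {hi:.3g}) with no integer rank",
                stacklevel=2,
            )
    return BinScheme(edges=edges[keep])


def default_bins() -> BinScheme:
    """The standard scheme: ranks 1..10^4, 11 bins (~3 per decade)."""
    return make_log_bins(1, 10_000, per_decade=2.75)


def wide_bins() -> BinScheme:
    """Wider bins for ratio statistics such as r_k: 2 per decade over 1..10^4."""
    return make_log_bins(1, 10_000, per_decade=2.0)


def bin_spectrum(
    spec: FoldSpectrum, scheme: BinScheme
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Bin one fold's spectrum: (bin centers, bin means, member counts).

    Bin value is the arithmetic mean of member-rank values; bin center is the
    geometric mean of member ranks.  Bins beyond the spectrum's length are
    dropped.
    """
    K = len(spec.values)
    members = scheme.members(K)
    centers = np.array([np.exp(np.mean(np.log(m))) for m in members])
    means = np.array([spec.values[m - 1].mean() for m in members])
    counts = np.array([len(m) for m in members])
    return centers, means, counts


def aggregate_folds(binned: list[tuple[np.ndarray, np.ndarray, np.ndarray]]) -> BinnedSpectrum:
    """Average per-fold binned values; sd is the population sd across folds.

    Folds may differ in retained rank count by one near a bin edge; only the
    bins common to all folds are aggregated.
    """
    if len(binned) < 1:
        raise ValueError("need at least one fold")
    n_bins = min(len(b[0]) for b in binned)
    fold_values = np.stack([b[1][:n_bins] for b in binned])
    centers = binned[0][0][:n_bins]
    counts = binned[0][2][:n_bins]
    if len(binned) == 1:
        sd = np.full(n_bins, np.nan)
    else:
        sd = fold_values.std(axis=0)  # population convention
    return BinnedSpectrum(
        bin_center=centers,
        mean=fold_values.mean(axis=0),
        sd=sd,
        n_ranks=counts,
        fold_values=fold_values,
    )


def binned_spectrum(
    fold_spectra: list[FoldSpectrum], scheme: BinScheme
) -> BinnedSpectrum:
    """Bin each fold's spectrum, then aggregate across folds."""
    return aggregate_folds([bin_spectrum(s, scheme) for s in fold_spectra])


def spectral_correlation(
    between: BinnedSpectrum,
    within_a: BinnedSpectrum,
    within_b: BinnedSpectrum,
) -> SpectralCorrelation:
    """Spectral correlation r per bin from binned between/within spectra.

    All three spectra must be binned on the same (wide) scheme.  r is defined
    only where both within-system means are strictly positive; bins where the
    between-system mean is less than three across-fold standard deviations
    above zero are flagged ``low_signal`` (open symbols in exports).
    """
    for other in (within_a, within_b):
        if between.n_bins != other.n_bins or not np.allclose(
            between.bin_center, other.bin_center
        ):
            raise ValueError("all three spectra must share one bin scheme")
    valid = (within_a.mean > 0) & (within_b.mean > 0)
    r = np.full(between.n_bins, np.nan)
    r[valid] = between.mean[valid] / np.sqrt(
        within_a.mean[valid] * within_b.mean[valid]
    )
    # per-fold r, where that fold's denominators allow it
    denom = within_a.fold_values * within_b.fold_values
    with np.errstate(invalid="ignore", divide="ignore"):
        fold_r = np.where(
            denom > 0, between.fold_values / np.sqrt(np.abs(denom)), np.nan
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        sd = np.nanstd(fold_r, axis=0)
    low_signal = between.mean < 3 * between.sd
    return SpectralCorrelation(
        bin_center=between.bin_center,
        r=r,
        valid=valid,
        sd=sd,
        low_signal=low_signal,
    )


def fit_power_law(
    bs: BinnedSpectrum, fit_range: tuple[float, float] | None = None
) -> PowerLawFit:
    """Unweighted OLS of log10(bin mean) on log10(bin center).

    Only bins with strictly positive means inside ``fit_range`` (inclusive,
    default: all bins) enter the fit; negative bins of the signed estimator
    are excluded.  The exponent is the log-log slope (e.g. −1.6 for a
    k^−1.6 spectrum).
    """
    if fit_range is None:
        fit_range = (bs.bin_center.min(), bs.bin_center.max())
    lo, hi = fit_range
    mask = (bs.bin_center >= lo) & (bs.bin_center <= hi) & (bs.mean > 0)
    if mask.sum() < 3:
        raise ValueError(
            f"need >= 3 positive bins in range {fit_range}, got {int(mask.sum())}"
        )
    slope, intercept = np.polyfit(
        np.log10(bs.bin_center[mask]), np.log10(bs.mean[mask]), deg=1
    )
    return PowerLawFit(
        exponent=float(slope),
        amplitude=float(10**intercept),
        fit_range=fit_range,
        n_points=int(mask.sum()),
    )
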