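"""Gabor filter-bank encoding model with ridge LOOCV.

A classic V1-style energy model: quadrature pairs of Gabor filters

    g(x, y; σ, γ, f, θ, ψ) = exp(−(x′² + γ² y′²) / (2σ²)) · cos(2π f x′ + ψ),
    x′ = x cosθ + y sinθ,   y′ = −x sinθ + y cosθ,

in relative image coordinates (square image side = 1, center at (0, 0)).
The feature space concatenates simple-cell responses of each "odd" (ψ = 0)
and "even" (ψ = π/2) filter with the complex-cell "energy" odd² + even².
The default bank — 3 scales × 3 frequencies × 8 orientations × 8×8 positions
— comprises 4,608 quadrature pairs and 13,824 features.

Channel responses are predicted from z-scored features by L2-regularized
regression; the shrinkage parameter is chosen per channel by closed-form
leave-one-out cross-validation (hat-matrix identity, no refitting loop) over
30 values log-spaced from 1e4 to 1e8.

The printed frequency rule f ∈ {0.25, 0.5, 0.75}·σ is dimensionally unusual
(frequencies normally scale as 1/σ); both conventions are available through
``GaborBankConfig.frequency_convention`` with the literal multiply-by-sigma
reading as default.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .data_io import FoldPlan, ResponseSet
from .spectra import BinnedSpectrum, BinScheme, binned_spectrum

__all__ = [
    "GaborParams",
    "GaborBankConfig",
    "GaborBank",
    "FeatureMatrix",
    "RidgeFit",
    "gabor_kernel",
    "build_bank",
    "extract_features",
    "ridge_loocv",
    "model_vs_neural_spectrum",
    "cumulative_variance_curve",
]


@dataclasses.dataclass
class GaborParams:
    """One Gabor filter in relative image coordinates."""

    x: float
    y: float
    sigma: float
    gamma: float
    f: float
    theta: float
    psi: float

    def __post_init__(self) -> None:
        if self.sigma <= 0 or self.gamma <= 0 or self.f <= 0:
            raise ValueError("sigma, gamma and f must be positive")


@dataclasses.dataclass
class GaborBankConfig:
    """Bank enumeration parameters; defaults give 4,608 pairs."""

    scales: tuple[float, ...] = (0.025, 0.050, 0.075)
    aspect_ratios: tuple[float, ...] = (1.0,)
    freq_multipliers: tuple[float, ...] = (0.25, 0.5, 0.75)
    frequency_convention: str = "multiply"  # f = m*sigma; "divide": f = m/sigma
    n_orientations: int = 8
    grid_size: int = 8
    grid_extent: float = 0.45  # positions uniform in [-extent, extent]
    resolution: int = 128  # raster resolution in pixels

    def frequency(self, multiplier: float, sigma: float) -> float:
        if self.frequency_convention == "multiply":
            return multiplier * sigma
        if self.frequency_convention == "divide":
            return multiplier / sigma
        raise ValueError(
            f"unknown frequency_convention {self.frequency_convention!r}"
        )


@dataclasses.dataclass
class GaborBank:
    """Enumerated quadrature pairs (phase-free parameter sets)."""

    config: GaborBankConfig
    pairs: list[GaborParams]  # psi field unused; one entry per quadrature pair

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def n_features(self) -> int:
        return 3 * self.n_pairs


@dataclasses.dataclass
class FeatureMatrix:
    """Stimuli × features matrix with per-feature metadata."""

    values: np.ndarray  # (n_stimuli, 3 * n_pairs)
    kinds: np.ndarray  # "odd" | "even" | "energy" per column
    pair_index: np.ndarray  # quadrature-pair index per column
    zscored: bool


@dataclasses.dataclass
class RidgeFit:
    """Per-target ridge solutions with LOOCV-chosen shrinkage."""

    weights: np.ndarray  # (n_features, n_targets)
    chosen_shrinkage: np.ndarray  # (n_targets,)
    loo_mse: np.ndarray  # (n_shrinkage, n_targets)
    shrinkage_grid: np.ndarray

    def predict(self, features: np.ndarray) -> np.ndarray:
        return features @ self.weights


def gabor_kernel(p: GaborParams, resolution: int) -> np.ndarray:
    """Rasterize one Gabor filter on the relative-coordinate pixel grid.

    Pixel centers span (−0.5, 0.5) on both axes; entry [i, j] is the filter
    value at (x = coords[j], y = coords[i]).  No truncation window and no
    norm normalization (downstream feature z-scoring absorbs scale).
    """
    if resolution < 8:
        raise ValueError("resolution must be >= 8")
    coords = (np.arange(resolution) + 0.5) / resolution - 0.5
    xg, yg = np.meshgrid(coords, coords)
    dx = xg - p.x
    dy = yg - p.y
    xp = dx * np.cos(p.theta) + dy * np.sin(p.theta)
    yp = -dx * np.sin(p.theta) + dy * np.cos(p.theta)
    envelope = np.exp(-(xp**2 + p.gamma**2 * yp**2) / (2 * p.sigma**2))
    return envelope * np.cos(2 * np.pi * p.f * xp + p.psi)


def build_bank(cfg: GaborBankConfig | None = None) -> GaborBank:
    """Enumerate all scale × frequency × orientation × position combinations."""
    cfg = cfg or GaborBankConfig()
    thetas = np.arange(cfg.n_orientations) * np.pi / cfg.n_orientations
    positions = np.linspace(-cfg.grid_extent, cfg.grid_extent, cfg.grid_size)
    pairs = [
        GaborParams(x=x, y=y, sigma=s, gamma=g, f=cfg.frequency(m, s), theta=t, psi=0.0)
        for s in cfg.scales
        for g in cfg.aspect_ratios
        for m in cfg.freq_multipliers
        for t in thetas
        for y in positions
        for x in positions
    ]
    return GaborBank(config=cfg, pairs=pairs)


def extract_features(
    images: np.ndarray, bank: GaborBank, zscore: bool = True
) -> FeatureMatrix:
    """Gabor feature matrix for a stack of square grayscale images.

    Odd (ψ=0) and even (ψ=π/2) simple-cell responses are inner products of
    each image with the rasterized kernels (at the images' own resolution);
    energy = odd² + even².  Features are then z-scored (population sd)
    across the provided stimulus set.
    """
    images = np.asarray(images, dtype=np.float64)
    if images.ndim != 3 or images.shape[1] != images.shape[2]:
        raise ValueError("images must be a (n, side, side) square grayscale stack")
    n, side, _ = images.shape
    flat = images.reshape(n, -1)
    odd = np.empty((n, bank.n_pairs))
    even = np.empty((n, bank.n_pairs))
    for j, p in enumerate(bank.pairs):
        k_odd = gabor_kernel(dataclasses.replace(p, psi=0.0), side)
        k_even = gabor_kernel(dataclasses.replace(p, psi=np.pi / 2), side)
        odd[:, j] = flat @ k_odd.ravel()
        even[:, j] = flat @ k_even.ravel()
    energy = odd**2 + even**2
    values = np.concatenate([odd, even, energy], axis=1)
    kinds = np.array(
        ["odd"] * bank.n_pairs + ["even"] * bank.n_pairs + ["energy"] * bank.n_pairs
    )
    pair_index = np.tile(np.arange(bank.n_pairs), 3)
    if zscore:
        sd = values.std(axis=0)
        dead = np.flatnonzero(sd == 0)
        if dead.size:
            raise ValueError(
                f"zero-variance feature columns across the stimulus set: "
                f"{dead[:20].tolist()}"
            )
        values = (values - values.mean(axis=0)) / sd
    return FeatureMatrix(
        values=values, kinds=kinds, pair_index=pair_index, zscored=zscore
    )


def ridge_loocv(
    features: np.ndarray,
    targets: np.ndarray,
    shrinkage_grid: np.ndarray | None = None,
) -> RidgeFit:
    """Ridge regression with closed-form leave-one-out shrinkage selection.

    Solves min ‖y − Xw‖² + λ‖w‖² (no intercept: features are expected
    z-scored and targets centered).  LOO errors come from the hat-matrix
    identity e_i = (y_i − ŷ_i)/(1 − h_ii), evaluated for every λ on the grid
    from one SVD of X; the chosen λ minimizes the mean squared LOO error per
    target and final weights are refit on all rows.
    """
    X = np.asarray(features, dtype=np.float64)
    Y = np.atleast_2d(np.asarray(targets, dtype=np.float64).T).T
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least 3 rows for leave-one-out selection")
    if shrinkage_grid is None:
        shrinkage_grid = np.logspace(4, 8, 30)
    grid = np.asarray(shrinkage_grid, dtype=np.float64)
    if grid.size == 0 or np.any(np.diff(grid) <= 0) or grid[0] <= 0:
        raise ValueError("shrinkage grid must be positive and strictly increasing")
    Q, s, Rt = np.linalg.svd(X, full_matrices=False)
    QtY = Q.T @ Y
    Q2 = Q**2
    loo = np.empty((grid.size, Y.shape[1]))
    for i, lam in enumerate(grid):
        c = s**2 / (s**2 + lam)
        fitted = Q @ (c[:, None] * QtY)
        h = Q2 @ c
        resid = (Y - fitted) / (1.0 - h)[:, None]
        loo[i] = np.mean(resid**2, axis=0)
    best = loo.argmin(axis=0)
    weights = np.empty((X.shape[1], Y.shape[1]))
    for t in range(Y.shape[1]):
        lam = grid[best[t]]
        weights[:, t] = Rt.T @ (s / (s**2 + lam) * QtY[:, t])
    return RidgeFit(
        weights=weights,
        chosen_shrinkage=grid[best],
        loo_mse=loo,
        shrinkage_grid=grid,
    )


def cumulative_variance_curve(bs: BinnedSpectrum) -> np.ndarray:
    """Normalized running sum of positive binned variance contributions.

    Each bin contributes (bin mean clipped at 0) × (member rank count); the
    curve is the cumulative sum divided by the total, so it rises to 1.  A
    model whose shared variance saturates after few dimensions reaches 1
    earlier than the data's own curve.
    """
    contrib = np.clip(bs.mean, 0, None) * bs.n_ranks
    total = contrib.sum()
    if total == 0:
        return np.zeros_like(contrib)
    return np.cumsum(contrib) / total


def model_vs_neural_spectrum(
    neural_trial1: ResponseSet,
    model_trial2: ResponseSet,
    folds: FoldPlan,
    scheme: BinScheme,
) -> tuple[BinnedSpectrum, np.ndarray]:
    """Cross-decompose measured responses against model-predicted responses.

    ``model_trial2`` holds the encoding model's predictions in the neural
    channel space (e.g. ridge predictions of trial-2 responses from Gabor
    features).  Returns the binned spectrum of reliable variance shared
    between data and model, and its cumulative-variance curve.
    """
    from .core import within_system_spectrum

    if neural_trial1.n_channels != model_trial2.n_channels:
        raise ValueError(
            "model predictions must have the neural channel dimensionality"
        )
    fold_spectra = within_system_spectrum(neural_trial1, model_trial2, folds)
    bs = binned_spectrum(fold_spectra, scheme)
    return bs, cumulative_variance_curve(bs)
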