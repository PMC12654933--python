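"""Synthetic multi-subject response ensembles with known scale-free structure.

The generator emulates the statistical skeleton of large visual-neuroimaging
datasets — several subjects viewing the same stimuli over repeated trials —
with fully known ground truth, so every estimator in the package can be
validated without any data download:

* shared zero-mean Gaussian latent signals whose variances decay as a power
  law in rank, λ_k ∝ k^(−α) (α = 1.6 by default, the decay observed for
  within-subject visual-cortex spectra);
* per-subject private latents with the same variance profile, mixed in with
  weight ``1 − shared_fraction`` so that ``shared_fraction`` is directly the
  expected between-subject spectral correlation r at every rank;
* subject-specific random orthonormal channel embeddings, optionally with a
  leading block of ``n_aligned_latents`` columns common to all subjects —
  the synthetic analogue of coarse anatomical correspondence (≈10 dimensions
  by default);
* independent white trial noise per channel, followed by per-channel
  z-scoring.

Defaults mirror the emulated study conditions: 766 shared stimuli, 2 trials,
2 subjects, 512 channels, full-rank latents, unit-scale trial noise.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .data_io import ResponseSet, zscore_channels

__all__ = [
    "SyntheticConfig",
    "SyntheticGroundTruth",
    "generate_ensemble",
    "expected_spectra",
    "generate_test_images",
]


@dataclasses.dataclass
class SyntheticConfig:
    """Generator parameters; defaults are the emulated study conditions."""

    n_subjects: int = 2
    n_trials: int = 2
    n_stimuli: int = 766
    n_channels: int = 512
    n_latent: int = 512  # K_true
    alpha: float = 1.6  # latent-variance power-law exponent
    shared_fraction: float = 0.8  # variance fraction common to all subjects
    n_aligned_latents: int = 10  # leading latents with shared channel loadings
    noise_sd: float = 1.0  # per-channel trial-noise sd (latents average unit variance)
    zscore: bool = True
    heavy_tailed: bool = False  # Student-t (df=3) latents instead of Gaussian
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_latent > self.n_channels:
            raise ValueError("n_latent must not exceed n_channels")
        if not (0 <= self.shared_fraction <= 1):
            raise ValueError("shared_fraction must lie in [0, 1]")
        if not (0 <= self.n_aligned_latents <= self.n_latent):
            raise ValueError("n_aligned_latents must lie in 0..n_latent")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")

    def latent_variances(self) -> np.ndarray:
        """λ_k ∝ k^(−α), normalized so the variances sum to n_latent."""
        lam = np.arange(1, self.n_latent + 1, dtype=np.float64) ** (-self.alpha)
        return lam * (self.n_latent / lam.sum())


@dataclasses.dataclass
class SyntheticGroundTruth:
    """Everything the generator knows, for recovery tests."""

    latent_variances: np.ndarray  # (K,)
    embeddings: list[np.ndarray]  # per subject, (d, K) orthonormal columns
    shared_fraction: float
    n_aligned_latents: int
    noise_sd: float
    expected_within: np.ndarray  # normalized-units expectation, see expected_spectra
    expected_between: np.ndarray


def _orthonormal_embedding(
    rng: np.random.Generator, d: int, K: int, aligned: np.ndarray | None
) -> np.ndarray:
    """Random (d, K) orthonormal embedding with optional fixed leading block."""
    if aligned is None or aligned.shape[1] == 0:
        Q, _ = np.linalg.qr(rng.standard_normal((d, K)))
        return Q
    m = aligned.shape[1]
    rest = rng.standard_normal((d, K - m))
    rest -= aligned @ (aligned.T @ rest)
    Q, _ = np.linalg.qr(rest)
    return np.concatenate([aligned, Q], axis=1)


def expected_spectra(cfg: SyntheticConfig) -> dict[str, np.ndarray]:
    """Closed-form expected spectra in the pipeline's output units.

    The pipeline z-scores channels (expected per-channel variance
    Σλ/d + noise_sd²) and divides spectra by the channel count, so the
    expected *normalized* within-subject spectrum is
    λ_k / (Σλ + d·noise_sd²); the between-subject expectation is
    ``shared_fraction`` times that (trial noise cancels in expectation in
    both).  ``latent_variances`` carries the raw λ_k for reference.

    With z-scoring the uniform-rescaling approximation degrades when a few
    leading latents dominate per-channel variance (their realized channel
    loadings make the per-channel scale heterogeneous); with
    ``zscore=False`` the expectations are exact up to estimator shrinkage.
    """
    lam = cfg.latent_variances()
    scale = lam.sum() + cfg.n_channels * cfg.noise_sd**2
    if not cfg.zscore:
        scale = cfg.n_channels  # only the sqrt(d·d) normalization applies
    within = lam / scale
    return {
        "latent_variances": lam,
        "within": within,
        "between": cfg.shared_fraction * within,
    }


def generate_ensemble(
    cfg: SyntheticConfig,
) -> tuple[list[list[ResponseSet]], SyntheticGroundTruth]:
    """Draw the full ensemble: ``sets[subject][trial]`` plus ground truth.

    Stimulus-level latents are fixed across trials within a subject; each
    trial adds independent white channel noise.  Deterministic given
    ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    lam = cfg.latent_variances()
    sd = np.sqrt(lam)
    n, d, K = cfg.n_stimuli, cfg.n_channels, cfg.n_latent

    def draw_latents() -> np.ndarray:
        if cfg.heavy_tailed:
            df = 3.0
            t = rng.standard_t(df, size=(n, K))
            return t / np.sqrt(df / (df - 2)) * sd
        return rng.standard_normal((n, K)) * sd

    z_shared = draw_latents()
    aligned = None
    if cfg.n_aligned_latents > 0:
        aligned, _ = np.linalg.qr(
            rng.standard_normal((d, cfg.n_aligned_latents))
        )
    embeddings = [
        _orthonormal_embedding(rng, d, K, aligned) for _ in range(cfg.n_subjects)
    ]
    stimulus_ids = np.array([f"s{i:06d}" for i in range(n)])
    channel_ids = np.array([f"c{i:05d}" for i in range(d)])

    sets: list[list[ResponseSet]] = []
    exp = expected_spectra(cfg)
    for subj in range(cfg.n_subjects):
        z_priv = draw_latents()
        z = (
            np.sqrt(cfg.shared_fraction) * z_shared
            + np.sqrt(1 - cfg.shared_fraction) * z_priv
        )
        signal = z @ embeddings[subj].T
        trials = []
        for trial in range(cfg.n_trials):
            noise = cfg.noise_sd * rng.standard_normal((n, d))
            rs = ResponseSet(
                subject_id=f"sub{subj + 1:02d}",
                region_id="synthetic",
                trial_index=trial + 1,
                stimulus_ids=stimulus_ids,
                channel_ids=channel_ids,
                values=signal + noise,
            )
            if cfg.zscore:
                rs = zscore_channels(rs)
            trials.append(rs)
        sets.append(trials)
    truth = SyntheticGroundTruth(
        latent_variances=lam,
        embeddings=embeddings,
        shared_fraction=cfg.shared_fraction,
        n_aligned_latents=cfg.n_aligned_latents,
        noise_sd=cfg.noise_sd,
        expected_within=exp["within"],
        expected_between=exp["between"],
    )
    return sets, truth


def generate_test_images(
    kind: str, count: int, resolution: int = 64, seed: int = 0
) -> np.ndarray:
    """Procedural image stacks for encoding-model tests.

    ``"gratings"``: full-field sinusoidal gratings with random orientation
    (uniform on [0, π)), spatial frequency (2–8 cycles per image) and phase.
    ``"bandlimited-noise"``: white noise band-pass filtered in the Fourier
    domain to an annulus of 2–12 cycles per image.  Deterministic given
    ``seed``.
    """
    rng = np.random.default_rng(seed)
    coords = (np.arange(resolution) + 0.5) / resolution - 0.5
    xg, yg = np.meshgrid(coords, coords)
    if kind == "gratings":
        images = np.empty((count, resolution, resolution))
        for i in range(count):
            theta = rng.uniform(0, np.pi)
            freq = rng.uniform(2, 8)
            phase = rng.uniform(0, 2 * np.pi)
            images[i] = np.cos(
                2 * np.pi * freq * (xg * np.cos(theta) + yg * np.sin(theta)) + phase
            )
        return images
    if kind == "bandlimited-noise":
        fx = np.fft.fftfreq(resolution) * resolution
        radius = np.sqrt(fx[None, :] ** 2 + fx[:, None] ** 2)
        annulus = (radius >= 2) & (radius <= 12)
        white = rng.standard_normal((count, resolution, resolution))
        filtered = np.fft.ifft2(np.fft.fft2(white) * annulus).real
        return filtered / filtered.std(axis=(1, 2), keepdims=True)
    raise ValueError(f"unknown image kind {kind!r}")
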