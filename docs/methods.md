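# Methods

This note records the statistical model behind `crossdecomp`, the
conventions and defaults the implementation commits to, and what the
synthetic validation does and does not establish.

## The cross-decomposition estimator

Two response sets X ∈ ℝ^{n×d_X}, Y ∈ ℝ^{n×d_Y} are rows-by-stimuli,
columns-by-channels. Stimuli are split into folds (default 8; 7 train : 1
test). On the training folds, both matrices are centered by their own
column means and the SVD of the 1/n-scaled cross-covariance is taken:

    (1/n) X_cᵀ Y_c = U Σ_train Vᵀ.

Training singular values are nonnegative and conflate stimulus-related and
noise variance. The cross-validated spectrum is evaluated on the held-out
fold as the diagonal of the *sample covariance* of the projections X_test U
and Y_test V (1/n convention; the projections' own column means are
subtracted). This detail matters: subtracting the projection means makes
the permutation null (shuffling the held-out rows of one side) centered at
exactly zero, and leaves the in-sample identity intact — evaluating on the
training data returns Σ_train to machine precision, because the training
projections are already mean-zero. Under independent test sides every
entry of the spectrum has expectation zero. Test values are *signed*.

Conventions and edge cases:

- Covariance scaling is 1/n (not 1/(n−1)) throughout, so the training
  spectrum of fully z-scored data sums exactly to d (or to 1 after channel
  normalization).
- Retained rank count K = min(d_X, d_Y, n_train − 1); centering removes one
  degree of freedom.
- SVD signs are fixed jointly per (u_k, v_k) pair — training singular
  values stay nonnegative and the largest-magnitude element of u_k is made
  positive for reproducibility. Signs cancel in all spectra.
- Ordering among exactly tied singular values is implementation-defined
  (NumPy's LAPACK order); tests avoid exact ties.
- An all-zero cross-covariance yields a zero spectrum, not an error.

Estimator variants:

- *Within-system*: the two sides are two trial repetitions of one system,
  so the spectrum reflects variance reliable across repeats that also
  generalizes to new stimuli.
- *Between-system* (subjects or regions): symmetrized over the two
  cross-trial pairings, ½[Σ̂(X1,Y2) + Σ̂(X2,Y1)]. Trials are put in
  canonical order by trial index first, so the result is invariant to
  argument order.
- *Anatomical*: identical fit, but U and V are exchanged at test time. If
  channels truly correspond one-to-one across systems, either rotation
  should work; the gap between functional and anatomical spectra therefore
  measures how much of the shared code is *not* channel-aligned. Requires
  an identical ordered channel space.
- *PCA* and *cvPCA* are included as contrasts only. PCA reports all
  variance. cvPCA projects both trials onto the trial-1 principal axes over
  the full stimulus set — reliability across repeats without a held-out
  stimulus split, which is precisely what distinguishes it from
  cross-decomposition; its exponents are not comparable to ours.

## Binning, fold aggregation, power-law fits

Per-rank estimates at high rank are individually noisy, so each fold's
spectrum is averaged within geometric rank bins first, then bins are
averaged across folds. The default scheme spans ranks 1..10⁴ with 12
geometric edges → 11 bins (≈2.75 per decade); rank k falls in bin j iff
edge_j ≤ k < edge_{j+1} (last bin right-inclusive), and bins containing no
integer rank are dropped with a warning. Bin centers are geometric means of
member ranks. Across-fold dispersion uses the population (divide-by-m)
convention, consistent with the covariance scaling; at 8 folds it differs
from the sample convention by √(8/7).

Power-law indices are unweighted OLS slopes of log10(bin mean) against
log10(bin center) over strictly positive bins in a chosen rank range.
Negative bins (legal for the signed estimator) are retained in exports but
excluded from fits. The recovery harness fits over ranks 2–200: two orders
of magnitude, excluding the leading bin, whose average over ranks {1,2} of
a convex power law sits above the line and would bias the slope.

## Spectral correlation r_k

r_k = Σ_k(X,Y) / [Σ_k(X1,X2)^½ Σ_k(Y1,Y2)^½], computed from binned
spectra on a common *wide* scheme (default 2 bins per decade — ratios are
noisier than spectra). r is defined only where both within-system means are
strictly positive; bins whose between-system mean is under three
across-fold standard deviations are flagged low-signal (rendered as open
symbols in exports). r is invariant to common rescaling and to orthonormal
rotation of either system's channel space.

## Permutation inference

The null ensemble re-runs the identical pipeline (same folds, bins,
normalization, pair-averaging) with the held-out rows of side B shuffled
independently per fold and permutation; N = 5000 by default. Percentile
envelopes at 68/95/99 describe the null spread per bin; per-bin one-sided
p-values use the add-one convention p = (1 + #{null ≥ obs})/(N + 1), so
p < 0.001 requires N ≥ 999. The test is one-sided (shared signal is a
positive covariance by construction); the null is symmetric, so this is
conservative for negative bins. No multiple-testing correction is applied
across bins — flags are per-bin at fixed level.

## Gabor encoding baseline

Quadrature pairs g(x,y) = exp(−(x′² + γ²y′²)/(2σ²))·cos(2πf x′ + ψ) on
relative image coordinates (square side 1, center (0,0)). Default bank:
3 scales σ ∈ {0.025, 0.050, 0.075}, γ = 1, 3 frequencies per scale, 8
orientations uniform on [0, π), 8×8 centers in [−0.45, 0.45]² → 4,608
pairs; features are odd (ψ=0) and even (ψ=π/2) simple-cell responses plus
the quadrature energy odd² + even², 13,824 columns, z-scored across the
stimulus set. The frequency rule f ∈ {0.25, 0.5, 0.75}·σ is dimensionally
unusual (frequency normally scales as 1/σ: the literal reading gives
sub-one-cycle filters); both conventions are implemented behind
`GaborBankConfig.frequency_convention`, defaulting to the literal
multiply-by-sigma form. Rasterization is at the images' own resolution
(config default 128 px), full-image support, no kernel normalization
(feature z-scoring absorbs scale).

Encoding fits are ridge regressions without intercept on z-scored features
and centered targets; the shrinkage parameter is selected per channel by
closed-form leave-one-out error (hat-matrix identity from one SVD — no
refit loop) over 30 values log-spaced 10⁴..10⁸, then refit on all training
rows. The no-intercept convention is what makes the closed form equal the
explicit refit-per-row oracle exactly. Model quality is summarized by
cross-decomposing measured trial-1 responses against model-predicted
trial-2 responses and plotting the cumulative normalized variance of the
positive binned contributions; low-dimensional models saturate early.

## RSA baseline and the low-rank control

RSMs are Pearson correlations between single-trial stimulus patterns;
two systems are compared by correlating the strictly upper triangles
(Pearson or Spearman — the diagonal is uninformative and inflates
agreement). The control reconstructs one side from its first 10 principal
components: because RSA is variance-weighted, this drastic reduction moves
the RSA correlation by ≲0.05 on scale-free data even though the reduced
data share no reliable variance beyond rank ≈10 — demonstrated jointly
with the cross-decomposition significance flags in the test suite.
Bootstrap dispersion resamples 90% of stimuli without repetition (default
5,000 resamples; 2 sd error bars).

## Synthetic generator

`generate_ensemble` emulates the skeleton of a multi-subject visual
experiment: shared zero-mean Gaussian latents with λ_k ∝ k^(−α) (sum
normalized to K), per-subject private latents with the same profile mixed
at weight 1 − shared_fraction (so shared_fraction is directly the expected
r at every rank), per-subject random orthonormal embeddings whose leading
`n_aligned_latents` columns are common to all subjects, independent white
trial noise, then per-channel z-scoring. Defaults mirror the emulated
study conditions: 2 subjects × 2 trials × 766 stimuli × 512 channels,
full-rank latents, α = 1.6, shared_fraction = 0.8, 10 aligned latents,
unit trial-noise sd (per-channel SNR ≈ 1, the regime of single-trial
fMRI betas). Latents are Gaussian by default (a Student-t option exists
but is off); trial noise is white — no spatial autocorrelation, session
drift, or hemodynamics.

Closed-form expectations: in raw units the expected within spectrum is
λ_k (trial noise cancels in expectation) and the between spectrum is
shared_fraction·λ_k; in pipeline units (z-scored channels, √(d_X d_Y)
normalization) these become λ_k/(Σλ + d·noise²). The z-scored form assumes
uniform per-channel rescaling, which degrades when a few leading latents
dominate per-channel variance; convergence tests therefore run in raw
units, where the form is exact up to estimator shrinkage.

## Known finite-sample behaviors and problem sizes

- *Shrinkage bias*: with finite training data the estimated rotations are
  noisy, so held-out covariance along them underestimates the true shared
  variance, more strongly at high rank. The bias vanishes as n grows; the
  exponent-recovery harness uses 4,096 stimuli × 512 channels at low noise,
  where fitted indices land within ±0.15 of truth for α ∈ {1.0, 1.6, 2.0}.
- *Alignment-boundary mixing*: with a smooth power law there is no spectral
  gap at the aligned/unaligned boundary (λ_10 ≈ λ_11), and one SVD supplies
  both subjects' rotations, so the estimated singular vectors just beyond
  rank 10 mix finitely sampled aligned latents *identically on both sides* —
  genuine, generalizing anatomically shared variance of order 1/n. A second
  genuine term comes from random overlap between the subjects' unaligned
  embedding columns (~K/d per direction), whose detection strength grows
  with test power. As a result, in the alignment comparison (anatomical
  significance confined to the bin containing rank 10, functional spectra
  significant well beyond it) the single *transition* bin just past rank 10
  sits near the permutation-detection threshold at the default study
  conditions, while all later bins are robustly at chance. The test suite
  asserts the property at the generator defaults with a fixed seed; a hard
  bin-boundary reading of "shared variance up to ≈10 dimensions" should be
  understood as fuzzy by about one transition bin, for the reasons above.
- *Null-ensemble cost* scales linearly in permutations and folds; the
  implementation permutes pre-projected test blocks, so N = 5000 on
  hundreds of stimuli runs in seconds.
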