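# crossdecomp

Cross-validated cross-decomposition of the covariance spectra shared between
high-dimensional neural response sets.

## The problem

Large neural recordings — fMRI betas, multi-unit spiking, calcium imaging —
give an *n* stimuli × *d* channels response matrix per trial. A central
question is how stimulus-related variance is distributed across latent
dimensions: is the population code effectively low-dimensional, or does
reliable signal extend across the full spectrum (a *scale-free*, power-law
decay)? And are those latent dimensions *shared* between individuals, or
merely statistically similar? Standard tools fall short: PCA mixes signal
with noise, cross-validated PCA (cvPCA) measures repeat reliability but not
generalization to new stimuli, and variance-weighted similarity measures
like RSA are dominated by the first handful of dimensions.

`crossdecomp` implements a spectral estimator that addresses both
questions, together with its full inference machinery and the baselines it
is compared against. It is aimed at researchers analyzing stimulus × channel
response matrices from any pair of "systems" — two trials of one subject,
two subjects, two brain regions, or data versus an encoding model.

## The estimator

Given paired response matrices X (n × d_X) and Y (n × d_Y), split stimuli
into folds. On the training folds, take the SVD of the cross-covariance

    cov(X_train, Y_train) = (1/n) X_trainᵀ Y_train = U Σ_train Vᵀ,

the Procrustes / PLS-SVD alignment used by hyperalignment: U and V rotate
each system into a shared latent space. Then evaluate, on held-out stimuli,
the *signed* covariance along each latent dimension k:

    Σ̂_k(X, Y) = diag( cov(X_test U, Y_test V) ).

A dimension whose training covariance does not generalize has expected test
value 0, so permutation of the held-out stimulus correspondence yields an
exactly centered null. The pipeline around the estimator provides:

- 8-fold cross-validation with fold-averaged spectra;
- logarithmic rank bins (11 bins over ranks 1..10⁴, ≈3 per decade) to pool
  signal-to-noise at high ranks;
- channel-count normalization by √(d_X·d_Y), making the training spectrum
  sum to 1 for z-scored data;
- permutation nulls (N = 5000) with 68/95/99th percentile envelopes and
  per-bin one-sided p-values;
- power-law (log-log OLS) exponent fits;
- the spectral correlation coefficient
  r_k = Σ_k(X,Y) / [Σ_k(X1,X2)^½ Σ_k(Y1,Y2)^½], the fraction of each
  system's reliable variance at rank k that is shared with the other;
- an *anatomical* variant (U and V exchanged at test time) that quantifies
  how far channel-for-channel correspondence alone carries;
- baselines: PCA, cvPCA, a Gabor quadrature-pair energy model with ridge
  LOOCV encoding, and RSA with a low-rank (10-PC) control;
- a synthetic generator with known power-law latent structure
  (λ_k ∝ k^(−α)) for end-to-end validation of every estimator.

## Worked example

Two synthetic subjects sharing 80% of their latent variance through
different channel embeddings, α = 1.6, 766 stimuli × 128 channels, two
trials each:

```python
import numpy as np
import crossdecomp as cd

cfg = cd.SyntheticConfig(
    n_subjects=2, n_stimuli=766, n_channels=128, n_latent=128,
    alpha=1.6, shared_fraction=0.8, noise_sd=0.3, seed=0,
)
sets, truth = cd.generate_ensemble(cfg)
(x1, x2), (y1, y2) = sets

folds = cd.make_folds(x1.stimulus_ids, n_folds=8, seed=0)
scheme = cd.default_bins()

within = cd.binned_spectrum(cd.within_system_spectrum(x1, x2, folds), scheme)
fit = cd.fit_power_law(within, fit_range=(2, 200))
print("bin means   :", [f"{v:.2e}" for v in within.mean])
print(f"power-law exponent over ranks 2-200: {fit.exponent:.2f}")

between = cd.binned_spectrum(cd.between_system_spectrum(x1, x2, y1, y2, folds), cd.wide_bins())
wa = cd.binned_spectrum(cd.within_system_spectrum(x1, x2, folds), cd.wide_bins())
wb = cd.binned_spectrum(cd.within_system_spectrum(y1, y2, folds), cd.wide_bins())
r = cd.spectral_correlation(between, wa, wb)
print("r per wide bin:", np.round(r.r, 2))

ens = cd.build_null_ensemble([(x1, x2)], folds, scheme, n_perms=1000, seed=1)
flagged = cd.flag_significance(within, ens, alpha=0.001)
print("significant bins (p < 0.001):", flagged.significant.astype(int))
```

Output:

```
bin means   : ['2.12e-01', '5.73e-02', '1.84e-02', '4.86e-03', '1.17e-03', '2.93e-04']
power-law exponent over ranks 2-200: -1.65
r per wide bin: [0.79 0.78 0.76 0.69 0.58]
significant bins (p < 0.001): [1 1 1 1 1 1]
```

The binned within-subject spectrum decays close to the generative power law
(fitted index −1.65 for a k^−1.6 ground truth); every rank bin carries
reliable variance at p < 0.001 against 1000 permutations; and the
between-subject spectral correlation sits near the generating
shared-fraction of 0.8, drifting down at high ranks where estimation noise
bites first.

The same analyses run from the shell: `crossdecomp simulate`, `spectrum`,
`null`, `correlation`, `rsa`, and `gabor` subcommands read/write the HDF5
and CSV containers described in the module docstrings (`crossdecomp --help`).

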