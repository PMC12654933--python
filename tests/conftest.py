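import numpy as np
import pytest

from crossdecomp import ResponseSet, SyntheticConfig, generate_ensemble, make_folds


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_response_set(values, subject="subA", trial=1, region="roi"):
    values = np.asarray(values, dtype=float)
    n, d = values.shape
    return ResponseSet(
        subject_id=subject,
        region_id=region,
        trial_index=trial,
        stimulus_ids=np.array([f"s{i:04d}" for i in range(n)]),
        channel_ids=np.array([f"c{i:04d}" for i in range(d)]),
        values=values,
    )


@pytest.fixture
def small_ensemble():
    """Two subjects, two trials, modest power-law structure; session-scale."""
    cfg = SyntheticConfig(
        n_subjects=2,
        n_trials=2,
        n_stimuli=160,
        n_channels=48,
        n_latent=48,
        alpha=1.6,
        shared_fraction=0.8,
        n_aligned_latents=5,
        noise_sd=0.5,
        seed=99,
    )
    sets, truth = generate_ensemble(cfg)
    return cfg, sets, truth


@pytest.fixture
def small_folds(small_ensemble):
    _, sets, _ = small_ensemble
    return make_folds(sets[0][0].stimulus_ids, n_folds=8, seed=5)
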