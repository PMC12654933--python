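"""Representational similarity analysis and the low-rank control.

RSA summarizes a response set by the n × n matrix of Pearson correlations
between stimulus patterns (RSM) and compares two systems by correlating
their RSMs' strictly upper triangles.  Being variance-weighted, RSA is
dominated by the leading latent dimensions: reducing one system to its 10
leading principal components leaves the RSA correlation nearly unchanged
even though the reduction destroys all higher-rank shared structure — the
control implemented by :func:`low_rank_reconstruct`.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import stats

from .data_io import ResponseSet

__all__ = [
    "RSM",
    "compute_rsm",
    "low_rank_reconstruct",
    "rsa_correlation",
    "bootstrap_rsa",
]


@dataclasses.dataclass
class RSM:
    """Pairwise stimulus pattern-similarity matrix (Pearson)."""

    values: np.ndarray  # (n, n), symmetric, unit diagonal
    stimulus_ids: np.ndarray
    method: str = "pearson"


def compute_rsm(rs: ResponseSet) -> RSM:
    """RSM entry (i, j) = Pearson correlation of stimulus i's and j's patterns."""
    if rs.n_channels < 2:
        raise ValueError("need at least 2 channels for pattern correlations")
    spread = rs.values.std(axis=1)
    dead = np.flatnonzero(spread == 0)
    if dead.size:
        raise ValueError(
            "zero-spread stimulus patterns: " + ", ".join(rs.stimulus_ids[dead][:20])
        )
    return RSM(values=np.corrcoef(rs.values), stimulus_ids=rs.stimulus_ids)


def low_rank_reconstruct(rs: ResponseSet, n_components: int) -> ResponseSet:
    """Reconstruct responses from their leading principal components.

    The centered data are projected onto the first ``n_components`` principal
    axes and mapped back, with the channel means added back in.
    """
    max_rank = min(rs.n_stimuli - 1, rs.n_channels)
    if not (1 <= n_components <= max_rank):
        raise ValueError(
            f"n_components must lie in 1..{max_rank}, got {n_components}"
        )
    mean = rs.values.mean(axis=0)
    centered = rs.values - mean
    U, s, Vt = np.linalg.svd(centered, full_matrices=False)
    low = U[:, :n_components] * s[:n_components] @ Vt[:n_components]
    return dataclasses.replace(rs, values=low + mean)


def _upper(values: np.ndarray) -> np.ndarray:
    return values[np.triu_indices_from(values, k=1)]


def rsa_correlation(a: RSM, b: RSM, method: str = "pearson") -> float:
    """Correlation of two RSMs' strictly upper triangles (Pearson or Spearman)."""
    if not np.array_equal(a.stimulus_ids, b.stimulus_ids):
        raise ValueError("RSMs must cover the same ordered stimulus set")
    ua, ub = _upper(a.values), _upper(b.values)
    if np.ptp(ua) == 0 or np.ptp(ub) == 0:
        raise ValueError("constant upper triangle: RSA correlation undefined")
    if method == "pearson":
        return float(stats.pearsonr(ua, ub).statistic)
    if method == "spearman":
        return float(stats.spearmanr(ua, ub).statistic)
    raise ValueError(f"unknown method {method!r}")


def bootstrap_rsa(
    a_data: ResponseSet,
    b_data: ResponseSet,
    n_boot: int = 5000,
    fraction: float = 0.9,
    seed: int = 0,
    method: str = "pearson",
) -> np.ndarray:
    """Bootstrap distribution of the RSA correlation under stimulus subsampling.

    For each resample, ``fraction`` of the stimuli are subsampled without
    repetition, both RSMs are recomputed on the subset, and their
    correlation recorded.  Report dispersion as 2 standard deviations of the
    returned distribution.  Deterministic given ``seed``.
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must lie in (0, 1]")
    if not np.array_equal(a_data.stimulus_ids, b_data.stimulus_ids):
        raise ValueError("response sets must share one ordered stimulus list")
    n = a_data.n_stimuli
    m = max(int(round(fraction * n)), 0)
    if m < 3:
        raise ValueError(f"subsample of {m} stimuli is too small (need >= 3)")
    rng = np.random.default_rng(seed)
    out = np.empty(n_boot)
    for i in range(n_boot):
        rows = np.sort(rng.choice(n, size=m, replace=False))
        sub_a = dataclasses.replace(
            a_data, stimulus_ids=a_data.stimulus_ids[rows], values=a_data.values[rows]
        )
        sub_b = dataclasses.replace(
            b_data, stimulus_ids=b_data.stimulus_ids[rows], values=b_data.values[rows]
        )
        out[i] = rsa_correlation(compute_rsm(sub_a), compute_rsm(sub_b), method)
    return out
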