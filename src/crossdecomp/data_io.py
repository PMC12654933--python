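"""Containers and plumbing for stimulus × channel response matrices.

A :class:`ResponseSet` holds one trial's responses of one subject (or one
region of interest) to an ordered list of stimuli: an ``n × d`` real matrix
whose rows are stimuli and whose columns are recording channels (voxels,
electrodes, model units).  The module also provides readers/writers for HDF5
and delimited-text containers, pairing of two response sets on their common
stimuli, cross-validation fold planning, and per-channel z-scoring.

Conventions
-----------
* Standard deviations are *population* standard deviations (divide by the
  number of rows), so that after z-scoring over the full set the trace of the
  channel covariance equals exactly ``d``.
* Stimulus pairing sorts the common stimuli lexicographically by identifier;
  downstream estimators are invariant to this choice.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "ResponseSet",
    "PairedResponses",
    "FoldPlan",
    "load_response_set",
    "save_response_set",
    "align_common_stimuli",
    "make_folds",
    "zscore_channels",
]


@dataclasses.dataclass
class ResponseSet:
    """One trial's ``n_stimuli × n_channels`` response matrix with identifiers."""

    subject_id: str
    region_id: str
    trial_index: int
    stimulus_ids: np.ndarray  # (n,) str
    channel_ids: np.ndarray  # (d,) str
    values: np.ndarray  # (n, d) float64

    def __post_init__(self) -> None:
        self.stimulus_ids = np.asarray(self.stimulus_ids, dtype=str)
        self.channel_ids = np.asarray(self.channel_ids, dtype=str)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.trial_index < 1:
            raise ValueError("trial_index must be a positive integer")
        n, d = self.values.shape
        if n < 2:
            raise ValueError(f"need at least 2 stimuli, got n={n}")
        if d < 1:
            raise ValueError("need at least 1 channel")
        if len(self.stimulus_ids) != n:
            raise ValueError(
                f"stimulus_ids length {len(self.stimulus_ids)} != n rows {n}"
            )
        if len(self.channel_ids) != d:
            raise ValueError(
                f"channel_ids length {len(self.channel_ids)} != d columns {d}"
            )
        if len(np.unique(self.stimulus_ids)) != n:
            raise ValueError("duplicate stimulus identifiers")
        if len(np.unique(self.channel_ids)) != d:
            raise ValueError("duplicate channel identifiers")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values contain missing or non-finite entries")

    @property
    def n_stimuli(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    def restrict_stimuli(self, stimulus_ids: np.ndarray) -> "ResponseSet":
        """Return a copy restricted to ``stimulus_ids`` in the order given."""
        index = {s: i for i, s in enumerate(self.stimulus_ids)}
        try:
            rows = np.array([index[s] for s in stimulus_ids])
        except KeyError as err:
            raise KeyError(f"stimulus {err} not present in response set") from err
        return dataclasses.replace(
            self,
            stimulus_ids=np.asarray(stimulus_ids, dtype=str).copy(),
            values=self.values[rows].copy(),
        )


@dataclasses.dataclass
class PairedResponses:
    """Two response sets restricted to an identical ordered stimulus list."""

    side_a: ResponseSet
    side_b: ResponseSet

    def __post_init__(self) -> None:
        if not np.array_equal(self.side_a.stimulus_ids, self.side_b.stimulus_ids):
            raise ValueError("paired sides must share an identical stimulus ordering")

    @property
    def stimulus_ids(self) -> np.ndarray:
        return self.side_a.stimulus_ids

    @property
    def n_stimuli(self) -> int:
        return self.side_a.n_stimuli


@dataclasses.dataclass
class FoldPlan:
    """Partition of stimuli into cross-validation folds.

    ``assignment`` maps each stimulus identifier to a fold index in
    ``1..n_folds``; fold sizes differ by at most one.
    """

    n_folds: int
    assignment: dict[str, int]
    seed: int

    def __post_init__(self) -> None:
        folds = np.array(sorted(self.assignment.values()))
        if folds.min() < 1 or folds.max() > self.n_folds:
            raise ValueError("fold indices must lie in 1..n_folds")
        sizes = np.bincount(folds, minlength=self.n_folds + 1)[1:]
        if sizes.max() - sizes.min() > 1:
            raise ValueError("fold sizes differ by more than 1")

    def test_mask(self, stimulus_ids: np.ndarray, fold: int) -> np.ndarray:
        """Boolean mask over ``stimulus_ids`` selecting the held-out fold."""
        return np.array([self.assignment[s] == fold for s in stimulus_ids])

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"stimulus_id": list(self.assignment), "fold": list(self.assignment.values())}
        ).to_csv(path, index=False)


def load_response_set(path: str | Path, layout: str = "hdf5") -> ResponseSet:
    """Read a :class:`ResponseSet` from an HDF5 or delimited-text container.

    Parameters
    ----------
    path:
        File to read.
    layout:
        ``"hdf5"`` for the HDF5 container (datasets ``values``,
        ``stimulus_ids``, ``channel_ids``; attributes ``subject_id``,
        ``region_id``, ``trial_index``), or ``"csv"`` / ``"tsv"`` for
        delimited text with a header row of channel ids and the stimulus id
        in the first column.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if layout == "hdf5":
        with h5py.File(path, "r") as f:
            for key in ("values", "stimulus_ids", "channel_ids"):
                if key not in f:
                    raise ValueError(f"malformed file {path}: missing dataset '{key}'")
            return ResponseSet(
                subject_id=str(f.attrs.get("subject_id", "")),
                region_id=str(f.attrs.get("region_id", "")),
                trial_index=int(f.attrs.get("trial_index", 1)),
                stimulus_ids=f["stimulus_ids"].asstr()[...],
                channel_ids=f["channel_ids"].asstr()[...],
                values=f["values"][...],
            )
    if layout in ("csv", "tsv"):
        sep = "," if layout == "csv" else "\t"
        df = pd.read_csv(path, sep=sep, index_col=0)
        if df.isna().any().any():
            raise ValueError(f"malformed file {path}: missing entries in 'values'")
        return ResponseSet(
            subject_id="",
            region_id="",
            trial_index=1,
            stimulus_ids=df.index.astype(str).to_numpy(),
            channel_ids=df.columns.astype(str).to_numpy(),
            values=df.to_numpy(dtype=np.float64),
        )
    raise ValueError(f"unknown layout {layout!r}")


def save_response_set(rs: ResponseSet, path: str | Path, layout: str = "hdf5") -> None:
    """Write ``rs`` in the layout that :func:`load_response_set` reads."""
    path = Path(path)
    if layout == "hdf5":
        with h5py.File(path, "w") as f:
            f.create_dataset("values", data=rs.values)
            f.create_dataset("stimulus_ids", data=rs.stimulus_ids.astype("S"))
            f.create_dataset("channel_ids", data=rs.channel_ids.astype("S"))
            f.attrs["subject_id"] = rs.subject_id
            f.attrs["region_id"] = rs.region_id
            f.attrs["trial_index"] = rs.trial_index
        return
    if layout in ("csv", "tsv"):
        sep = "," if layout == "csv" else "\t"
        df = pd.DataFrame(rs.values, index=rs.stimulus_ids, columns=rs.channel_ids)
        df.index.name = "stimulus_id"
        df.to_csv(path, sep=sep, float_format="%.17g")
        return
    raise ValueError(f"unknown layout {layout!r}")


def align_common_stimuli(a: ResponseSet, b: ResponseSet) -> PairedResponses:
    """Restrict two response sets to their common stimuli in canonical order.

    The common stimuli are sorted lexicographically by identifier and both
    sides' rows are permuted to that order.  Raises if fewer than two stimuli
    are shared.
    """
    common = np.intersect1d(a.stimulus_ids, b.stimulus_ids)  # sorted
    if len(common) < 2:
        raise ValueError(
            f"insufficient stimulus overlap: {len(common)} common stimuli (need >= 2)"
        )
    return PairedResponses(a.restrict_stimuli(common), b.restrict_stimuli(common))


def make_folds(stimulus_ids, n_folds: int = 8, seed: int = 0) -> FoldPlan:
    """Randomly partition stimuli into ``n_folds`` near-equal folds.

    Identifiers are shuffled with a seeded generator and dealt round-robin,
    so any remainder lands in the lowest-index folds.  Deterministic given
    ``seed``.
    """
    ids = np.asarray(stimulus_ids, dtype=str)
    n = len(ids)
    if n_folds < 2:
        raise ValueError("need at least 2 folds")
    if n < n_folds:
        raise ValueError(f"cannot split {n} stimuli into {n_folds} folds")
    rng = np.random.default_rng(seed)
    shuffled = ids[rng.permutation(n)]
    assignment = {s: (i % n_folds) + 1 for i, s in enumerate(shuffled)}
    return FoldPlan(n_folds=n_folds, assignment=assignment, seed=seed)


def zscore_channels(rs: ResponseSet, reference_rows=None) -> ResponseSet:
    """Z-score each channel by its mean and population sd over reference rows.

    ``reference_rows`` is a boolean mask or integer index over stimuli
    (default: all rows); the shift/scale estimated there is applied to *all*
    rows, so e.g. z-scoring referenced on training rows leaves test rows
    generally non-centered — the desired behavior for honest generalization
    tests.
    """
    if reference_rows is None:
        ref = rs.values
    else:
        ref = rs.values[reference_rows]
        if ref.shape[0] == 0:
            raise ValueError("reference rows are empty")
    mean = ref.mean(axis=0)
    sd = ref.std(axis=0)  # population: divide by m
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise ValueError(
            "zero-spread channels over reference rows: "
            + ", ".join(rs.channel_ids[dead][:20])
        )
    return dataclasses.replace(rs, values=(rs.values - mean) / sd)
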