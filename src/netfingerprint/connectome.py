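"""Node time courses -> per-subject, per-condition connectivity matrices.

Node time series are either read directly from delimited files (frames x
nodes) or extracted from a 4-D image with an integer label atlas (mean over
voxels per label, per frame). Condition blocks are concatenated across
blocks and runs — the short fixation baseline between blocks is never
included — and edges are node-by-node pairwise Pearson correlations, with
Fisher z as an option.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError, ParameterError

__all__ = [
    "TimeSeries",
    "ConnectivityMatrix",
    "extract_node_timeseries",
    "concatenate_condition_blocks",
    "connectivity_matrix",
    "read_timeseries",
]

log = logging.getLogger(__name__)


@dataclass
class TimeSeries:
    """Frames x nodes numeric series for one subject and condition."""

    data: np.ndarray
    condition: str | None = None
    subject: str | None = None
    block_of_frame: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ParameterError(f"time series must be 2-D, got shape {self.data.shape}")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.data.shape[1]


@dataclass
class ConnectivityMatrix:
    """Nodes x nodes edge matrix: Pearson r, or Fisher z when flagged."""

    values: np.ndarray
    subject: str | None = None
    condition: str | None = None
    fisher_z: bool = False

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    def to_tsv(self, path: str | Path) -> None:
        np.savetxt(path, self.values, delimiter="\t")


def _as_array(obj, name: str) -> np.ndarray:
    """Accept a numpy array, a NIfTI path, or a nibabel image."""
    if isinstance(obj, (str, Path)):
        import nibabel as nib

        return np.asanyarray(nib.load(str(obj)).dataobj)
    if hasattr(obj, "dataobj"):  # nibabel image
        return np.asanyarray(obj.dataobj)
    return np.asarray(obj)


def extract_node_timeseries(image4d, label_atlas) -> TimeSeries:
    """Mean time course over the voxels of each atlas label.

    ``image4d`` is (x, y, z, t); ``label_atlas`` is (x, y, z) with
    non-negative integer labels, 0 meaning background. Nodes are ordered by
    label 1..max; a label with no voxels yields a warning and an all-NaN
    column.
    """
    img = _as_array(image4d, "image4d").astype(float)
    atlas = _as_array(label_atlas, "label_atlas")
    if img.ndim != 4:
        raise DataError(f"expected a 4-D image, got shape {img.shape}")
    if atlas.shape != img.shape[:3]:
        raise DataError(
            f"label atlas grid {atlas.shape} does not match image grid {img.shape[:3]}"
        )
    if not np.issubdtype(atlas.dtype, np.integer):
        if not np.allclose(atlas, np.round(atlas)):
            raise DataError("label atlas must contain integers")
        atlas = np.round(atlas).astype(int)
    if atlas.min() < 0:
        raise DataError("label atlas contains negative labels")
    n_labels = int(atlas.max())
    if n_labels == 0:
        raise DataError("label atlas contains only background (label 0)")

    lab = atlas.reshape(-1)
    flat = img.reshape(-1, img.shape[3])
    counts = np.bincount(lab, minlength=n_labels + 1)[1:]
    n_frames = flat.shape[1]
    out = np.full((n_frames, n_labels), np.nan)
    for t in range(n_frames):
        sums = np.bincount(lab, weights=flat[:, t], minlength=n_labels + 1)[1:]
        with np.errstate(invalid="ignore", divide="ignore"):
            out[t] = sums / counts
    empty = np.flatnonzero(counts == 0) + 1
    for label in empty:
        warnings.warn(f"label {label} has no voxels; node column set to NaN")
    return TimeSeries(out)


def concatenate_condition_blocks(
    series: TimeSeries | np.ndarray,
    blocks: pd.DataFrame,
    condition: str,
    lag_frames: int = 0,
) -> TimeSeries:
    """Concatenate the frames of one condition's blocks, in order.

    ``blocks`` needs columns ``condition``, ``start``, ``stop`` (frame
    indices, half-open). Each window is shifted forward by ``lag_frames``
    (e.g., to absorb a hemodynamic delay; the default of 0 matches raw
    block time courses). Shifted windows must stay inside the run and must
    not overlap one another.
    """
    data = series.data if isinstance(series, TimeSeries) else np.asarray(series, float)
    if lag_frames < 0:
        raise ParameterError("lag_frames must be non-negative")
    required = {"condition", "start", "stop"}
    if not required <= set(blocks.columns):
        raise DataError(f"block table must have columns {sorted(required)}")
    sel = blocks[blocks["condition"] == condition]
    if sel.empty:
        have = sorted(blocks["condition"].unique())
        raise DataError(f"condition {condition!r} absent from block table (have {have})")

    windows = []
    for _, row in sel.iterrows():
        start, stop = int(row["start"]) + lag_frames, int(row["stop"]) + lag_frames
        if start < 0 or stop > data.shape[0]:
            raise DataError(
                f"shifted window [{start}, {stop}) falls outside run of "
                f"{data.shape[0]} frames"
            )
        if stop <= start:
            raise DataError(f"empty window [{start}, {stop})")
        windows.append((start, stop))
    for (a0, a1), (b0, b1) in zip(sorted(windows), sorted(windows)[1:]):
        if b0 < a1:
            raise DataError(
                f"shifted windows overlap: [{a0}, {a1}) and [{b0}, {b1})"
            )

    parts = [data[a:b] for a, b in windows]
    block_ids = np.concatenate(
        [np.full(b - a, i) for i, (a, b) in enumerate(windows)]
    )
    out = np.concatenate(parts, axis=0)
    if out.shape[0] == 0:
        raise DataError("concatenation produced zero frames")
    return TimeSeries(out, condition=condition, block_of_frame=block_ids)


def connectivity_matrix(
    series: TimeSeries | np.ndarray,
    fisher_z: bool = False,
    constant_policy: str = "error",
    subject: str | None = None,
    condition: str | None = None,
) -> ConnectivityMatrix:
    """Pairwise Pearson correlations between node time courses.

    With ``fisher_z=True`` the off-diagonal entries are ``atanh(r)`` and the
    diagonal is 0. A constant node column either raises (default policy
    ``"error"``) or, with policy ``"missing"``, sets that node's edges to
    NaN and logs a warning.
    """
    ts = series if isinstance(series, TimeSeries) else TimeSeries(series)
    if ts.n_frames < 3:
        raise DataError(f"need at least 3 frames, got {ts.n_frames}")
    if constant_policy not in ("error", "missing"):
        raise ParameterError(f"unknown constant_policy {constant_policy!r}")

    x = ts.data
    sd = x.std(axis=0)
    constant = np.flatnonzero(sd == 0.0)
    if constant.size and constant_policy == "error":
        raise DataError(f"constant node column(s): {constant.tolist()}")

    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x, rowvar=False)
    r = (r + r.T) / 2.0
    np.fill_diagonal(r, 1.0)
    if constant.size:
        log.warning("setting edges of constant nodes %s to NaN", constant.tolist())
        r[constant, :] = np.nan
        r[:, constant] = np.nan
        np.fill_diagonal(r, 1.0)

    if fisher_z:
        with np.errstate(divide="ignore"):
            r = np.arctanh(np.clip(r, -1.0, 1.0))
        np.fill_diagonal(r, 0.0)

    return ConnectivityMatrix(
        values=r,
        subject=subject or (ts.subject if isinstance(series, TimeSeries) else None),
        condition=condition or ts.condition,
        fisher_z=fisher_z,
    )


def read_timeseries(path: str | Path) -> TimeSeries:
    """Read a frames x nodes delimited file written by the simulator."""
    data = np.loadtxt(path, delimiter="\t", ndmin=2)
    name = Path(path).stem
    subject, _, condition = name.rpartition("_")
    return TimeSeries(data, subject=subject or None, condition=condition or None)
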