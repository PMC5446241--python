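"""Per-frame scalar series: distance traces and rolling averages."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .structure_io import Trajectory, find_atom_index, parse_atom_path

__all__ = ["ScalarSeries", "distance_series", "rolling_average"]


@dataclass(frozen=True)
class ScalarSeries:
    """A per-frame scalar (distance, RMSD, count …) with its time base."""

    values: np.ndarray
    unit: str
    frame_interval_ns: float

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1:
            raise ValueError("values must be one-dimensional")
        if not np.all(np.isfinite(vals)):
            raise ValueError("values must be finite")
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return len(self.values)

    def times_ns(self) -> np.ndarray:
        return np.arange(len(self.values)) * self.frame_interval_ns

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_ns": self.times_ns(), f"value_{self.unit}": self.values}
        )


def _resolve_point(traj: Trajectory, spec) -> np.ndarray:
    """(n_frames, 3) coordinates of an atom path or a static point.

    ``spec`` is either a ``"chain:resnum:atom_name"`` address, resolved in
    every frame, or a fixed 3-vector (e.g. a bound-like reference atom
    position mapped into the trajectory frame), broadcast over frames.
    """
    if isinstance(spec, str):
        chain, resnum, name = parse_atom_path(spec)
        i = find_atom_index(traj.frames[0], chain, resnum, name)
        return np.array([f.atoms[i].position for f in traj.frames])
    point = np.asarray(spec, dtype=float)
    if point.shape != (3,):
        raise ValueError("static point must be a 3-vector")
    return np.broadcast_to(point, (traj.n_frames, 3))


def distance_series(traj: Trajectory, atom_a, atom_b) -> ScalarSeries:
    """Per-frame Euclidean distance (Å) between two atoms.

    Either endpoint may be given as an atom path string or as a static
    3-vector position.
    """
    pa = _resolve_point(traj, atom_a)
    pb = _resolve_point(traj, atom_b)
    d = np.linalg.norm(pa - pb, axis=1)
    return ScalarSeries(d, unit="A", frame_interval_ns=traj.frame_interval_ns)


def rolling_average(series: ScalarSeries, window_ns: float) -> ScalarSeries:
    """Centred moving mean with truncated edges (output length preserved).

    Frame ``i`` averages every frame whose time lies within ``window_ns/2``
    of frame ``i``'s time; near the edges only the frames actually inside
    the window contribute (no padding).  A window of one frame interval is
    the identity.
    """
    if window_ns < series.frame_interval_ns:
        raise ValueError("window_ns must be at least one frame interval")
    # symmetric window in frames; tiny epsilon absorbs float division error
    half = int(window_ns / (2 * series.frame_interval_ns) + 1e-9)
    n = len(series.values)
    csum = np.concatenate([[0.0], np.cumsum(series.values)])
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half, n - 1)
    smoothed = (csum[hi + 1] - csum[lo]) / (hi - lo + 1)
    return ScalarSeries(smoothed, series.unit, series.frame_interval_ns)
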