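"""Trajectory container, file dialect reader/writer, and preprocessing.

A trajectory is a time-stamped sequence of 2-D positions (meters, seconds)
with the recording metadata of the individual it belongs to.  The on-disk
dialect is one tab-delimited text file per individual: a single header line,
then one row per video frame with the metadata columns first and the time,
x and y columns last.  Files in the wild carry either nine or ten columns
(with or without the video-frame rank); both layouts are accepted, keyed on
header names when present with a positional fallback (x, y are always the
final two columns and time the third from last).

Coordinate convention used throughout the package: y runs along the steepest
line of the support, positive uphill; x is horizontal.  Headings are radians
in (-pi, pi], 0 pointing uphill, increasing counterclockwise.

Preprocessing mirrors the standard protocol for drop-release assays: the
early part of the track is discarded until the animal has moved at least
``start_trim_distance`` from its dropping site, and the track is truncated
at its first exit from the circle of radius ``exit_radius`` centered on the
dropping site.  A track that never exits is kept whole and flagged censored.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import (
    DegenerateGeometryError,
    EmptyTrajectoryError,
    TrajectoryParseError,
)

__all__ = [
    "Trajectory",
    "Domain",
    "read_trajectory_file",
    "write_trajectory_file",
    "trim_start",
    "truncate_exit",
    "path_length_and_speed",
]

#: canonical metadata column names, in on-disk order (frame rank optional)
_META_COLUMNS = (
    "inclination_label",
    "colony_label",
    "temperature",
    "humidity",
    "date",
    "individual_index",
)


@dataclass
class Trajectory:
    """Time-stamped 2-D track of one individual.

    Parameters
    ----------
    xy : (n, 2) array of float
        Positions in meters.
    t : (n,) array of float
        Times in seconds, strictly increasing.
    meta : dict
        Recording metadata (inclination label, colony, temperature...).
        Preprocessing steps record their flags here (``censored``,
        ``trim_index``, ``reference_start``).
    nominal_rate : float
        Nominal sampling rate in Hz (25 for the reference data sets).
    """

    xy: np.ndarray
    t: np.ndarray
    meta: dict = field(default_factory=dict)
    nominal_rate: float = 25.0

    def __post_init__(self):
        self.xy = np.asarray(self.xy, dtype=float)
        self.t = np.asarray(self.t, dtype=float)
        if self.xy.ndim != 2 or self.xy.shape[1] != 2:
            raise ValueError("xy must be an (n, 2) array")
        if len(self.xy) != len(self.t):
            raise ValueError("positions and times must have the same length")
        if len(self.t) < 2:
            raise EmptyTrajectoryError("a trajectory needs at least 2 points")
        if not (np.isfinite(self.xy).all() and np.isfinite(self.t).all()):
            raise ValueError("coordinates and times must be finite")
        if not (np.diff(self.t) > 0).all():
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def censored(self) -> bool:
        return bool(self.meta.get("censored", False))

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])


@dataclass(frozen=True)
class Domain:
    """Geometry of the assay: the exit circle and the start trim distance."""

    exit_radius: float = 0.2
    start_trim_distance: float = 0.01

    def __post_init__(self):
        if self.exit_radius <= 0 or self.start_trim_distance <= 0:
            raise ValueError("domain distances must be strictly positive")


def _split_row(line: str) -> list[str]:
    # rstrip tolerates trailing tabs / CR without spawning phantom columns
    return line.rstrip("\r\n\t ").split("\t")


def read_trajectory_file(path: str | Path, nominal_rate: float = 25.0) -> Trajectory:
    """Read one tab-delimited trajectory file.

    The final two columns are x and y in meters.  Time in seconds is the
    column whose header contains "time" (case-insensitive), falling back to
    the third column from the end.  Remaining leading columns are stored as
    metadata under canonical names.

    Raises
    ------
    TrajectoryParseError
        On a non-numeric coordinate/time value (with the line number) or
        when fewer than two data rows are present.
    """
    path = Path(path)
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise TrajectoryParseError(f"{path}: empty file")
    header = _split_row(lines[0])
    ncol = len(header)
    time_col = ncol - 3
    for i, name in enumerate(header):
        if "time" in name.lower():
            time_col = i
            break

    xs, ys, ts = [], [], []
    meta: dict = {}
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = _split_row(line)
        if len(fields) < 3:
            raise TrajectoryParseError(
                f"{path}: expected at least 3 columns, got {len(fields)}",
                line_number=lineno,
            )
        try:
            ts.append(float(fields[time_col]))
            xs.append(float(fields[-2]))
            ys.append(float(fields[-1]))
        except (ValueError, IndexError) as exc:
            raise TrajectoryParseError(
                f"{path}: non-numeric coordinate or time ({exc})",
                line_number=lineno,
            ) from None
        if not meta:
            meta = _extract_meta(header, fields, time_col)
    if len(ts) < 2:
        raise TrajectoryParseError(f"{path}: fewer than 2 data rows")
    return Trajectory(
        xy=np.column_stack([xs, ys]), t=np.asarray(ts), meta=meta,
        nominal_rate=nominal_rate,
    )


def _extract_meta(header: Sequence[str], fields: Sequence[str], time_col: int) -> dict:
    """Map the leading metadata columns of the first data row to canonical names."""
    meta: dict = {}
    leading = list(range(0, min(time_col, len(fields) - 2)))
    # drop a video-frame-rank column right before time if present (10-col layout)
    if len(leading) == len(_META_COLUMNS) + 1:
        meta["frame_rank_start"] = fields[leading[-1]]
        leading = leading[:-1]
    for name, col in zip(_META_COLUMNS, leading):
        meta[name] = fields[col]
    return meta


def write_trajectory_file(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory in the same dialect, plus a JSON metadata sidecar.

    Coordinates are written with 12 significant digits so a write/read round
    trip preserves them beyond 9 significant digits.
    """
    path = Path(path)
    meta = traj.meta
    header = list(_META_COLUMNS) + ["time in second", "x", "y"]
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for (x, y), t in zip(traj.xy, traj.t):
            row = [str(meta.get(k, "NA")) for k in _META_COLUMNS]
            row += [f"{t:.12g}", f"{x:.12g}", f"{y:.12g}"]
            fh.write("\t".join(row) + "\n")
    sidecar = {
        k: v for k, v in meta.items()
        if k in ("censored", "trim_index", "reference_start")
    }
    if sidecar:
        with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
            json.dump(sidecar, fh, default=list)


def trim_start(traj: Trajectory, d: float) -> Trajectory:
    """Drop the early part of the track until the first point at Euclidean
    distance >= ``d`` from the first tracked point (the dropping site).

    The dropping site is kept in ``meta['reference_start']`` since the exit
    circle stays centered on it.
    """
    if d <= 0:
        raise ValueError("trim distance must be positive")
    start = np.asarray(
        traj.meta.get("reference_start", traj.xy[0]), dtype=float
    )
    dist = np.hypot(*(traj.xy - start).T)
    idx = np.argmax(dist >= d)
    if dist[idx] < d:
        raise EmptyTrajectoryError(
            f"no point ever reaches {d} m from the start (max {dist.max():.4g} m)"
        )
    if idx > len(traj) - 2:
        raise EmptyTrajectoryError("trimming leaves fewer than 2 points")
    meta = dict(traj.meta)
    meta.setdefault("reference_start", (float(start[0]), float(start[1])))
    meta["trim_index"] = int(meta.get("trim_index", 0) + int(idx))
    return replace(traj, xy=traj.xy[idx:], t=traj.t[idx:], meta=meta)


def truncate_exit(traj: Trajectory, R: float, center: Sequence[float]) -> Trajectory:
    """Truncate at the first sample strictly outside radius ``R`` from ``center``.

    If the track never exits, the full trajectory is returned with
    ``meta['censored'] = True`` (censoring is a flagged outcome, not an error).
    """
    if R <= 0:
        raise ValueError("exit radius must be positive")
    center = np.asarray(center, dtype=float)
    dist = np.hypot(*(traj.xy - center).T)
    outside = dist > R
    meta = dict(traj.meta)
    if not outside.any():
        meta["censored"] = True
        return replace(traj, meta=meta)
    i = int(np.argmax(outside))
    meta["censored"] = False
    end = max(i + 1, 2)  # keep >= 2 samples even when the first sample is outside
    return replace(traj, xy=traj.xy[:end], t=traj.t[:end], meta=meta)


def path_length_and_speed(traj: Trajectory) -> tuple[float, float, float]:
    """Return (path length m, duration s, mean speed m/s); stops are included
    in the duration, so the mean speed is length / total duration."""
    steps = np.hypot(*np.diff(traj.xy, axis=0).T)
    length = float(steps.sum())
    duration = traj.duration
    if duration <= 0:
        raise DegenerateGeometryError("zero total duration")
    return length, duration, length / duration
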