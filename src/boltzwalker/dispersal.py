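"""Population-scale dispersal statistics.

Mean square displacement is indexed by the number of reorientation events
rather than time: ants vary their speed and stop occasionally, and counting
events makes the dispersal curve insensitive to those fluctuations.  The
MSD at lag n pools |X_{k+n} - X_k|^2 over every start index k of every
trajectory (overlapping windows, so the confidence bounds are approximate).

Exit headings (the angle from the start to the first crossing of the exit
circle) are the population summary of directional dispersal; samples are
compared with the two-sample Kolmogorov-Smirnov test on the raw angles,
exactly as is customary for these data (a linear test on circular support,
noted as questionable in the methods documentation, kept for comparability).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .circular import heading_of
from .segmentation import SegmentedTrajectory
from .trajectory import Domain, Trajectory, path_length_and_speed

__all__ = [
    "MSDCurve",
    "IndividualSummary",
    "msd_vs_events",
    "summarize_individual",
    "interpolated_exit_heading",
    "ks_two_sample",
]


@dataclass
class MSDCurve:
    """Mean square displacement vs number of reorientation events."""

    n: np.ndarray          # event counts, strictly increasing
    msd: np.ndarray        # m^2
    ci_low: np.ndarray     # approximate 95% bounds (overlapping windows)
    ci_high: np.ndarray
    replicates: np.ndarray  # pooled window count per n


@dataclass
class IndividualSummary:
    """Per-individual time-averaged summary inside the exit circle."""

    mean_speed: float        # m/s, stops included
    residence_time: float    # s inside the disk
    trajectory_length: float  # m inside the disk
    mean_abs_x: float        # time-averaged |x - x_start|, m
    mean_abs_y: float        # time-averaged |y - y_start|, m
    exit_heading: float | None  # rad, None when censored
    censored: bool


def msd_vs_events(
    segmented: list[SegmentedTrajectory] | SegmentedTrajectory,
    n_max: int,
) -> MSDCurve:
    """MSD(n) over reorientation locations, pooled across trajectories.

    Reorientation locations are the turning points of each segmented
    trajectory (segment boundaries).  For each lag n <= n_max the average
    of |X_{k+n} - X_k|^2 runs over all start indices k of all trajectories.
    """
    if isinstance(segmented, SegmentedTrajectory):
        segmented = [segmented]
    pts = [st.turning_points() for st in segmented]
    max_events = max(len(p) - 1 for p in pts)
    if n_max > max_events:
        raise ValueError(
            f"n_max={n_max} exceeds every trajectory's event count ({max_events})"
        )
    ns = np.arange(1, n_max + 1)
    msd = np.empty(n_max)
    lo = np.empty(n_max)
    hi = np.empty(n_max)
    reps = np.empty(n_max, dtype=int)
    for i, n in enumerate(ns):
        sq = []
        for p in pts:
            if len(p) - 1 >= n:
                d = p[n:] - p[:-n]
                sq.append((d**2).sum(axis=1))
        sq = np.concatenate(sq)
        m = float(sq.mean())
        se = float(sq.std(ddof=1) / math.sqrt(len(sq))) if len(sq) > 1 else 0.0
        msd[i] = m
        lo[i], hi[i] = m - 1.96 * se, m + 1.96 * se
        reps[i] = len(sq)
    return MSDCurve(n=ns, msd=msd, ci_low=lo, ci_high=hi, replicates=reps)


def interpolated_exit_heading(traj: Trajectory, R: float, center) -> float | None:
    """Exit heading of a sampled track: the angle of the linearly
    interpolated crossing of the first inside->outside step, or None if the
    track never leaves the circle."""
    center = np.asarray(center, dtype=float)
    rel = traj.xy - center
    dist = np.hypot(*rel.T)
    outside = dist > R
    if not outside.any():
        return None
    i = int(np.argmax(outside))
    if i == 0:
        p = rel[0]
        return heading_of(p[0], p[1])
    p0, p1 = rel[i - 1], rel[i]
    d = p1 - p0
    a = float(d @ d)
    b = 2.0 * float(p0 @ d)
    c = float(p0 @ p0) - R * R
    t = (-b + math.sqrt(max(b * b - 4 * a * c, 0.0))) / (2 * a)
    p = p0 + t * d
    return heading_of(p[0], p[1])


def summarize_individual(
    traj: Trajectory, domain: Domain | None = None
) -> IndividualSummary:
    """Time-averaged summary of one preprocessed trajectory.

    Residence time and path length are measured inside the exit disk (the
    whole preprocessed track when censored); |x| and |y| are relative to the
    dropping site (``meta['reference_start']`` when present, else the first
    sample).  Stops are included, so mean speed = length / duration.
    """
    domain = domain or Domain()
    start = np.asarray(
        traj.meta.get("reference_start", traj.xy[0]), dtype=float
    )
    length, duration, speed = path_length_and_speed(traj)
    rel = traj.xy - start
    exit_heading = interpolated_exit_heading(traj, domain.exit_radius, start)
    censored = exit_heading is None
    return IndividualSummary(
        mean_speed=speed,
        residence_time=duration,
        trajectory_length=length,
        mean_abs_x=float(np.abs(rel[:, 0]).mean()),
        mean_abs_y=float(np.abs(rel[:, 1]).mean()),
        exit_heading=exit_heading,
        censored=censored,
    )


def ks_two_sample(a, b) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test: returns (D, p) with the
    asymptotic p-value."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both samples need at least 2 observations")
    res = sps.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)
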