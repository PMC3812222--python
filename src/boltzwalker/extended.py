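"""Heading-sector-conditioned estimation and simulation (the extended walker).

On an inclined support, a walker's speed, mean free path and phase function
may all depend on its current heading relative to the steepest line.  The
extended Boltzmann Walker captures this by partitioning the heading circle
into S sectors (8 by default, sector 0 centered uphill) and attaching to
each sector the empirical statistics of the segments whose heading falls in
it: mean speed, mean free path (mean segment length), persistence (mean
cosine of the outgoing deviation), and the empirical CDFs of segment
lengths and signed deviations.  Simulation then replays Algorithm-2-style
generation, but at every event draws the free path and the deviation from
the ECDFs of the sector of the *current* heading, via inverse-CDF sampling
with linear interpolation on a 100-bin abscissa grid.

Conditioning convention: a segment's length and speed condition on the
segment's own heading; the deviation at the end of a segment conditions on
the pre-turn heading.  This matches the simulation loop, which draws both
quantities from the sector of the heading being walked.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .bw import ExitRecord, circle_crossing
from .circular import heading_of, heading_to_unit, wrap_angle
from .errors import ConfigError, DegenerateGeometryError, EmptySectorError
from .segmentation import SegmentedTrajectory
from .trajectory import Trajectory

__all__ = [
    "SectorPartition",
    "EmpiricalCDF",
    "SectorStats",
    "sector_of",
    "estimate_sector_stats",
    "build_ecdf",
    "sample_ecdf",
    "simulate_extended_bw",
    "predict_exit_headings",
]


@dataclass(frozen=True)
class SectorPartition:
    """Half-open heading sectors of width 2*pi/S centered at
    offset + 2*pi*k/S; sector 0 is centered uphill (heading 0)."""

    S: int = 8
    offset: float = 0.0

    def __post_init__(self):
        if self.S < 2 or self.S % 2 != 0:
            raise ConfigError("sector count must be even and >= 2")

    @property
    def width(self) -> float:
        return 2.0 * math.pi / self.S

    def centers(self) -> np.ndarray:
        return wrap_angle(self.offset + self.width * np.arange(self.S))


def sector_of(theta, part: SectorPartition):
    """Index of the half-open arc [center - pi/S, center + pi/S) containing
    theta (boundary angles belong to the upper sector)."""
    rel = np.asarray(wrap_angle(np.asarray(theta) - part.offset))
    idx = np.floor((rel + part.width / 2.0) / part.width).astype(int) % part.S
    return idx if idx.ndim else int(idx)


@dataclass
class EmpiricalCDF:
    """Step ECDF discretized on a uniform abscissa grid.

    ``abscissae`` spans [sample min, sample max] with B+1 grid points;
    ``values`` is non-decreasing with F(a_0) = 0 and F(a_B) = 1 forced
    (the lower endpoint convention accepts a vanishing bias at the lower
    edge).  ``degenerate`` flags an all-identical sample, for which
    sampling returns the constant.
    """

    abscissae: np.ndarray
    values: np.ndarray
    degenerate: bool = False

    def mean(self) -> float:
        """Mean of the piecewise-linear distribution the grid encodes."""
        if self.degenerate:
            return float(self.abscissae[0])
        mid = 0.5 * (self.abscissae[1:] + self.abscissae[:-1])
        w = np.diff(self.values)
        return float((mid * w).sum())


def build_ecdf(samples, B: int = 100) -> EmpiricalCDF:
    """Discretize the ECDF of a sample on a uniform B-bin abscissa grid."""
    s = np.sort(np.asarray(samples, dtype=float))
    if s.size < 2:
        raise ValueError("need at least 2 samples")
    lo, hi = float(s[0]), float(s[-1])
    if hi - lo <= 0:
        grid = np.full(B + 1, lo)
        vals = np.linspace(0.0, 1.0, B + 1)
        return EmpiricalCDF(grid, vals, degenerate=True)
    grid = np.linspace(lo, hi, B + 1)
    vals = np.searchsorted(s, grid, side="right") / s.size
    vals[0] = 0.0
    vals[-1] = 1.0
    return EmpiricalCDF(grid, vals)


def sample_ecdf(F: EmpiricalCDF, rng: np.random.Generator, size=None):
    """Inverse-CDF draw with linear interpolation between grid abscissae.

    For a uniform r in [0, 1), the lowest grid abscissa a_j with F(a_j) >= r
    is located and the return value interpolates between a_{j-1} and a_j
    proportionally to (r - F(a_{j-1})) / (F(a_j) - F(a_{j-1})).
    """
    scalar = size is None
    r = rng.random(1 if scalar else size)
    if F.degenerate:
        out = np.full(r.shape, F.abscissae[0])
        return float(out[0]) if scalar else out
    j = np.clip(np.searchsorted(F.values, r, side="left"), 1, len(F.values) - 1)
    f0, f1 = F.values[j - 1], F.values[j]
    a0, a1 = F.abscissae[j - 1], F.abscissae[j]
    w = np.where(f1 > f0, (r - f0) / np.where(f1 > f0, f1 - f0, 1.0), 0.0)
    out = np.where(r <= 0.0, F.abscissae[0], a0 + w * (a1 - a0))
    return float(out[0]) if scalar else out


@dataclass
class SectorStats:
    """Per-heading-sector motion statistics of a segmented data set."""

    partition: SectorPartition
    mean_speed: np.ndarray       # m/s per sector (NaN where empty)
    mean_free_path: np.ndarray   # m per sector
    persistence: np.ndarray      # mean cos(deviation) per sector
    length_ecdf: list[EmpiricalCDF | None]
    deviation_ecdf: list[EmpiricalCDF | None]
    heading_frequency: np.ndarray  # fraction of segments per sector
    counts: np.ndarray
    meta: dict = field(default_factory=dict)

    @property
    def empty_sectors(self) -> np.ndarray:
        return np.flatnonzero(self.counts == 0)

    def global_mean_speed(self) -> float:
        ok = self.counts > 0
        return float(
            (self.mean_speed[ok] * self.counts[ok]).sum() / self.counts[ok].sum()
        )

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        def ecdf_d(F):
            if F is None:
                return None
            return {
                "abscissae": F.abscissae.tolist(),
                "values": F.values.tolist(),
                "degenerate": F.degenerate,
            }

        return {
            "partition": {"S": self.partition.S, "offset": self.partition.offset},
            "mean_speed": self.mean_speed.tolist(),
            "mean_free_path": self.mean_free_path.tolist(),
            "persistence": self.persistence.tolist(),
            "heading_frequency": self.heading_frequency.tolist(),
            "counts": self.counts.tolist(),
            "length_ecdf": [ecdf_d(F) for F in self.length_ecdf],
            "deviation_ecdf": [ecdf_d(F) for F in self.deviation_ecdf],
            "meta": self.meta,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SectorStats":
        def ecdf_u(e):
            if e is None:
                return None
            return EmpiricalCDF(
                np.asarray(e["abscissae"]), np.asarray(e["values"]),
                degenerate=bool(e.get("degenerate", False)),
            )

        return cls(
            partition=SectorPartition(**d["partition"]),
            mean_speed=np.asarray(d["mean_speed"], dtype=float),
            mean_free_path=np.asarray(d["mean_free_path"], dtype=float),
            persistence=np.asarray(d["persistence"], dtype=float),
            length_ecdf=[ecdf_u(e) for e in d["length_ecdf"]],
            deviation_ecdf=[ecdf_u(e) for e in d["deviation_ecdf"]],
            heading_frequency=np.asarray(d["heading_frequency"], dtype=float),
            counts=np.asarray(d["counts"], dtype=int),
            meta=d.get("meta", {}),
        )

    def save(self, directory: str | Path) -> None:
        """Write stats.json (scalars + meta) and ecdfs.tsv (grid table)."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        d = self.to_dict()
        grids = {k: d.pop(k) for k in ("length_ecdf", "deviation_ecdf")}
        with open(directory / "stats.json", "w") as fh:
            json.dump(d, fh, indent=1)
        with open(directory / "ecdfs.tsv", "w") as fh:
            fh.write("kind\tsector\tdegenerate\tabscissa\tF\n")
            for kind, lst in grids.items():
                for s, e in enumerate(lst):
                    if e is None:
                        continue
                    for a, v in zip(e["abscissae"], e["values"]):
                        fh.write(
                            f"{kind}\t{s}\t{int(e['degenerate'])}\t{a:.12g}\t{v:.12g}\n"
                        )

    @classmethod
    def load(cls, directory: str | Path) -> "SectorStats":
        directory = Path(directory)
        with open(directory / "stats.json") as fh:
            d = json.load(fh)
        S = d["partition"]["S"]
        grids: dict = {
            "length_ecdf": [None] * S,
            "deviation_ecdf": [None] * S,
        }
        rows: dict = {}
        with open(directory / "ecdfs.tsv") as fh:
            next(fh)
            for line in fh:
                kind, s, deg, a, v = line.rstrip("\n").split("\t")
                rows.setdefault((kind, int(s)), ([], [], bool(int(deg))))
                rows[(kind, int(s))][0].append(float(a))
                rows[(kind, int(s))][1].append(float(v))
        for (kind, s), (aa, vv, deg) in rows.items():
            grids[kind][s] = {"abscissae": aa, "values": vv, "degenerate": deg}
        d.update(grids)
        return cls.from_dict(d)


def estimate_sector_stats(
    segmented: list[SegmentedTrajectory] | SegmentedTrajectory,
    part: SectorPartition | None = None,
    B: int = 100,
) -> SectorStats:
    """Pool segments from one or more segmented trajectories into per-sector
    statistics.

    Each segment contributes its length and speed to the sector of its own
    heading; each deviation contributes cos(alpha) (persistence) and alpha
    (deviation ECDF) to the sector of the pre-turn heading.  Sectors with no
    observations are flagged (NaN scalar fields, None ECDFs).
    """
    part = part or SectorPartition()
    if isinstance(segmented, SegmentedTrajectory):
        segmented = [segmented]
    lengths: list[list[float]] = [[] for _ in range(part.S)]
    speeds: list[list[float]] = [[] for _ in range(part.S)]
    devs: list[list[float]] = [[] for _ in range(part.S)]
    total = 0
    for st in segmented:
        hs = st.headings
        ls = st.lengths
        ds = st.durations
        sec = sector_of(hs, part)
        sec = np.atleast_1d(sec)
        for s, l, d in zip(sec, ls, ds):
            lengths[s].append(l)
            if d > 0:
                speeds[s].append(l / d)
        for s, a in zip(sec[:-1], st.deviations):
            devs[s].append(a)
        total += len(st)
    if total == 0:
        raise ValueError("no segments to pool")
    S = part.S
    counts = np.array([len(lengths[s]) for s in range(S)])
    mean_speed = np.full(S, np.nan)
    mfp = np.full(S, np.nan)
    pers = np.full(S, np.nan)
    len_e: list[EmpiricalCDF | None] = [None] * S
    dev_e: list[EmpiricalCDF | None] = [None] * S
    for s in range(S):
        if counts[s] == 0:
            continue
        mfp[s] = float(np.mean(lengths[s]))
        if speeds[s]:
            mean_speed[s] = float(np.mean(speeds[s]))
        if len(lengths[s]) >= 2:
            len_e[s] = build_ecdf(lengths[s], B)
        if len(devs[s]) >= 1:
            pers[s] = float(np.mean(np.cos(devs[s])))
        if len(devs[s]) >= 2:
            dev_e[s] = build_ecdf(devs[s], B)
    return SectorStats(
        partition=part,
        mean_speed=mean_speed,
        mean_free_path=mfp,
        persistence=pers,
        length_ecdf=len_e,
        deviation_ecdf=dev_e,
        heading_frequency=counts / total,
        counts=counts,
    )


def mirror_stats(stats: SectorStats) -> SectorStats:
    """Reflect a SectorStats about the steepest-line (uphill/downhill) axis.

    Reflecting the plane about the steepest line negates every heading
    (theta -> -theta) and every deviation; sector s maps to the sector of
    its reflected center.  Used as a symmetry check against the mirror
    symmetry expected for pairs of opposite incoming directions.
    """
    part = stats.partition
    centers = part.centers()
    target = sector_of(wrap_angle(-centers), part)
    S = part.S
    out = SectorStats(
        partition=part,
        mean_speed=np.empty(S),
        mean_free_path=np.empty(S),
        persistence=np.empty(S),
        length_ecdf=[None] * S,
        deviation_ecdf=[None] * S,
        heading_frequency=np.empty(S),
        counts=np.empty(S, dtype=int),
        meta=dict(stats.meta),
    )
    for s in range(S):
        m = int(target[s])
        out.mean_speed[m] = stats.mean_speed[s]
        out.mean_free_path[m] = stats.mean_free_path[s]
        out.persistence[m] = stats.persistence[s]
        out.heading_frequency[m] = stats.heading_frequency[s]
        out.counts[m] = stats.counts[s]
        out.length_ecdf[m] = stats.length_ecdf[s]
        F = stats.deviation_ecdf[s]
        if F is None:
            out.deviation_ecdf[m] = None
        else:
            out.deviation_ecdf[m] = EmpiricalCDF(
                -F.abscissae[::-1], 1.0 - F.values[::-1], F.degenerate
            )
    return out


def simulate_extended_bw(
    stats: SectorStats,
    rng: np.random.Generator,
    radius: float = 0.2,
    speed_mode: str = "global",
    max_events: int = 100_000,
) -> tuple[Trajectory, ExitRecord]:
    """Generate one extended-BW trajectory from per-sector statistics.

    The initial heading is uniform; at each event the sector of the current
    heading supplies the free-path ECDF and the deviation ECDF.  The run
    stops at the first exit from the disk of ``radius`` about the origin
    (exact segment-circle crossing appended).  ``speed_mode`` is "global"
    (one pooled mean speed scales all time stamps — speed is typically
    isotropic) or "sector" (per-sector mean speed).  Encountering a sector
    with no data aborts with a diagnostic.
    """
    part = stats.partition
    if speed_mode not in ("global", "sector"):
        raise ConfigError("speed_mode must be 'global' or 'sector'")
    pos = np.zeros(2)
    heading = float(rng.uniform(-math.pi, math.pi))
    pts = [pos.copy()]
    times = [0.0]
    v_global = stats.global_mean_speed()
    exited = False
    capped = False
    exit_angle = None
    for _ in range(max_events):
        s = sector_of(heading, part)
        F_l = stats.length_ecdf[s]
        F_d = stats.deviation_ecdf[s]
        if F_l is None or F_d is None:
            raise EmptySectorError(
                f"sector {s} (center {part.centers()[s]:+.3f} rad) has no data"
            )
        l = float(sample_ecdf(F_l, rng))
        if l <= 0:
            continue
        v = v_global if speed_mode == "global" else float(stats.mean_speed[s])
        new = pos + l * heading_to_unit(heading)
        if float(new @ new) > radius * radius:
            cross = circle_crossing(pos, new, radius)
            pts.append(cross)
            times.append(times[-1] + float(np.hypot(*(cross - pos))) / v)
            exit_angle = heading_of(cross[0], cross[1])
            exited = True
            break
        pts.append(new)
        times.append(times[-1] + l / v)
        pos = new
        heading = wrap_angle(heading + float(sample_ecdf(F_d, rng)))
    else:
        capped = True
    traj = Trajectory(
        xy=np.asarray(pts), t=np.asarray(times),
        meta={"model": "extended_bw", "censored": not exited, "capped": capped},
    )
    return traj, ExitRecord(exited, exit_angle, n_events=len(pts) - 1, capped=capped)


def predict_exit_headings(
    stats: SectorStats,
    rng: np.random.Generator,
    N: int = 10_000,
    radius: float = 0.2,
    speed_mode: str = "global",
) -> np.ndarray:
    """Exit-heading sample of N independent extended-BW runs from the center:
    the angle of each exact circle-crossing point."""
    if N < 1:
        raise ConfigError("N must be >= 1")
    out = np.empty(N)
    for i in range(N):
        _, rec = simulate_extended_bw(
            stats, rng, radius=radius, speed_mode=speed_mode
        )
        if not rec.exited:
            raise DegenerateGeometryError(
                "a simulated walker hit the event cap before exiting"
            )
        out[i] = rec.exit_angle
    return out
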