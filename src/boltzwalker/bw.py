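"""The standard Boltzmann Walker: a 2-D velocity-jump process.

A walker moves at constant speed ``v`` along straight free paths whose
lengths are exponential with mean free path ``lambda`` (the memory-less
assumption), and reorients instantaneously at the end of each free path by
a signed deviation drawn from a *phase function* symmetric about zero.  The
phase function used for generation is the elliptical family: the density is
proportional to the polar radius of an ellipse with one focus at the
origin,

    f(alpha) = sqrt(1 - e^2) / (2 pi (1 - e cos alpha)),   alpha in (-pi, pi],

whose mean cosine (the anisotropy or persistence coefficient) is
g = (1 - sqrt(1 - e^2)) / e, inverted by e = 2 g / (1 + g^2).  g = 0 is a
uniform reorientation (pure random walk), g -> 1 is complete persistence.

In the diffusive limit the population spreads with diffusion coefficient
D = v lambda / (2 (1 - g)) and the transport mean free path is
lambda* = lambda / (1 - g): a correlated walk with (lambda, g) disperses
like a pure random walk with mean free path lambda*.

All sampling is threaded through an explicit ``numpy.random.Generator``;
there is no global random state anywhere in the package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .circular import heading_of, heading_to_unit
from .errors import ConfigError
from .trajectory import Trajectory

__all__ = [
    "BWParameters",
    "EllipticalPhase",
    "eccentricity_from_g",
    "sample_elliptical",
    "sample_free_path",
    "simulate_bw",
    "simulate_bw_events",
    "batch_turning_points",
    "msd_over_time",
    "circle_crossing",
    "diffusion_coefficient",
    "transport_mean_free_path",
    "crw_msd_oracle",
    "ExitRecord",
]

_TWO_PI = 2.0 * math.pi


@dataclass(frozen=True)
class BWParameters:
    """Parameters of the standard (isotropic) Boltzmann Walker.

    speed in m/s, mean_free_path in m, persistence g dimensionless in [0, 1).
    """

    speed: float
    mean_free_path: float
    g: float = 0.0

    def __post_init__(self):
        if self.speed <= 0:
            raise ConfigError("speed must be > 0")
        if self.mean_free_path <= 0:
            raise ConfigError("mean free path must be > 0")
        if not (0.0 <= self.g < 1.0):
            raise ConfigError("persistence g must be in [0, 1)")


def eccentricity_from_g(g: float) -> float:
    """Eccentricity of the elliptical phase function with mean cosine g."""
    if not (0.0 <= g < 1.0):
        raise ConfigError("g must be in [0, 1)")
    return 2.0 * g / (1.0 + g * g)


@dataclass(frozen=True)
class EllipticalPhase:
    """Elliptical (focus-polar) turning-angle distribution with mean cosine g."""

    g: float
    e: float = field(init=False)

    def __post_init__(self):
        object.__setattr__(self, "e", eccentricity_from_g(self.g))

    def pdf(self, alpha):
        alpha = np.asarray(alpha, dtype=float)
        return np.sqrt(1.0 - self.e**2) / (_TWO_PI * (1.0 - self.e * np.cos(alpha)))

    def cdf(self, alpha):
        """CDF on (-pi, pi] (F(-pi) = 0, F(pi) = 1)."""
        alpha = np.asarray(alpha, dtype=float)
        k = math.sqrt((1.0 + self.e) / (1.0 - self.e))
        out = 0.5 + np.arctan(k * np.tan(alpha / 2.0)) / math.pi
        out = np.where(alpha >= math.pi, 1.0, out)
        out = np.where(alpha <= -math.pi, 0.0, out)
        return out if out.ndim else float(out)

    def ppf(self, u):
        """Exact inverse CDF: u in [0, 1) -> deviation in (-pi, pi]."""
        u = np.asarray(u, dtype=float)
        k = math.sqrt((1.0 - self.e) / (1.0 + self.e))
        out = 2.0 * np.arctan(k * np.tan(math.pi * (u - 0.5)))
        return out if out.ndim else float(out)

    def sample(self, rng: np.random.Generator, size=None):
        return self.ppf(rng.random(size))


def sample_elliptical(g: float, rng: np.random.Generator, size=None):
    """Draw turning deviations from the elliptical phase function (exact
    inverse-CDF; symmetric about 0, mean cosine = g)."""
    return EllipticalPhase(g).sample(rng, size)


def sample_free_path(lam: float, rng: np.random.Generator, size=None):
    """Exponential free-path lengths with survival P(L > l) = exp(-l / lam)."""
    if lam <= 0:
        raise ConfigError("mean free path must be > 0")
    return rng.exponential(lam, size)


@dataclass
class ExitRecord:
    """Outcome of a disk-bounded run: whether and where the walker exited."""

    exited: bool
    exit_angle: float | None
    n_events: int
    capped: bool = False


def circle_crossing(p0: np.ndarray, p1: np.ndarray, R: float) -> np.ndarray:
    """Exact intersection of the segment p0 (inside) -> p1 (outside) with the
    circle of radius R about the origin."""
    d = p1 - p0
    a = float(d @ d)
    b = 2.0 * float(p0 @ d)
    c = float(p0 @ p0) - R * R
    disc = b * b - 4.0 * a * c
    t = (-b + math.sqrt(max(disc, 0.0))) / (2.0 * a)
    return p0 + t * d


def simulate_bw(
    params: BWParameters,
    rng: np.random.Generator,
    radius: float | None = 0.2,
    max_events: int = 1_000_000,
    start=(0.0, 0.0),
) -> tuple[Trajectory, ExitRecord]:
    """Generate one standard BW trajectory of turning points.

    The initial heading is uniform on (-pi, pi].  Each iteration draws an
    exponential free path, advances along the current heading, then draws an
    elliptical deviation and turns.  The run stops at the first exit from the
    disk of ``radius`` about the start (the boundary crossing point is
    computed exactly by segment-circle intersection and appended), or after
    ``max_events`` free paths (flagged ``capped``).  With ``radius=None``
    only the event cap stops the run.

    Returns the turning-point Trajectory (time stamps = cumulative length /
    speed) and an ExitRecord.
    """
    phase = EllipticalPhase(params.g)
    lam = params.mean_free_path
    start = np.asarray(start, dtype=float)
    pos = np.zeros(2)
    heading = float(rng.uniform(-math.pi, math.pi))
    pts = [pos.copy()]
    exited = False
    capped = False
    exit_angle = None
    for _ in range(max_events):
        l = float(rng.exponential(lam))
        new = pos + l * heading_to_unit(heading)
        if radius is not None and float(new @ new) > radius * radius:
            cross = circle_crossing(pos, new, radius)
            pts.append(cross)
            exit_angle = heading_of(cross[0], cross[1])
            exited = True
            break
        pts.append(new)
        pos = new
        heading = float(
            math.remainder(heading + phase.sample(rng), _TWO_PI)
        )
    else:
        capped = True
    pts = np.asarray(pts)
    seglen = np.hypot(*np.diff(pts, axis=0).T)
    times = np.concatenate([[0.0], np.cumsum(seglen)]) / params.speed
    traj = Trajectory(
        xy=pts + start, t=times,
        meta={"model": "standard_bw", "censored": not exited, "capped": capped},
    )
    return traj, ExitRecord(exited, exit_angle, n_events=len(pts) - 1, capped=capped)


def simulate_bw_events(
    params: BWParameters, n_events: int, rng: np.random.Generator
) -> Trajectory:
    """Generate one unbounded BW trajectory with exactly ``n_events`` free
    paths (vectorized; turning points only)."""
    if n_events < 1:
        raise ConfigError("n_events must be >= 1")
    pts = batch_turning_points(params, 1, n_events, rng)[0]
    seglen = np.hypot(*np.diff(pts, axis=0).T)
    times = np.concatenate([[0.0], np.cumsum(seglen)]) / params.speed
    return Trajectory(xy=pts, t=times, meta={"model": "standard_bw"})


def batch_turning_points(
    params: BWParameters, n_walkers: int, n_events: int, rng: np.random.Generator
) -> np.ndarray:
    """Turning points of ``n_walkers`` independent BW runs of ``n_events``
    free paths each; returns an (n_walkers, n_events + 1, 2) array starting
    at the origin."""
    lengths = rng.exponential(params.mean_free_path, (n_walkers, n_events))
    dev = sample_elliptical(params.g, rng, (n_walkers, n_events - 1)) \
        if n_events > 1 else np.zeros((n_walkers, 0))
    h0 = rng.uniform(-math.pi, math.pi, (n_walkers, 1))
    headings = np.concatenate([h0, h0 + np.cumsum(dev, axis=1)], axis=1)
    steps = lengths[..., None] * heading_to_unit(headings)
    pts = np.concatenate(
        [np.zeros((n_walkers, 1, 2)), np.cumsum(steps, axis=1)], axis=1
    )
    return pts


def msd_over_time(
    params: BWParameters,
    times,
    n_walkers: int,
    rng: np.random.Generator,
    chunk: int = 2000,
) -> np.ndarray:
    """Monte-Carlo mean square displacement |X(t) - X(0)|^2 at the requested
    times, averaged over ``n_walkers`` independent walkers.

    Positions at intermediate times are interpolated exactly along the
    constant-speed polyline.  Walkers are simulated in chunks to bound
    memory.
    """
    times = np.asarray(times, dtype=float)
    s_targets = params.speed * times  # arc lengths to reach
    s_max = float(s_targets.max())
    mean_n = s_max / params.mean_free_path
    n_events = int(mean_n + 8.0 * math.sqrt(mean_n) + 16)
    total = np.zeros(times.shape)
    done = 0
    while done < n_walkers:
        m = min(chunk, n_walkers - done)
        pts = batch_turning_points(params, m, n_events, rng)
        seglen = np.hypot(*np.moveaxis(np.diff(pts, axis=1), 2, 0))
        cum = np.concatenate([np.zeros((m, 1)), np.cumsum(seglen, axis=1)], axis=1)
        # top-up rare walkers whose path is shorter than needed
        short = cum[:, -1] < s_max
        while short.any():
            n_events = int(n_events * 1.5) + 8
            pts_s = batch_turning_points(params, int(short.sum()), n_events, rng)
            pts = _pad_points(pts, pts_s, short)
            seglen = np.hypot(*np.moveaxis(np.diff(pts, axis=1), 2, 0))
            cum = np.concatenate([np.zeros((m, 1)), np.cumsum(seglen, axis=1)], axis=1)
            short = cum[:, -1] < s_max
        rows = np.arange(m)
        for i, s in enumerate(s_targets):
            # rows of cum are sorted: first index with cum >= s
            j = np.clip((cum < s).sum(axis=1), 1, cum.shape[1] - 1)
            s0 = cum[rows, j - 1]
            s1 = cum[rows, j]
            w = np.where(s1 > s0, (s - s0) / np.where(s1 > s0, s1 - s0, 1.0), 0.0)
            p = pts[rows, j - 1] + w[:, None] * (pts[rows, j] - pts[rows, j - 1])
            total[i] += float((p**2).sum())
        done += m
    return total / n_walkers


def _pad_points(pts, pts_new, mask):
    """Replace masked walker rows with freshly drawn longer runs, padding the
    kept rows with their final position so array shapes agree."""
    m, k_old, _ = pts.shape
    k_new = pts_new.shape[1]
    if k_new < k_old:
        pad = np.repeat(pts_new[:, -1:, :], k_old - k_new, axis=1)
        pts_new = np.concatenate([pts_new, pad], axis=1)
        k_new = k_old
    pad = np.repeat(pts[:, -1:, :], k_new - k_old, axis=1)
    out = np.concatenate([pts, pad], axis=1)
    out[mask] = pts_new
    return out


def diffusion_coefficient(v: float, lam: float, g: float) -> float:
    """Diffusive-limit coefficient D = v lambda / (2 (1 - g)) (2-D)."""
    if g >= 1.0:
        raise ConfigError("D diverges as g -> 1")
    return v * lam / (2.0 * (1.0 - g))


def transport_mean_free_path(lam: float, g: float) -> float:
    """lambda* = lambda / (1 - g), the persistence-equivalent RW free path."""
    if g >= 1.0:
        raise ConfigError("transport mean free path diverges as g -> 1")
    return lam / (1.0 - g)


def crw_msd_oracle(n, lam: float, g: float):
    """Closed-form E[R_n^2] after n free paths of a correlated random walk.

    Steps are i.i.d. exponential with mean ``lam`` (E[l] = lam,
    E[l^2] = 2 lam^2); successive directions have correlation
    E[cos(theta_j - theta_i)] = g^(j-i) because deviations are i.i.d. and
    symmetric.  Then

        E[R_n^2] = 2 lam^2 n
                 + 2 lam^2 [ n g / (1 - g) - g (1 - g^n) / (1 - g)^2 ]

    which reduces to 2 n lam^2 at g = 0 and has large-n slope
    2 lam^2 / (1 - g) per event, consistent with the diffusive limit.
    """
    n = np.asarray(n, dtype=float)
    if g == 0.0:
        out = 2.0 * n * lam * lam
    else:
        corr = n * g / (1.0 - g) - g * (1.0 - g**n) / (1.0 - g) ** 2
        out = 2.0 * lam * lam * (n + corr)
    return out if out.ndim else float(out)
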