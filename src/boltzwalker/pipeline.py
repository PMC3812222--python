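"""End-to-end orchestration: segment -> estimate -> simulate -> compare.

``run_pipeline`` processes a directory (or list) of trajectory files grouped
by experimental condition (the inclination label from the file metadata, or
the parent directory name as a fallback).  Per group it preprocesses every
track, segments it, pools the segments into per-heading-sector statistics,
simulates the parameterized extended walker, and compares observed against
predicted exit headings; MSD curves and per-individual summaries are
written alongside.  All randomness derives from one master seed through
per-stage substreams, so a rerun with the same configuration is
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import yaml

from .circular import hodges_ajne
from .dispersal import ks_two_sample, msd_vs_events, summarize_individual
from .errors import ConfigError
from .extended import (
    SectorPartition,
    estimate_sector_stats,
    predict_exit_headings,
)
from .segmentation import SegmentationConfig, segment_trajectory
from .trajectory import Domain, read_trajectory_file, trim_start, truncate_exit

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Configuration of one end-to-end run (YAML-loadable)."""

    inputs: list[str]
    output_dir: str
    epsilon: float = 1e-3
    speed_scaling: bool = False
    reference_speed: float = 0.015
    sectors: int = 8
    exit_radius: float = 0.2
    trim_distance: float = 0.01
    n_simulations: int = 10_000
    seed: int = 0
    speed_mode: str = "global"
    msd_max_events: int = 30

    def __post_init__(self):
        if self.n_simulations < 1:
            raise ConfigError("n_simulations must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:12]


def _collect_files(inputs: list[str]) -> list[Path]:
    files: list[Path] = []
    for item in inputs:
        p = Path(item)
        if p.is_dir():
            files.extend(sorted(q for q in p.iterdir() if q.suffix in (".txt", ".tsv")))
        elif p.is_file():
            files.append(p)
        else:
            raise ConfigError(f"input path does not exist: {p}")
    if not files:
        raise ConfigError("no trajectory files found")
    return files


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the full analysis; returns the report dict (also written to
    ``output_dir`` as JSON plus per-group TSV tables)."""
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = _collect_files(cfg.inputs)
    domain = Domain(exit_radius=cfg.exit_radius, start_trim_distance=cfg.trim_distance)
    part = SectorPartition(S=cfg.sectors)
    seg_cfg = SegmentationConfig(
        epsilon=cfg.epsilon,
        reference_speed=cfg.reference_speed,
        speed_scaling=cfg.speed_scaling,
    )
    groups: dict[str, list[Path]] = {}
    for f in files:
        try:
            traj = read_trajectory_file(f)
            label = str(traj.meta.get("inclination_label", f.parent.name))
        except Exception:
            label = f.parent.name
        groups.setdefault(label, []).append(f)

    master = np.random.SeedSequence(cfg.seed)
    report: dict = {
        "config": asdict(cfg),
        "config_hash": cfg.config_hash(),
        "groups": {},
    }
    for (label, members), ss in zip(sorted(groups.items()), master.spawn(len(groups))):
        rng = np.random.default_rng(ss)
        segmented = []
        summaries = []
        observed_exits = []
        failures = []
        for f in members:
            try:
                traj = read_trajectory_file(f)
                traj = trim_start(traj, domain.start_trim_distance)
                traj = truncate_exit(
                    traj, domain.exit_radius, traj.meta["reference_start"]
                )
                summ = summarize_individual(traj, domain)
                seg = segment_trajectory(traj, seg_cfg)
                segmented.append(seg)
                summaries.append((f.name, summ))
                if summ.exit_heading is not None:
                    observed_exits.append(summ.exit_heading)
            except Exception as exc:  # partial outputs preserved
                failures.append((f.name, f"{type(exc).__name__}: {exc}"))
        if not segmented:
            report["groups"][label] = {"error": "no usable trajectories",
                                       "failures": failures}
            continue
        stats = estimate_sector_stats(segmented, part)
        stats.meta["group"] = label
        stats.save(outdir / f"stats_{label}")
        predicted = predict_exit_headings(
            stats, rng, N=cfg.n_simulations, radius=cfg.exit_radius,
            speed_mode=cfg.speed_mode,
        )
        m_pred, p_pred = hodges_ajne(predicted)
        entry: dict = {
            "n_trajectories": len(segmented),
            "n_segments": int(sum(len(s) for s in segmented)),
            "sector_counts": stats.counts.tolist(),
            "mean_free_path": stats.mean_free_path.tolist(),
            "persistence": stats.persistence.tolist(),
            "predicted_exit_uniformity": {"m": m_pred, "p": p_pred},
            "failures": failures,
        }
        if len(observed_exits) >= 4:
            m_obs, p_obs = hodges_ajne(observed_exits)
            D, p_ks = ks_two_sample(observed_exits, predicted)
            entry["observed_exit_uniformity"] = {"m": m_obs, "p": p_obs}
            entry["exit_comparison_ks"] = {"D": D, "p": p_ks}
        n_max = min(
            cfg.msd_max_events, max(len(s) - 1 for s in segmented)
        )
        if n_max >= 1:
            curve = msd_vs_events(segmented, n_max)
            _write_tsv(
                outdir / f"msd_{label}.tsv",
                ["n", "msd", "ci_low", "ci_high", "replicates"],
                zip(curve.n, curve.msd, curve.ci_low, curve.ci_high,
                    curve.replicates),
            )
        _write_tsv(
            outdir / f"individuals_{label}.tsv",
            ["file", "mean_speed", "residence_time", "trajectory_length",
             "mean_abs_x", "mean_abs_y", "exit_heading", "censored"],
            (
                (name, s.mean_speed, s.residence_time, s.trajectory_length,
                 s.mean_abs_x, s.mean_abs_y,
                 "NA" if s.exit_heading is None else s.exit_heading,
                 int(s.censored))
                for name, s in summaries
            ),
        )
        np.savetxt(outdir / f"predicted_exits_{label}.tsv", predicted,
                   fmt="%.10g", header="exit_heading", comments="")
        report["groups"][label] = entry
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1)
    return report


def _write_tsv(path: Path, header: list[str], rows) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(_fmt(v) for v in row) + "\n")


def _fmt(v) -> str:
    if isinstance(v, float) or isinstance(v, np.floating):
        return f"{v:.10g}"
    return str(v)
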