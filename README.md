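# boltzwalker

Boltzmann Walker analysis of 2-D animal trajectories: segment noisy tracked
paths into straight free paths and reorientation events, estimate
direction-dependent motion parameters, and simulate dispersal.

## The problem

When a walking insect is released on a tilted surface, gravity gives it a
directional cue.  Tracked at video rate, its path is a noisy point cloud;
the behavioral decisions hide in the geometry — how long it walks straight,
and which new heading it picks when it turns.  `boltzwalker` analyzes such
trajectories with the *Boltzmann Walker* model (a velocity-jump process
borrowed from linear transport theory): motion is a sequence of straight
free paths of exponential length (mean free path λ) separated by
instantaneous reorientations drawn from a phase function f(α) with mean
cosine g (the persistence), walked at speed v.  In the diffusive limit the
population spreads with D = vλ/(2(1−g)).

The *extended* Boltzmann Walker lets v, λ and f depend on the walker's
current heading relative to the steepest line, which separates three kinds
of response: speed changes (orthokinesis), longer free paths when aligned
with the slope (klinokinesis), and biased new headings at turning points
(geomenotaxis).  Heading dependence is discretized over 8 sectors, each
carrying empirical distributions (inverse-CDF sampled) of segment lengths
and turning deviations estimated from data.

The toolkit covers the full workflow:

- **trajectory I/O** — the tab-delimited per-individual file dialect,
  start-trim and exit-circle preprocessing (`boltzwalker.trajectory`);
- **segmentation** — bottom-up piecewise-linear agglomeration with a
  maximum point-to-axis error criterion ε (`boltzwalker.segmentation`);
- **circular statistics** — axial summaries by angle doubling and the
  Hodges–Ajne uniformity test (`boltzwalker.circular`);
- **walker models** — exact simulation of standard and extended walkers,
  closed-form diffusion oracles (`boltzwalker.bw`, `boltzwalker.extended`);
- **dispersal metrics** — MSD versus reorientation events, exit headings,
  two-sample KS comparison (`boltzwalker.dispersal`);
- **synthetic validation** — constant-rate resampling, tracking noise,
  parameter-recovery experiments (`boltzwalker.synthetic`);
- **pipeline + CLI** — `boltzwalker run --config run.yaml` orchestrates
  segment → estimate → simulate → compare over a directory of files
  (`boltzwalker.pipeline`, `boltzwalker.cli`).

## Worked example

Simulate a known walker, degrade it to camera-like data, and recover its
parameters (`examples/02_segment_and_recover.py` is this script):

```python
import numpy as np
from boltzwalker import (
    BWParameters, SegmentationConfig, Trajectory,
    segment_trajectory, simulate_bw_events,
)
from boltzwalker.synthetic import add_tracking_noise, resample_constant_rate

rng = np.random.default_rng(0)
params = BWParameters(speed=0.015, mean_free_path=0.01, g=0.6)
walk = simulate_bw_events(params, 500, rng)          # 500 true free paths

pts = resample_constant_rate(walk.xy, v=0.015, dt=0.04)   # 25 Hz camera
pts = add_tracking_noise(pts, 1e-4, rng)                  # sub-mm noise
traj = Trajectory(xy=pts, t=0.04 * np.arange(len(pts)))

# criterion = 4 tracking-noise SDs: noise never spawns segments
seg = segment_trajectory(traj, SegmentationConfig(epsilon=4e-4))
lam_hat = seg.lengths.mean()
g_hat = np.cos(seg.deviations).mean()
print(f"recovered {len(seg)} segments")
print(f"lambda_hat = {lam_hat:.4f} m   (true 0.0100)")
print(f"g_hat      = {g_hat:.3f}       (true 0.600)")
```

Output:

```
recovered 352 segments
lambda_hat = 0.0154 m   (true 0.0100)
g_hat      = 0.535       (true 0.600)
```

352 of 500 free paths are resolved at a criterion of 4 tracking-noise SDs:
turns smaller than the angle resolvable at ε merge into their neighbors,
so the recovered mean free path reads high by roughly the unresolved
fraction, and the persistence reads low because the merged-away deviations
are the near-zero (high-cosine) ones.  On noise-free data a demanding
criterion resolves ≈ 90% of turns; the resolution biases and the
calibrated criterion are characterized in `docs/methods.md`.

Other narrative scripts in `examples/`: standard-walker simulation and
diffusion check (`01`), heading-sector estimation and extended simulation
(`03`), dispersal statistics and the MSD oracle (`04`), the end-to-end
pipeline on a synthetic colony (`05`).

## CLI

```sh
boltzwalker segment --epsilon 0.001 data/*.txt        # segment table (TSV)
boltzwalker headings --window 1.0 data/*.txt          # axial heading stats
boltzwalker estimate --outdir stats/ data/*.txt       # sector statistics
boltzwalker simulate-ext --stats stats/ --n 10000 --seed 1 --out exits.tsv
boltzwalker msd data/*.txt                            # MSD vs events
boltzwalker validate --grid 0.01,0.015,0.02 --reps 30 # recovery experiment
boltzwalker run --config run.yaml                     # full pipeline
```
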