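# Methods

## The model

`boltzwalker` treats a walking animal as a *Boltzmann Walker* (a 2-D
velocity-jump process): motion is a sequence of straight *free paths*
separated by instantaneous reorientation events.  Three quantities specify
the standard, isotropic walker:

- **speed** `v` (m/s) — constant along a run; stops are treated as part of
  the time budget, not of the geometry;
- **mean free path** `λ` (m) — the process is memory-less, so free-path
  lengths are exponential with survival `P(L > l) = exp(−l/λ)`;
- **phase function** `f(α)` — the density of the signed turning deviation
  `α ∈ (−π, π]`, symmetric about 0, summarized by its mean cosine
  `g = E[cos α]` (the anisotropy or persistence coefficient; `g = 0` is a
  pure random walk, `g → 1` never turns).

For generation the package uses the elliptical family: `f(α)` proportional
to the polar radius of an ellipse with one focus at the origin,

    f(α) = sqrt(1 − e²) / (2π (1 − e cos α)),   e = 2g / (1 + g²),

sampled by exact inverse CDF
`α = 2·atan( sqrt((1−e)/(1+e)) · tan(π(u − ½)) )`.  The closed form of the
CDF makes the sampler exact and invertible; the contract `E[cos α] = g`
holds analytically and is asserted numerically in the tests.

In the diffusive limit the population spreads with
`D = vλ / (2(1 − g))` and the transport mean free path is
`λ* = λ/(1 − g)`.  A closed-form finite-`n` mean square displacement is
used as an oracle throughout the tests: for `n` exponential steps with
first-order directional correlation `g`,

    E[R_n²] = 2λ² [ n + n·g/(1 − g) − g(1 − gⁿ)/(1 − g)² ],

which reduces to `2nλ²` at `g = 0`, to `2λ²` at `n = 1`, and has the
asymptotic slope `2λ²/(1 − g)` per event consistent with `D`.  The form is
cross-checked against brute-force simulation before being trusted.

### The extended walker

On an inclined support, `v`, `λ` and `f` may depend on the walker's heading
relative to the steepest line (klinokinesis + geomenotaxis).  The extended
walker discretizes this dependence over `S = 8` half-open heading sectors
of width `2π/S`, sector 0 centered uphill.  Each sector carries the
empirical distributions of the segments whose heading falls in it: segment
lengths and signed deviations as discretized ECDFs (101 grid points over
the sample range, `F(a₀) = 0` forced, inverse sampled with linear
interpolation), plus scalar summaries (mean speed, mean length, mean
cos α).  The simulation loop draws, at each event, the free path and then
the deviation from the ECDFs of the sector of the *current* heading; this
fixes the estimation convention: a segment's length and speed condition on
its own heading, a deviation conditions on the pre-turn heading.  Speed is
treated as isotropic by default (`speed_mode="global"`), since it only
scales time stamps and heading-dependence of speed is typically absent;
a per-sector mode is available.

Coordinate convention everywhere: y runs along the steepest line (positive
uphill), x horizontal; headings in `(−π, π]` with 0 uphill, increasing
counterclockwise; meters and seconds throughout.

## Segmentation

Tracked positions are noisy samples, so free paths are recovered by
bottom-up piecewise-linear agglomeration.  A run of consecutive points is
represented by the segment joining the orthogonal projections of its first
and last points onto the principal axis of the run's covariance; the run's
error is the maximum perpendicular point-to-axis distance (distances are
measured to the infinite axis line, matching the projection construction;
eigenvalue ties break toward the first-to-last chord).  Starting from the
finest partition, the algorithm repeatedly applies the pairwise merge (two
adjacent runs → one) or triple merge (three adjacent runs → two, split at
the interior point minimizing error) with the smallest resulting error —
always recomputed from the raw points — until no candidate stays within
the criterion `ε`.  Ties between a pair and a triple merge prefer the pair
(the smaller change), then the leftmost candidate; this plus the explicit
generator seeding makes runs bit-reproducible.  A priority queue with lazy
invalidation re-evaluates only candidates overlapping a changed run, and
prefix sums make each axis fit O(1) plus one pass for the maximum
distance; ~38k points segment in ~15 s on one core.

`ε` is ultimately a minimal resolvable turning angle at the data's spatial
sampling frequency, so it should scale with the mean inter-point spacing:
`scale_criterion` applies `ε = ε₀ · v̄ / v_ref` (linear in mean speed at a
fixed frame rate).  The shipped analysis default `ε₀ = 1 mm` at
`v_ref = 0.015 m/s` keeps sub-noise wiggles (sub-millimeter tracking
noise) from spawning segments.

### Validation on synthetic data and the calibrated demanding criterion

Ground truth is unavailable for real animals, so the segmentation is
validated on its own generator: a standard-BW walk with known `(λ, g)` is
resampled at constant arc-length spacing (camera at fixed rate filming a
constant-speed walker; corners are crossed, not snapped), optionally
perturbed with i.i.d. Gaussian tracking noise (default σ = 2×10⁻⁴ m per
coordinate), and segmented.  Estimators: `λ̂` = mean recovered segment
length, `ĝ` = mean cos of recovered deviations.

The reference benchmark uses a walk of exactly 2266 free paths with
`g = 0.6`, `λ = 0.01 m`, resampled at spacing `λ/16.7` (≈ 37.9k points),
zero noise.  The demanding criterion for this noise-free setting is
calibrated once against the benchmark's known resolution behavior:

- for `ε ≳ 0.3 × spacing`, corners with small deviations are absorbed into
  single runs (under-segmentation);
- for `ε ≲ 0.2 × spacing`, the sample pair straddling a corner can fail to
  join either adjacent run and survives as a spurious two-point segment
  (over-segmentation);
- the crossover, `ε = 0.24 × spacing ≈ 1.44×10⁻⁴ m`, resolves ≈ 90% of
  reorientation events — the reference resolution for this benchmark
  (≈ 2037 of 2266 segments recovered).  It is frozen as the package
  default for noise-free validation.

Two resolution biases are inherent and documented rather than hidden.
Missed breakpoints are concentrated at small `|α|` (two nearly aligned
free paths merge when their deviation falls below the minimal angle
resolvable at `ε`), so `λ̂` is biased up by the inverse of the resolved
fraction (≈ +11% at the reference sampling of 16.7 points per free path,
shrinking to ≈ +2% at 33 points per path) and `ĝ` slightly *down* at
reference sampling (the removed deviations are the high-cosine ones,
≈ −0.02).  Conversely, at fine relative sampling (≳ 50 points per path)
the corner-straddling sample pair increasingly splits one turn into two
smaller ones, pushing `ĝ` *up*.  The estimators are therefore validated
over an operating range of roughly 17–33 points per free path (mean free
paths of 1–2 reference units at the reference camera): there the
grid-pooled `λ̂/λ` stays within 10%, `ĝ` within 0.05 per grid point, and
the ranking of recovered `λ̂` across the grid is exact.

What the synthetic generator does *not* emulate: variable speed within a
run, pauses, body-axis wobble, and non-Gaussian tracking outliers.
Passing recovery tests therefore demonstrate correctness of the
segmentation and estimation machinery under the model's own assumptions,
not robustness to every artifact of real video tracking.

## Circular statistics

Headings on a slope are axial (up and down favored together), so summaries
double the angles modulo 2π, compute the circular moments of the doubled
sample, and back-transform: mean axis `φ̄ = φ*/2 ∈ [0, π)`, axial angular
deviation `s = sqrt(2(1 − R̄))/2`.  Uniformity is tested with the
Hodges–Ajne statistic `m` (minimum count in any half-plane bounded by a
diameter, found by sweeping the data-defined diameters).  The exact
combinatorial p-value `(n − 2m)·C(n, m)·2^(1−n)` is used for `n ≤ 50`, the
large-sample approximation above that.  The test is applied to the
*doubled* angles by default: the raw statistic is blind to antipodally
symmetric departures (two opposite clusters leave every half-plane with
~n/2 points), while doubling folds opposite modes together and leaves the
uniform null unchanged.  A `double=False` flag restores the raw test.

Short-time heading estimates (`local_headings`) split a track into 1-s
windows and report the orientation of each window's first principal
component, axial by default, optionally sign-resolved by net displacement.

## Dispersal metrics

MSD is indexed by the number of reorientation events, not time, making it
insensitive to speed fluctuation and stops; lags pool overlapping windows
within and across trajectories, so the reported confidence bounds are
approximate (autocorrelated windows).  Exit headings are the angle of a
track's first crossing of the exit circle — exact segment–circle
intersection for simulated walkers, linear interpolation of the first
inside→outside step for sampled tracks.  Observed and predicted exit
samples are compared with the two-sample Kolmogorov–Smirnov test on raw
angles; a linear test on circular support is questionable in principle
(it is not rotation-invariant) but is the field's standard comparison and
is kept for comparability.

## Pipeline, seeding and problem sizes

`run_pipeline` groups files by inclination label (directory-name
fallback), preprocesses (trim the first 1 cm of excursion from the
dropping site; truncate at the first exit from the 0.2 m circle, censored
tracks flagged and kept), segments, pools per-sector statistics, simulates
the parameterized extended walker, and writes TSV/JSON reports.  All
randomness derives from a single master seed through `SeedSequence`
substreams, one per group, so reruns are byte-identical.

The shipped validation suite runs at desk scale, chosen to keep the full
check under a few minutes per property while leaving Monte-Carlo error
well below every tolerance: 10 seeds of the 2266-segment benchmark; 100
replicates per grid point (300 total) of 50-segment walks for recovery;
10⁴ walkers for the diffusive limit; 20 pipeline runs of 69 synthetic
individuals for the isotropy null, compared at an exit-sample size of 100
simulations per run.  That last size is deliberate: per-sector statistics
estimated from a finite data set carry sampling anisotropy of order
`1/sqrt(segments per sector)`, which arbitrarily many simulated walkers
would eventually resolve; comparing at the scale of an observed sample
(~10² exits) asks the scientifically relevant question — whether the
pipeline itself introduces anisotropy detectable at data scale — rather
than whether an estimate from finite data is exactly isotropic (it never
is).

## Numerical choices and degenerate inputs

- Angle wrapping maps to `(−π, π]`, with `−π → +π`; sector boundaries are
  half-open, boundary angles belong to the counterclockwise sector.
- ECDF grids force `F(a₀) = 0` at the sample minimum (a vanishing bias at
  the lower edge); degenerate (constant) samples are flagged and sample as
  the constant.
- All-identical point runs raise a degenerate-geometry error in
  `fit_segment`; inside the agglomeration engine they have zero error by
  construction and merge freely.
- Censoring (a track that never exits the circle) is a flagged outcome,
  never an error; empty heading sectors are flagged at estimation and
  refuse simulation with a diagnostic.
- Boundary crossings are solved exactly (quadratic segment–circle
  intersection), so exit points sit on the circle to ~10⁻¹² m.

## Known limitations

- The extended walker discretizes heading dependence over sectors; within
  a sector the dependence is flat.  Position-dependent parameters
  (heterogeneous landscapes) are out of scope.
- Negative persistence (u-turners) is excluded from the elliptical family;
  empirical ECDF sampling covers such shapes when estimated from data.
- `λ̂` from mean segment length inherits the resolution bias described
  above; comparisons across conditions with very different speeds should
  use the speed-scaled criterion to keep the bias comparable.
- The linear KS test on exit headings ignores circular topology.
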