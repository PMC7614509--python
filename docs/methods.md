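# Methods

This note documents the models, parameters, numerical choices, and known
limitations of `gcsearch`. It is the design record a maintainer should read
before changing defaults.

## The scientific setting

Germinal centers (GCs) are sites of intense B-cell death. Tingible body
macrophages (TBMs) clear the resulting apoptotic-cell fragments, yet
intravital imaging shows TBMs are stationary — an apparently "lazy" search
strategy for a predator whose prey moves. The package quantifies this
predator–prey system three ways:

1. **Track motility statistics** — mean velocity, displacement, meandering
   index (MI), and the MSD anomalous exponent α of imaged 3D tracks.
2. **Spatial dispersion** — whether TBM centroids are more evenly spaced
   than a random hard-sphere arrangement, via the nearest-neighbor index
   (NNI) against a Monte Carlo null.
3. **An agent-based clearance simulator** — stationary versus migratory
   TBMs removing motile fragments in a spherical GC, with parameter sweeps.

## Motility statistics (`motility`)

* **Mean velocity** is the mean of per-step speeds in μm/min. With gap-free
  uniformly sampled tracks this equals path length / duration; both readings
  of "mean velocity" coincide, so only one is implemented. Zero-length steps
  count as observed zero speeds; they are skipped in turn angles (no
  direction).
* **MI** = straight-line displacement / path length ∈ [0, 1]; 1 iff every
  step is collinear and co-directional.
* **MSD** is time-averaged per track over all overlapping frame pairs, then
  ensemble-averaged (unweighted) over tracks contributing at each lag. This
  is the standard estimator for short noisy tracks and is fixed so tests can
  be exact. α is the least-squares slope of log MSD vs log lag over lags
  1..⌊max/4⌋ by default (the window is exposed); the restriction avoids the
  poorly populated long-lag tail.
* The duration filter keeps tracks strictly longer than 150 s (five 30-s
  frames), the convention used when the imaging tracks were curated.

## Dispersion null (`spatial_stats`)

The null places 18 non-overlapping spheres of radius 10 μm (macrophage
bodies) uniformly in a container sphere of radius 81 μm — the radius of a
sphere holding the mean measured GC volume of 2.23×10⁶ μm³ — by sequential
rejection sampling, restarting a configuration if an insertion stalls.
Spheres are fully contained (centers within R − r): the modeled macrophages
sit inside the GC. Fifty placements pool 900 nearest-neighbor distances;
their grand mean (≈30.5–31.5 μm) is the random-placement expectation.
Observed mean NND (41 μm in the imaging data) over this expectation gives
NNI ≈ 1.3, i.e. TBMs are dispersed. Significance uses the two-sided
Wilcoxon rank-sum between distance samples, the generic test used for the
imaging comparisons.

## Fragment movement law and calibration (`calibration`)

Fragment motion is a persistent random walk with three ingredients:

| ingredient | law | default | origin |
|---|---|---|---|
| per-step speed | LogNormal(μ, σ) μm/min | μ=1.17, σ=0.335 (mean 3.41) | MLE fit to imaged fragment speeds |
| turn angle / π | Beta(α, β) | α=2.02, β=1.707 | MLE fit to imaged turn angles |
| per-cell meander probability | LogNormal(μ_m, σ_m), clamped to [0,1] | μ_m=−1.08, σ_m=0.50 | this package's calibration (below) |

* Lognormal MLE is closed form: mean and population (1/n) standard
  deviation of the log samples. The 1/n choice is below any test tolerance
  but fixed for determinism.
* Beta MLE maximizes the standard-Beta likelihood (`scipy.stats.beta.fit`
  with location/scale fixed); boundary samples are nudged inward by 1e-6.
* Turn angles in [0, π] map to the Beta support by θ/π — the minimal
  bijection.
* The two-sample Anderson–Darling test uses the ties-adjusted (midrank)
  k-sample statistic with the exact finite-N variance. The asymptotic
  p-value interpolates the published critical-point table quadratically in
  log significance and extrapolates linearly (tangent slope) beyond it, so
  near-identical samples report p ≫ 0.25 instead of a clipped 0.25.

**Meander calibration.** MI is an emergent property of the walk, so the
meander lognormal cannot be sampled from a fitted MI distribution directly.
`calibrate_meander` grid-searches (μ_m, σ_m): fragment-only simulations
(reflecting wall, no removal) are resampled at the 30-s imaging cadence —
the walk runs at 15-s steps, and the coarser observation absorbs the
resolution mismatch of applying 30-s-interval turn statistics per 15-s step
— and per-track MIs are compared to the observed MI sample with the AD
test; candidates are ranked by p, with p > 0.05 "accepted".

**Shipped defaults.** No observed MI sample ships with the package, so the
default (μ_m, σ_m) was fixed by a different, documented calibration: a grid
search selecting the parameters at which the *stationary dispersed*
simulation at observed conditions reproduces the reported stationary
clearance rate of 1.21 %/min (selected: μ_m=−1.08, σ_m=0.50, giving
1.218 ± 0.008 %/min over 24 replicates). Only the stationary condition was
used for selection; migratory and random-placement conditions are
independent predictions (see "Known limitations"). σ_m is weakly identified
by a single rate target; 0.50 (moderate per-cell heterogeneity) was chosen
as the middle of the plausible range, and the stationary rate is insensitive
to σ_m at fixed achieved rate.

## The clearance simulator (`abm`)

Geometry and schedule (defaults): GC sphere of volume 2.23×10⁶ μm³
(radius 81.05 μm); 18 TBM hard spheres of diameter 27 μm (the sphere
holding the mean measured TBM volume, ~10,306 μm³); 2,665 fragments of
diameter 3.54 μm; 15-s steps for 75 simulated minutes. Clearance rate =
removals / (n_fragments × duration) × 100, in %/min; the fragment count is
conserved (every removal spawns a replacement).

Placement:

* **dispersed** — whole TBM configurations are resampled until the mean
  nearest-neighbor distance is within `nnd_tolerance` (default 2 μm) of the
  observed 41 μm. Plain non-overlapping proposals center near 34 μm, making
  41 a far-tail event, so proposals are drawn with an inflated exclusion
  distance (0.9 × target — still valid non-overlapping configurations);
  the acceptance criterion is unchanged and the accepted ensemble centers
  on the target.
* **random** — plain non-overlapping placement (mean NND ≈ 34 μm at the
  13.5-μm TBM radius).

Dynamics, per step, in fixed agent order:

1. Every fragment draws a speed from the lognormal. With probability
   `meander_chance` it steps directly away from its spawn point (a
   "meander"); otherwise its heading is rotated by pitch and roll angles,
   each π·X with X ~ Beta and an independent random sign, about two axes
   orthogonal to the heading, and it steps along the new heading. Turn draws
   are made for every fragment each step so the random stream is
   shape-stable.
2. Migratory TBMs move at constant speed (default 5 μm/min) under the same
   heading-update law, rejecting moves that overlap another TBM or exit the
   arena (10 retries, then stay put). Stationary TBMs do not move.
3. Any fragment whose center is within (TBM radius + fragment radius)
   = 15.27 μm of a TBM center is removed, counted, and replaced by a fresh
   fragment (new spawn point, heading, and meander chance) placed uniformly
   outside all capture radii — excluding capture interiors avoids spurious
   zero-lag recapture.

Contact is tested at end-of-step positions only: the mean fragment step
(≈0.85 μm) and TBM step (1.25 μm) are far below the capture radius, so
tunneling is negligible.

**Boundary.** The default is **exit-respawn**: a fragment whose step leaves
the GC is replaced at a random interior position (not counted as cleared).
This mirrors the imaging observation that fragments migrate out of the GC
into the subcapsular region, and it is required for a sustained clearance
rate: with a reflecting wall (`boundary="reflect"`, retained as an option
and used wherever continuous trajectories are needed — track generation and
MI calibration), outward-meandering fragments accumulate in a shell at the
wall (90% of fragments within 11 μm of it by 75 min) and the clearance rate
decays several-fold within a run, capping the 75-min mean near 0.85 %/min
for any meander setting.

**RNG.** One `numpy` PCG64 generator per run drives all draws in a fixed
order; identical (config, seed) runs are bit-identical. Replicates and
sweeps derive child seeds via `SeedSequence`. (A per-agent hashed-stream
scheme was considered and rejected: it precludes the vectorization that
keeps a full observed-condition run around 2 s.)

**Sweeps.** `sweep` varies TBM volume (diameter recomputed), fragment
count, or a (mean fragment speed, count) grid — speed realized by shifting
the lognormal location at fixed shape — for both TBM modes with rank-sum
comparisons per value. `crossover_density` interpolates mean clearance vs
log₁₀ density with a monotone PCHIP spline per mode, locates the root of
the migratory−stationary difference by bisection, and bootstraps replicates
within conditions for a percentile CI; non-crossing curves return an
explicit out-of-range result.

## Synthetic data (`synthetic_data`)

`gen_tracks` produces track tables with the statistical structure the
analysis assumes: `fragment` mode delegates to the simulator's own step law
(no TBMs, reflecting wall) subsampled to the 30-s imaging cadence, so
calibration tests are true inverse problems — generator and fitter share
only the forward model. `ballistic` (MI exactly 1, α≈2), `brownian`
(α≈1), and `stationary` (α≈0) modes give analytically known references.
Optional lognormal duration censoring emulates tracks truncated by the
imaging volume. What these generators do **not** emulate: segmentation
noise, drift, track fragmentation/id switches, and fragment–fragment
interactions — so passing tests validate the statistical pipeline, not
robustness to imaging artifacts.

## Problem sizes used by the shipped checks

The acceptance script pools the dispersion null over 20 seeds (18,000
distances), uses 20 replicates per simulated clearance condition, and 10⁵
draws for MLE-recovery checks — sizes at which Monte Carlo error is well
below the comparison tolerances while a full recomputation stays within a
few minutes on one core.

## Known limitations

* **The migratory and random-placement clearance rates disagree with the
  reported values, and this is a property of the published rules, not a
  tuning failure.** Any parameterization that sustains the reported
  stationary rate of 1.21 %/min turns over ~91% of the fragment population
  in 75 min, which requires fragments to mix through the GC. For mixing
  prey and absorbing spheres, kinetic theory is unforgiving: a TBM moving
  at 5 μm/min encounters prey at the relative-speed rate — this simulator
  yields a migratory/stationary ratio of 1.39, close to the kinetic factor
  √(v_f² + v_T²)/v_f ≈ 1.36 — so migration must *increase* clearance, not
  halve it as reported. Likewise, moving 18 capture spheres from dispersed
  (NND 41 μm) to random (NND ≈ 34 μm) placement changes total capture
  coverage by ~2%, which cannot produce the reported 3.5-fold drop. The
  reported ordering (stationary ≫ migratory; dispersed ≫ random) therefore
  must arise from features of the original closed-source simulation that
  its written description does not state. Boundary variants (reflecting,
  reflecting with origin reset, exit-respawn), contact conventions, and
  meander extremes were all tested; none reverses the ordering. The
  implementation reports its own, kinetically consistent numbers.
* The migratory TBM walk law is the main free modeling choice (the source
  description is silent); the fragment heading-update law at constant speed
  is used.
* The meander σ_m default is weakly identified (see calibration above);
  analyses sensitive to per-cell MI heterogeneity should calibrate
  `calibrate_meander` against their own observed MI sample.
* Fragments do not interact after initial placement; TBM processes,
  chemotaxis, satiation, and GC zonal structure are out of scope — the TBM
  capture sphere is an effective volume that already understates the reach
  of its processes.
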