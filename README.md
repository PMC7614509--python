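# gcsearch

Motility statistics, spatial dispersion nulls, and an agent-based clearance
simulator for germinal-center tingible body macrophages (TBMs).

## The problem

Germinal centers (GCs) are sites of massive B-cell apoptosis. The resident
scavengers, TBMs, are stationary, yet they must clear a population of motile
apoptotic-cell fragments — an unusual predator–prey arrangement in which the
prey moves and the predator sits still. This package provides the
computational toolkit for analyzing that arrangement from 3D imaging
exports and for simulating it:

* **Track motility** — per-track mean velocity (μm/min), displacement,
  meandering index MI = displacement/path length ∈ [0, 1], and the ensemble
  mean squared displacement with its anomalous exponent α (log MSD vs log
  lag slope: α≈1 diffusive, α≈2 ballistic).
* **Spatial dispersion** — nearest-neighbor distances (NND) of TBM
  centroids against a hard-sphere Monte Carlo null (18 non-overlapping
  10-μm spheres in an 81-μm GC sphere, 50 placements), summarized by the
  nearest-neighbor index NNI = observed mean NND / null mean NND.
* **Movement-law calibration** — lognormal MLE for per-step fragment
  speeds, Beta MLE for π-normalized turn angles, and a grid-search
  calibration of the per-cell meander probability using the two-sample
  Anderson–Darling test on MI distributions.
* **Agent-based simulation** — stationary vs migratory TBM spheres clearing
  a constant population of random-walking fragments in a spherical GC, with
  parameter sweeps (TBM volume, fragment abundance, speed×abundance grids)
  and rank-sum comparisons between conditions. The headline statistic is
  the clearance rate, `removals / (n_fragments × duration) × 100` in %/min.

Intended users: quantitative immunologists working with intravital
two-photon tracking exports (Imaris-style "Position" tables), and modelers
studying search strategies of phagocytes.

## Worked example

Generate synthetic fragment tracks (the generator shares the simulator's
forward movement law), compute motility statistics, and build the
dispersion null:

```console
$ gcs synth tracks --mode fragment --n 200 --frames 40 --seed 7 --out frag_tracks.csv
wrote 200 fragment tracks -> frag_tracks.csv

$ gcs motility frag_tracks.csv --min-duration 150 --out stats.csv
200 tracks: mean velocity 2.63 μm/min, median MI 0.501, MSD alpha 1.58

$ gcs nnd-null --seed 1
null: n=900 mean NND 31.36 μm
```

The mean velocity (2.63 μm/min at the 30-s sampling interval) is lower than
the 3.41 μm/min per-15-s-step mean of the generating lognormal because
coarser sampling hides path tortuosity; α = 1.58 reflects the directional
("meander") component of fragment motion. The null mean of ≈31 μm is the
NND expected if 18 macrophages were placed at random in the GC — observed
TBM spacing of 41 μm gives NNI ≈ 1.3, i.e. TBMs are actively dispersed.

Run one clearance simulation at observed GC conditions (18 dispersed
27-μm TBMs, 2,665 fragments, 75 min):

```python
>>> from gcsearch.abm import SimConfig, run
>>> res = run(SimConfig(tbm_mode="stationary"), seed=42)
>>> print(f"{res.clearance_rate:.3f} %/min ({res.removals} removals)")
1.264 %/min (2526 removals)
```

Equivalently from the shell: `gcs simulate --seed 42`. Sweeps over fragment
abundance with both TBM modes: `gcs sweep --axis fragment_count --values
10:7000:log --reps 8`.

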