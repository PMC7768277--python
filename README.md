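# punctaquant

Quantification of punctate fluorescent cargo in live-cell and fixed-cell
microscopy, for two widely used assays:

1. **Axonal transport from kymographs.** Time-lapse movies of a motor or
   vesicle marker (e.g. KIF1A-GFP carrying dense core vesicles) are
   resampled along an axon path into a kymograph; per-punctum
   trajectories are segmented into directed runs and summarized as flux,
   velocity, run length and directionality, per direction of travel.
2. **Organelle dispersion from radial line scans.** Single-frame images
   of a punctate organelle marker (e.g. the Golgi marker giantin, after
   chemically induced motor recruitment) are profiled by 360 line scans
   from the nucleus centroid to the cell periphery, yielding a per-cell
   dispersion profile over normalized radial distance.

Both arms come with a ground-truthed synthetic-data generator, so every
stage of the pipeline is testable end to end without any experimental
download, and a statistics layer that performs the group comparisons
these assays conventionally use.

## The statistics at the core

**Flux.** With run lengths `dᵢ` (μm), imaged axon length `l` (μm) and
movie duration `t` (min),

```
flux = Σᵢ |dᵢ| / (l · t)        [min⁻¹]
```

A trajectory segment qualifies as a **directed run** if it covers at
least 2 μm. The threshold is a safe estimate of the diffusion limit: a
passive cargo with diffusion coefficient `D = 0.01 μm²/s` observed for
`t = 50 s` has 1-D RMS displacement `√(2Dt) = 1 μm`, so 2 μm cannot be
reached by diffusion except at the Gaussian-tail rate `2Φ(−2) ≈ 4.6%`.
A run terminates when the punctum stays in place for at least four
consecutive frames (or reverses direction sustainedly). Velocity is
per-run displacement over duration; anterograde means away from the
soma. Percent flux normalizes a treated condition to its control.

**Dispersion profile.** Per cell: 360 radial line scans → scaled
background subtraction (a cargo-free scan resampled onto each scan's
normalized distance axis) → nuclear samples removed, distances mapped to
0 (nuclear membrane) … 1 (cell periphery) → duplicate pixels near the
centre counted once → 20 distance bins of width 0.05, top 200 pixel
intensities per bin averaged. Group profiles are mean ± SEM per bin;
conditions are compared with a per-bin two-tailed unpaired Student's
t-test, and transport metrics with one-way ANOVA + Tukey HSD.

## Worked example

Simulate one cell's transport movie, quantify it, and compare with the
generator's ground truth:

```sh
$ punctaquant simulate-transport --seed 5 --out demo
simulated 20 puncta, true flux 4.123 min^-1 -> demo

$ punctaquant quantify-transport --trajectories demo/trajectories.csv \
      --axon-length 100 --duration 1.4917 --stationary-eps 0.5 --out demo_q
44 runs; flux all/antero/retro = 3.939/3.430/0.509 min^-1 -> demo_q
```

The simulator placed 20 puncta (half anterograde, a quarter retrograde,
a quarter stationary) in a 100-μm axon for 90 s and recorded a true flux
of 4.123 min⁻¹ over 70 generated runs. The pipeline, given only the
trajectories, segments 44 runs ≥ 2 μm (short runs fall below the
diffusion-limit criterion and merged pauses join others) and recovers a
total flux of 3.939 min⁻¹ — within 5% — split 3.430/0.509 between
anterograde and retrograde, matching the simulated 2:1 motile-fraction
asymmetry. `demo_q/` contains the per-run table (`runs.csv`), the
summary in the conventional flux/velocity/run-length layout
(`summary.csv`, `summary.json`) and a manifest of all parameters used.

The dispersion arm, end to end on one simulated cell:

```sh
$ punctaquant simulate-golgi --seed 3 --dispersion-scale 0.8 --out demo_g
simulated cell at dispersion_scale=0.8 -> demo_g

$ punctaquant quantify-golgi --image demo_g/cell.tif --masks demo_g/cell_masks.tif \
      --background-angle 200 --out demo_gq
profile written (weighted mean distance 0.435) -> demo_gq
```

At dispersion scale 0.8 the organelle signal is scattered toward the
periphery, and the profile's intensity-weighted mean normalized distance
comes out at 0.435 (a perinuclear cell at scale 0 gives ≈ 0.10–0.15).
`demo_gq/profile.csv` holds the 20-bin profile; `compare-groups` takes
two sets of such per-cell profiles and writes group means ± SEM and the
per-bin t-tests with significance stars.

The same functionality is available as a library
(`punctaquant.simulate`, `.kymo`, `.transport`, `.golgi`, `.stats`);
real data enter as TIFF stacks plus an axon-path CSV, as trajectory CSVs
(e.g. manual kymograph traces), or as image + label-mask TIFF pairs for
the dispersion assay.

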