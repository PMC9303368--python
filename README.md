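# mcpalm — motion-correction PALM for moving chromatin loci

`mcpalm` analyzes correlative conventional-fluorescence + single-molecule
localization (PALM) movies of genomic loci — for example telomeres labeled
with dCas9-GFP while individual dCas9/MCP probes are tracked one molecule at
a time. Live-cell PALM accumulates localizations over minutes, but chromatin
moves on that timescale, so raw localizations smear along the locus
trajectory and cannot be turned into structure. The package solves this by
tracking the diffraction-limited conventional signal of each locus,
interpolating its position into every PALM frame, and

1. **classifying** each single-molecule trace as *bound*, *partially bound*
   or *unbound* by whether its localizations fall inside the moving locus
   footprint (radius + both localization precisions) — a geometric criterion
   that works even when bound and unbound mobilities overlap;
2. **motion-correcting** bound localizations by subtracting the interpolated
   locus trajectory, recovering the time-averaged sub-diffraction structure
   of the locus (convex-hull area, extension, radius of gyration, covariance
   ellipse, duration-normalized localization density);
3. **quantifying mobility** from time-averaged mean squared displacements,
   ⟨r²⟩(Δt) = 4DΔt + 2σ², with Gaussian-mixture modeling of log₁₀D
   (BIC-selected), distribution-overlap coefficients, and the mobility of
   bound molecules *relative to* the locus they sit on.

It is written for microscopists and chromatin biophysicists who already have
localization tables (Insight3/ThunderSTORM-style CSV/TSV exports); raw-frame
fitting is out of scope. A synthetic-experiment module generates complete
correlative acquisitions with ground truth, so every stage of the pipeline
can be validated without proprietary data.

## The model in brief

* **Acquisition**: a repeating shutter cycle (default 10 frames at 20 Hz):
  frame 1 conventional image, frame 2 photoactivation, frames 3–10 PALM.
* **Linking**: single molecules are linked within 0.48 µm across consecutive
  PALM frames (no dark frames, ≥ 4 localizations); conventional cluster
  localizations within 0.68 µm across cycles (≥ 5 localizations, fitted
  widths within 200 nm — a focus-continuity filter).
* **Registration**: the single-molecule channel is mapped onto the
  conventional channel with a full bivariate polynomial of total degree 3
  per axis, fitted to multi-field bead calibrations; precision is reported
  on held-out fields.
* **Colocalization**: localization ℓ at frame *f* belongs to cluster *c* iff
  dist(ℓ, center_c(f)) < radius_c(f) + σ_c + σ_ℓ, with center_c linearly
  interpolated between conventional frames and radius_c held from the last
  conventional localization.
* **Motion correction**: corrected coordinates are raw − interpolated center;
  rigid locus motion cancels exactly and within-frame geometry is preserved.
* **Precision**: per-localization σ from the Thompson formula
  σ² = s²/N + a²/(12N) + 8πs⁴b²/(a²N²).

## Worked example

`examples/01_full_pipeline.py` simulates a 200 s experiment (12 loci, 520
probe molecules) and runs the full analysis:

```
stage counts:
  sm_localizations: 3128
  cluster_localizations: 4800
  traces: 313
  cluster_tracks: 12
  traces_bound: 71
  traces_partially_bound: 16
  traces_unbound: 226
  ...

per-locus structure (motion-corrected):
 cluster_id  n_localizations  radius_of_gyration_nm  area_um2  extension_nm  localization_density_per_um2_s
          0               42                128.673     0.067       410.805                           3.151
          1               63                215.302     0.204       577.748                           1.547
          ...
```

313 single-molecule traces were linked; 71 are classified bound to one of
the 12 locus tracks. After subtracting each locus trajectory, the bound
localizations of, e.g., cluster 0 collapse to a 129 nm radius-of-gyration
cluster — structure far below the diffraction limit despite locus motion.
`examples/04_mobility_states.py` shows why this cannot be done with a
mobility cutoff: the apparent-D distributions of bound and unbound traces
overlap by ~39%, the best possible single D-threshold classifies only 77% of
traces correctly, while the geometric classification reaches 97%.

The other examples cover interpolation-error calibration (`02`), channel
registration (`03`) and motion-corrected structure recovery with
super-resolution rendering (`05`). A thin CLI wraps the same library:

```sh
mcpalm simulate --seed 3 --out sim/
mcpalm run --sm sim/sm_localizations.csv --clusters sim/cluster_localizations.csv \
           --beads sim/bead_pairs.csv --out results/
mcpalm report --results results/
```

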