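# Methods

## The measurement problem

A genomic locus carrying tens of bound fluorescent probes is visible as a
diffraction-limited cluster in a conventional fluorescence channel, while a
PALM channel records sparse single-molecule localizations of individual
probes. Accumulating enough localizations for a super-resolved image takes
minutes; over that time the locus diffuses (and is occasionally actively
transported over micrometres), so localizations of bound probes trace out
the locus trajectory instead of its structure, and slowly diffusing unbound
probes are indistinguishable from bound ones by mobility alone. `mcpalm`
treats the conventional-channel cluster track as a per-locus fiducial: its
interpolated position defines, at every PALM frame, both a co-moving
reference frame (for structure) and a footprint (for classification).

## Pipeline model and assumptions

**Shutter bookkeeping.** Frames are 1-based. A cycle of `cycle_length`
(default 10) frames holds one conventional frame (slot 1), one
activation/bright-field frame (slot 2) and `cycle_length − 2` PALM frames.
"Consecutive" for single-molecule linking means adjacent positions on the
PALM-frame grid; the two non-PALM slots inside a cycle are not dark frames.
A consequence is that one physical lag per cycle is 3 camera frames
(0.15 s at 20 Hz); TAMSD bins displacements by the true frame difference, so
that lag is never averaged into the 0.05 s bin.

**Linking.** Greedy global nearest-neighbour per frame pair: all candidate
links within the radius are sorted by distance and assigned one-to-one
(ties by trace id, then row order), making linking deterministic given
sorted input. Defaults: 0.48 µm and ≥ 4 localizations (single molecules,
no dark frames), 0.68 µm, ≥ 5 localizations and |Δwidth| ≤ 200 nm
(clusters; the width-continuity filter rejects axial drift, since width
changes of 200 nm correspond to roughly the lateral link radius in depth).
Activation is assumed sparse enough that link conflicts are rare; the
generator respects this (~1 active molecule per PALM frame).

**Interpolation.** Cluster centers are linear in frame number between
conventional localizations and exact at the anchors. The cluster radius and
precision are held from the last conventional localization before each
frame. The interpolation-error experiment quantifies the cost: for tracks
localized at the full frame rate, positions at every `cycle_length`-th frame
are used as anchors and the interpolated-vs-observed distance is pooled over
all intermediate frames, plus a mean-error-vs-gap curve up to 20 frames.
Two analytic limits validate it: for a stationary cluster with per-axis
noise σ, the error at fractional position w is Rayleigh with per-axis sd
σ·√(1 + (1−w)² + w²); for pure Brownian motion the bridge variance
2D·τ(T−τ)/T per axis adds to that.

**Registration.** Full bivariate polynomial of total degree 3 (10
coefficients per output axis), plain linear least squares on bead pairs,
with rank and conditioning checks. Because the real instrument's distortion
basis is unknown beyond "3rd-order polynomial", the full total-degree basis
is the least-committal choice. Precision is
estimated by leave-one-field-out cross-validation and reported both as RMS
and mean Euclidean error — the estimator behind a quoted registration
precision is rarely stated, so both are exported.

**Colocalization and classification.** The footprint test is
`dist < radius + σ_cluster + σ_molecule`, nearest footprint wins, exact ties
go to the lower cluster id. σ_cluster comes from the Thompson formula applied
to the cluster localization's photometry. Traces with all members in one
footprint are *bound*; none, *unbound*; anything else *partially bound* —
interpreted as searching or freely diffusing, because probe residence times
when actually bound exceed trace durations by orders of magnitude. Two open
cases are resolved conservatively: a trace whose members co-localize with
different clusters is partially bound and flagged `multi_cluster`; a
would-be bound trace whose "outside" members all fall beyond the host
cluster's observation window is bound, but flagged `excluded_short` (and
dropped from bound statistics) when fewer than 4 of its frames overlap the
window, mirroring the 4-frame mobility cutoff.

**Motion correction and structure.** Corrected coordinate = registered
coordinate − interpolated center at that frame, so the origin is the cluster
center and within-frame relative geometry is untouched. Metrics use standard
definitions: convex-hull area (µm²); extension = maximal pairwise distance
(equal to the hull-vertex diameter); radius of gyration = RMS distance to
the centroid; covariance-ellipse axes = 2·√eigenvalues of the sample
covariance (ddof = 1). Localization density divides the duration-normalized
count (constant photoactivation makes counts proportional to observation
time) by the hull area; the duration-normalized rate alone is also exported,
since "localization density" is used both ways in practice. Rendering sums
unit-integral Gaussians of width equal to each localization's precision.

**Mobility.** ⟨r²⟩(Δt) = 4DΔt + 2σ² by ordinary least squares, with
D = slope/4 and σ = √(intercept/2). σ here is the *combined two-axis*
precision; with per-axis noise σ_ax the intercept is 4σ_ax², i.e.
σ = √2·σ_ax. Negative fitted D (short noisy traces) is retained for
distribution tails but excluded, with a count, from log-mixtures. By default
only the **first two TAMSD points** enter the fit (`max_fit_lags = 2`,
configurable; `None` fits all lags): for traces of ~4–10 localizations the
high lags average one or two strongly correlated displacement pairs, which
makes the all-lag per-trace D̂ distribution so right-skewed that its median
falls ~40% below the true D; restricting to the first lags is the standard
remedy for localization-noise-dominated traces, and in validation brings the
ensemble median within ~5–15% of truth across D from 0.002 to 0.21 µm²/s.
Pooled fits (relative mobility) average MSD curves across traces with
per-lag pair-count weights *before* fitting, and cluster-track lags are the
conventional-frame spacing. Mixtures are Gaussians in log₁₀D with K chosen
by BIC among {1, 2, 3}; the overlap coefficient is ∫min(p̂_a, p̂_b) of
kernel-density estimates (Silverman bandwidth) on the log₁₀D axis.

## The synthetic experiment

The generator emulates the statistical structure the analysis assumes, not
the camera physics. Defaults (all configurable, distances µm, D µm²/s):

| parameter | default | rationale |
|---|---|---|
| movie | 4000 frames (200 s at 20 Hz) | matches the interpolation-error calibration length; desk-scale |
| clusters | 12, log-normal D, median 0.002, 0.5 dex sd | telomere-like locus mobility with ~1 dex spread |
| cluster radius | Gaussian 376 ± 221 nm, clipped to [250, 4181] | fitted-width statistics of telomere clusters |
| cluster noise | 30 nm/axis | Thompson precision of a 376 nm, ~200-photon spot |
| bound molecules | 120; local D 0.006 on top of the cluster motion | bound apparent D ≈ 0.008, faster than the locus itself |
| binding sites | Gaussian sd = 0.4·radius, truncated at the radius | sites lie within the locus the width measures |
| unbound molecules | 400; 70% at 0.21, 30% at 0.008 | fast searching fraction plus a slow fraction overlapping bound mobility |
| photoactivation / bleaching | uniform activation; geometric length, mean 6 PALM frames | constant activation rate; survivable under the ≥4-frame cutoff |
| single-molecule noise | 20 nm/axis | stated single-molecule precision |
| channel warp | cubic, ~1 pixel amplitude; 5 fields × 12 beads, 5 nm noise | typical dual-channel calibration |

Photon counts are drawn so that the Thompson precision of each emitted row
equals the noise actually added (the generator inverts the formula for the
target precision), keeping photometry and noise self-consistent. Setting a
noise parameter to 0 produces an idealized noise-free acquisition. Ground
truth records every molecule's class, true positions, binding-site offset,
and the true per-frame cluster paths; fitted tracks are matched to true
clusters by mean trajectory distance, and linked traces to molecules by
majority vote over their member localizations.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: Brownian (not sub-diffusive/confined) motion for
both loci and molecules, no fluorophore blinking or multiple reactivations,
no detection failures or spurious localizations, no axial dimension beyond
the width-continuity filter, Gaussian binding-site clouds rather than
polymer conformations, and spatially uniform unbound background.

## Validation problem sizes and numerical choices

The validation suite uses: 120 full-rate tracks × 4000 frames for the
interpolation error (median reproduces the mid-40s nm figure with the
mean error monotone in gap length); 6 bead fields × 12 beads for held-out
registration (~10–12 nm RMS ≤ 15 nm); 1000 traces per D for recovery
(median within 25%); 400 + 400 draws for two-component mixture recovery
(within 0.15 dex); a 240-bound-molecule transported-cluster experiment for
motion correction (median corrected/true Rg within 10%, median uncorrected
inflation > 3×; medians across loci, because with tens of molecules per
locus the per-locus Rg has ~±30% sampling scatter); and the default
experiment for classification (accuracy > 95%, strictly above the best
diffusion-threshold sweep). Closed-form anchors: overlap of two unit
Gaussians 2σ apart = 2Φ(−1); stationary-track interpolation error matches
the Rayleigh-median mixture across slot positions.

Degenerate inputs raise explicit errors rather than returning NaN: fewer
bead pairs than coefficients, rank-deficient bead layouts, < 3 or collinear
points for hulls/ellipses, single-localization TAMSD, all-identical D for
mixtures, zero duration/area for densities. Exact distance ties in linking
and colocalization are broken by id for determinism. All randomness flows
through `numpy.random.default_rng` seeds recorded in configs and manifests.

## Known limitations

* Apparent D from short traces is a relative, not absolute, mobility
  measure; the per-trace estimator remains skewed even with lag capping.
* Linear interpolation underestimates locus excursions between anchors; the
  interpolation error (~45–55 nm median under default conditions) dominates
  the resolution of motion-corrected structure, not the 20 nm localization
  precision.
* Classification inherits the footprint definition: probes bound at the far
  periphery of a locus, or unbound probes dwelling inside a footprint for a
  whole short trace, are occasionally misassigned (a few percent under
  default conditions).
* The pipeline assumes one cluster per footprint; merging/splitting locus
  topologies and gap-closing are out of scope.
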