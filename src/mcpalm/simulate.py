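"""Synthetic correlative conventional + PALM experiments with ground truth.

Generates the full input set the pipeline consumes — a single-molecule
localization table (in the distorted "top" camera channel), a conventional
cluster-channel table, a multi-field bead-pair calibration table — together
with frame-by-frame ground truth (true cluster paths, true molecule classes
and diffusion coefficients, true binding-site offsets).

The default configuration encodes the study conditions the analysis is built
for: a 10-frame shutter cycle at 20 Hz; clusters (telomere-like loci) with
log-normally distributed diffusion coefficients of median 0.002 um^2/s and
Gaussian-fitted widths of 376 +/- 221 nm; bound molecules riding on a cluster
with ~0.006 um^2/s of additional local motion (apparent D ~ 0.008 um^2/s);
unbound molecules split between a fast fraction at 0.21 um^2/s and a slow
fraction whose mobility overlaps the bound population; constant
photoactivation and geometric bleaching with mean trace length 6 PALM frames;
20 nm (single-molecule) and 30 nm (cluster) per-axis localization noise with
photometry drawn so the Thompson precision of each emitted row matches the
noise actually added.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .locio import ShutterSequence, thompson_precision
from .registration import PolynomialTransform, polynomial_terms, _exponents
from .tracking import ClusterTrack, Trace
from .correlate import BOUND
from . import mobility as _mobility

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SimulatedExperiment",
    "simulate_experiment",
    "simulate_full_rate_tracks",
    "simulate_trace_ensemble",
    "make_bead_fields",
    "default_distortion",
    "photons_for_precision",
    "match_tracks_to_truth",
    "ground_truth_compare",
    "rg_recovery",
    "Scorecard",
]


def photons_for_precision(
    precision_nm: float, width_nm: float, background: float, pixel_size_nm: float = 160.0
) -> float:
    """Photon count at which the Thompson precision equals ``precision_nm``.

    Inverts sigma^2 = (s^2 + a^2/12)/N + 8 pi s^4 b^2/(a^2 N^2) for N.
    """
    if precision_nm <= 0:
        raise ValueError("target precision must be positive")
    s2 = precision_nm**2
    A = width_nm**2 + pixel_size_nm**2 / 12.0
    C = 8.0 * np.pi * width_nm**4 * background**2 / pixel_size_nm**2
    return float((A + np.sqrt(A**2 + 4.0 * s2 * C)) / (2.0 * s2))


@dataclass
class SimulationConfig:
    """Study conditions of one synthetic correlative experiment.

    Distances in micrometres unless suffixed ``_nm``; diffusion coefficients
    in um^2/s. ``seed`` is mandatory for reproducibility and is recorded in
    the ground truth.
    """

    seed: int = 0
    n_frames: int = 4000
    fov_um: float = 20.0
    shutter: ShutterSequence = field(default_factory=ShutterSequence)
    pixel_size_nm: float = 160.0
    # clusters (conventional channel)
    n_clusters: int = 12
    cluster_d_median: float = 0.002
    cluster_d_sigma_log10: float = 0.5
    cluster_radius_mean_nm: float = 376.0
    cluster_radius_sd_nm: float = 221.0
    cluster_radius_bounds_nm: tuple[float, float] = (250.0, 4181.0)
    cluster_width_jitter_nm: float = 30.0
    cluster_noise_nm: float = 30.0
    cluster_photons_median: float = 200.0
    transport_fraction: float = 0.0
    transport_speed_um_s: float = 0.015
    # single molecules (PALM channel)
    n_bound: int = 120
    n_unbound: int = 400
    slow_unbound_fraction: float = 0.3
    bound_local_d: float = 0.006
    site_sigma_fraction: float = 0.4  # binding-site sd as fraction of cluster radius
    unbound_fast_d: float = 0.21
    unbound_slow_d: float = 0.008
    mean_trace_length: int = 6
    sm_noise_nm: float = 20.0
    sm_width_nm: float = 300.0
    background: float = 2.0
    photon_sigma_log10: float = 0.1
    # channel registration
    distortion_amplitude_px: float = 1.0
    n_bead_fields: int = 5
    beads_per_field: int = 12
    bead_noise_nm: float = 5.0

    def __post_init__(self) -> None:
        if isinstance(self.shutter, dict):
            self.shutter = ShutterSequence(**self.shutter)
        bad = [
            name
            for name, v in (
                ("n_frames", self.n_frames),
                ("fov_um", self.fov_um),
                ("n_clusters", self.n_clusters),
                ("cluster_d_median", self.cluster_d_median),
                ("mean_trace_length", self.mean_trace_length),
            )
            if v <= 0
        ]
        if not 0.0 <= self.slow_unbound_fraction <= 1.0:
            bad.append("slow_unbound_fraction")
        if not 0.0 <= self.transport_fraction <= 1.0:
            bad.append("transport_fraction")
        if bad:
            raise ValueError(f"invalid simulation config field(s): {', '.join(bad)}")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GroundTruth:
    """Frame-consistent truth behind one simulated experiment."""

    molecules: pd.DataFrame  # molecule_id, cls, cluster_id, d_true, site_x, site_y, ...
    sm_truth: pd.DataFrame  # aligned with sm_locs: molecule_id, x_true, y_true (bottom channel)
    clusters: pd.DataFrame  # cluster_id, d_true, radius_nm, transported, displacement_um
    cluster_centers: pd.DataFrame  # cluster_id, frame, x, y (true path, every frame)
    distortion: PolynomialTransform
    seed: int


@dataclass
class SimulatedExperiment:
    sm_locs: pd.DataFrame
    cluster_locs: pd.DataFrame
    bead_pairs: pd.DataFrame
    truth: GroundTruth
    config: SimulationConfig


def _brownian_increments(rng, d: float, dt_s: np.ndarray) -> np.ndarray:
    """(n, 2) Brownian steps for per-step durations dt_s (2D: var 2*D*dt/axis)."""
    sd = np.sqrt(2.0 * d * dt_s)
    return rng.normal(size=(len(dt_s), 2)) * sd[:, None]


def default_distortion(
    fov_um: float, amplitude_px: float = 1.0, pixel_size_nm: float = 160.0
) -> PolynomialTransform:
    """A fixed, smooth cubic channel distortion of given peak amplitude.

    Maps bottom-channel coordinates to the top channel: identity plus a
    gentle field-dependent warp, emulating spherical aberration between two
    emission paths.
    """
    amp_um = amplitude_px * pixel_size_nm * 1e-3
    L = fov_um
    exps = _exponents(3)
    cx = np.zeros(len(exps))
    cy = np.zeros(len(exps))
    cx[exps.index((1, 0))] = 1.0
    cy[exps.index((0, 1))] = 1.0
    # displacement terms scaled so each contributes O(amp) at the field edge
    cx[exps.index((0, 0))] = 0.30 * amp_um
    cx[exps.index((2, 0))] = 0.40 * amp_um / L**2
    cx[exps.index((1, 1))] = 0.25 * amp_um / L**2
    cx[exps.index((3, 0))] = 0.35 * amp_um / L**3
    cx[exps.index((0, 3))] = -0.20 * amp_um / L**3
    cy[exps.index((0, 0))] = -0.20 * amp_um
    cy[exps.index((0, 2))] = -0.35 * amp_um / L**2
    cy[exps.index((1, 1))] = 0.30 * amp_um / L**2
    cy[exps.index((0, 3))] = 0.30 * amp_um / L**3
    cy[exps.index((2, 1))] = -0.25 * amp_um / L**3
    return PolynomialTransform(degree=3, coef_x=cx, coef_y=cy, rms_residual_nm=0.0)


def make_bead_fields(
    distortion: PolynomialTransform,
    n_fields: int = 5,
    beads_per_field: int = 12,
    fov_um: float = 20.0,
    noise_nm: float = 5.0,
    rng=None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Multi-field fiducial calibration table for the given channel warp.

    Beads are placed uniformly over the field; both channels carry
    independent per-axis localization noise.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    rows = []
    for f in range(n_fields):
        pos = rng.uniform(0.0, fov_um, size=(beads_per_field, 2))
        tx, ty = distortion.apply(pos[:, 0], pos[:, 1])
        noise = noise_nm * 1e-3
        rows.append(
            pd.DataFrame(
                {
                    "x_top": tx + rng.normal(scale=noise, size=beads_per_field),
                    "y_top": ty + rng.normal(scale=noise, size=beads_per_field),
                    "x_bot": pos[:, 0] + rng.normal(scale=noise, size=beads_per_field),
                    "y_bot": pos[:, 1] + rng.normal(scale=noise, size=beads_per_field),
                    "field_id": f,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def _draw_photometry(rng, n, median_photons, sigma_log10, width_nm, width_jitter_nm, background):
    photons = 10 ** rng.normal(np.log10(median_photons), sigma_log10, size=n)
    widths = np.maximum(width_nm + rng.normal(scale=width_jitter_nm, size=n), 50.0)
    bg = np.full(n, background)
    return photons, widths, bg


def simulate_experiment(config: SimulationConfig | None = None, seed: int | None = None) -> SimulatedExperiment:
    """Generate one complete correlative experiment with ground truth.

    Cluster centers follow the configured motion law sampled at the frame
    rate; bound molecules are the cluster center plus a fixed Gaussian
    binding-site offset plus slow local diffusion; unbound molecules diffuse
    freely (fast/slow mixture). Molecules activate at a constant rate and
    bleach with geometric trace lengths. The cluster table holds one row per
    cluster per conventional frame; the single-molecule table only has rows
    on PALM frames and is warped into the top channel by the configured
    polynomial distortion. Identical seeds give bit-identical tables.
    """
    cfg = config or SimulationConfig()
    if seed is not None:
        cfg = SimulationConfig(**{**cfg.to_dict(), "seed": seed})
    rng = np.random.default_rng(cfg.seed)
    shutter = cfg.shutter
    dt = shutter.dt
    n_frames = cfg.n_frames
    all_frames = np.arange(1, n_frames + 1)

    # --- cluster paths ------------------------------------------------------
    n_transport = int(round(cfg.transport_fraction * cfg.n_clusters))
    cluster_rows = []
    center_frames = []
    paths = np.empty((cfg.n_clusters, n_frames, 2))
    d_clusters = 10 ** rng.normal(np.log10(cfg.cluster_d_median), cfg.cluster_d_sigma_log10, cfg.n_clusters)
    radii = np.clip(
        rng.normal(cfg.cluster_radius_mean_nm, cfg.cluster_radius_sd_nm, cfg.n_clusters),
        *cfg.cluster_radius_bounds_nm,
    )
    for c in range(cfg.n_clusters):
        start = rng.uniform(0.15 * cfg.fov_um, 0.85 * cfg.fov_um, size=2)
        steps = _brownian_increments(rng, d_clusters[c], np.full(n_frames - 1, dt))
        path = start + np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
        transported = c < n_transport
        if transported:
            theta = rng.uniform(0.0, 2.0 * np.pi)
            v = cfg.transport_speed_um_s * np.array([np.cos(theta), np.sin(theta)])
            path = path + np.outer((all_frames - 1) * dt, v)
        paths[c] = path
        disp = float(np.hypot(*(path[-1] - path[0])))
        cluster_rows.append(
            {
                "cluster_id": c,
                "d_true": d_clusters[c],
                "radius_nm": radii[c],
                "transported": transported,
                "displacement_um": disp,
            }
        )
        center_frames.append(
            pd.DataFrame({"cluster_id": c, "frame": all_frames, "x": path[:, 0], "y": path[:, 1]})
        )
    clusters_df = pd.DataFrame(cluster_rows)
    centers_df = pd.concat(center_frames, ignore_index=True)

    # --- conventional-channel localizations ---------------------------------
    conv_frames = shutter.conventional_frames(n_frames)
    rows = []
    sd_c = cfg.cluster_noise_nm * 1e-3
    for c in range(cfg.n_clusters):
        n = len(conv_frames)
        photons, widths, bg = _draw_photometry(
            rng, n, cfg.cluster_photons_median, cfg.photon_sigma_log10,
            radii[c], cfg.cluster_width_jitter_nm, cfg.background,
        )
        rows.append(
            pd.DataFrame(
                {
                    "x": paths[c, conv_frames - 1, 0] + rng.normal(scale=sd_c, size=n),
                    "y": paths[c, conv_frames - 1, 1] + rng.normal(scale=sd_c, size=n),
                    "frame": conv_frames,
                    "photons": photons,
                    "width": widths,
                    "background": bg,
                }
            )
        )
    cluster_locs = (
        pd.concat(rows, ignore_index=True).sort_values("frame", kind="stable").reset_index(drop=True)
    )

    # --- molecules -----------------------------------------------------------
    palm_frames = shutter.palm_frames(n_frames)
    n_palm = len(palm_frames)
    mol_rows = []
    sm_rows = []
    truth_rows = []
    n_slow = int(round(cfg.slow_unbound_fraction * cfg.n_unbound))
    classes = (
        ["bound"] * cfg.n_bound + ["slow_unbound"] * n_slow + ["fast_unbound"] * (cfg.n_unbound - n_slow)
    )
    sm_photons_median = photons_for_precision(
        cfg.sm_noise_nm if cfg.sm_noise_nm > 0 else 20.0,
        cfg.sm_width_nm, cfg.background, cfg.pixel_size_nm,
    )
    for m, cls in enumerate(classes):
        start_idx = int(rng.integers(0, n_palm))
        length = int(rng.geometric(1.0 / cfg.mean_trace_length))
        idx = np.arange(start_idx, min(start_idx + length, n_palm))
        frames = palm_frames[idx]
        n = len(frames)
        host = -1
        site = (np.nan, np.nan)
        if cls == "bound":
            host = int(rng.integers(0, cfg.n_clusters))
            # binding sites lie within the locus: Gaussian with sd proportional
            # to the cluster radius, truncated at the radius itself
            r_um = radii[host] * 1e-3
            while True:
                site = rng.normal(scale=cfg.site_sigma_fraction * r_um, size=2)
                if np.hypot(*site) <= r_um:
                    break
            d_local = cfg.bound_local_d
            base = paths[host, frames - 1] + site
            walk_dt = np.diff(frames) * dt
            walk = np.vstack([[0.0, 0.0], np.cumsum(_brownian_increments(rng, d_local, walk_dt), axis=0)]) if n > 1 else np.zeros((n, 2))
            true_xy = base + walk
            d_app = clusters_df.loc[host, "d_true"] + d_local
        else:
            d_free = cfg.unbound_slow_d if cls == "slow_unbound" else cfg.unbound_fast_d
            start = rng.uniform(0.0, cfg.fov_um, size=2)
            walk_dt = np.diff(frames) * dt
            walk = np.vstack([[0.0, 0.0], np.cumsum(_brownian_increments(rng, d_free, walk_dt), axis=0)]) if n > 1 else np.zeros((n, 2))
            true_xy = start + walk
            d_app = d_free
        mol_rows.append(
            {
                "molecule_id": m,
                "cls": cls,
                "cluster_id": host,
                "d_true": d_app,
                "site_x": site[0],
                "site_y": site[1],
                "first_frame": int(frames[0]) if n else -1,
                "n_emitted": n,
            }
        )
        if n == 0:
            continue
        photons, widths, bg = _draw_photometry(
            rng, n, sm_photons_median, cfg.photon_sigma_log10,
            cfg.sm_width_nm, 15.0, cfg.background,
        )
        prec_nm = thompson_precision(photons, widths, bg, cfg.pixel_size_nm)
        if cfg.sm_noise_nm > 0:
            noisy = true_xy + rng.normal(size=(n, 2)) * (prec_nm * 1e-3)[:, None]
        else:  # idealized noise-free acquisition (photometry still emitted)
            noisy = true_xy.copy()
        sm_rows.append(
            pd.DataFrame(
                {
                    "x": noisy[:, 0],
                    "y": noisy[:, 1],
                    "frame": frames,
                    "photons": photons,
                    "width": widths,
                    "background": bg,
                }
            )
        )
        truth_rows.append(
            pd.DataFrame(
                {"molecule_id": m, "x_true": true_xy[:, 0], "y_true": true_xy[:, 1], "frame": frames}
            )
        )
    sm_bottom = pd.concat(sm_rows, ignore_index=True)
    sm_truth = pd.concat(truth_rows, ignore_index=True)
    order = np.argsort(sm_bottom["frame"].to_numpy(), kind="stable")
    sm_bottom = sm_bottom.iloc[order].reset_index(drop=True)
    sm_truth = sm_truth.iloc[order].reset_index(drop=True)

    # --- channel warp + bead calibration -------------------------------------
    distortion = default_distortion(cfg.fov_um, cfg.distortion_amplitude_px, cfg.pixel_size_nm)
    sm_locs = sm_bottom.copy()
    tx, ty = distortion.apply(sm_bottom["x"].to_numpy(), sm_bottom["y"].to_numpy())
    sm_locs["x"] = tx
    sm_locs["y"] = ty
    sm_locs.attrs["channel"] = "top"
    bead_pairs = make_bead_fields(
        distortion, cfg.n_bead_fields, cfg.beads_per_field, cfg.fov_um, cfg.bead_noise_nm, rng=rng
    )

    truth = GroundTruth(
        molecules=pd.DataFrame(mol_rows),
        sm_truth=sm_truth,
        clusters=clusters_df,
        cluster_centers=centers_df,
        distortion=distortion,
        seed=cfg.seed,
    )
    return SimulatedExperiment(
        sm_locs=sm_locs, cluster_locs=cluster_locs, bead_pairs=bead_pairs, truth=truth, config=cfg
    )


def simulate_full_rate_tracks(
    n_tracks: int = 120,
    n_frames: int = 4000,
    d_median: float = 0.002,
    d_sigma_log10: float = 0.5,
    noise_nm: float = 30.0,
    frame_rate: float = 20.0,
    width_nm: float = 376.0,
    seed: int = 0,
) -> list[ClusterTrack]:
    """Cluster tracks localized in *every* frame, for interpolation-error work.

    Emulates a calibration acquisition in which loci are conventionally
    imaged at the full frame rate (no interleaving), so interpolated and
    observed positions can be compared at intermediate frames.
    """
    rng = np.random.default_rng(seed)
    dt = 1.0 / frame_rate
    tracks = []
    frames = np.arange(1, n_frames + 1, dtype=np.int64)
    for t in range(n_tracks):
        d = 10 ** rng.normal(np.log10(d_median), d_sigma_log10)
        steps = _brownian_increments(rng, d, np.full(n_frames - 1, dt))
        path = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
        noisy = path + rng.normal(size=(n_frames, 2)) * (noise_nm * 1e-3)
        tracks.append(
            ClusterTrack(
                id=t,
                frames=frames.copy(),
                x=noisy[:, 0],
                y=noisy[:, 1],
                width_nm=np.full(n_frames, width_nm),
                precision_nm=np.full(n_frames, noise_nm),
                frame_rate=frame_rate,
            )
        )
    return tracks


def simulate_trace_ensemble(
    n_traces: int,
    d_um2_s: float,
    mean_length: int = 6,
    min_length: int = 4,
    noise_nm: float = 20.0,
    frame_rate: float = 20.0,
    seed: int = 0,
) -> list[Trace]:
    """Free-diffusion traces on a uniform frame grid, with localization noise.

    Trace lengths are geometric with the generator's mean, conditioned on the
    analysis cutoff ``min_length`` (shorter traces would be discarded by the
    linker anyway).
    """
    rng = np.random.default_rng(seed)
    dt = 1.0 / frame_rate
    traces = []
    while len(traces) < n_traces:
        length = int(rng.geometric(1.0 / mean_length))
        if length < min_length:
            continue
        steps = _brownian_increments(rng, d_um2_s, np.full(length - 1, dt))
        path = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
        noisy = path + rng.normal(size=(length, 2)) * (noise_nm * 1e-3)
        locs = pd.DataFrame(
            {"x": noisy[:, 0], "y": noisy[:, 1], "frame": np.arange(1, length + 1)}
        )
        traces.append(Trace(id=len(traces), locs=locs))
    return traces


def match_tracks_to_truth(tracks: list[ClusterTrack], truth: GroundTruth) -> dict[int, int]:
    """Map fitted track ids to true cluster ids by mean trajectory distance."""
    centers = truth.cluster_centers
    mapping = {}
    for tr in tracks:
        best, best_d = -1, np.inf
        for c, sub in centers.groupby("cluster_id"):
            path = sub.set_index("frame")
            common = path.loc[tr.frames]
            d = float(np.hypot(tr.x - common["x"].to_numpy(), tr.y - common["y"].to_numpy()).mean())
            if d < best_d:
                best, best_d = int(c), d
        mapping[tr.id] = best
    return mapping


@dataclass
class Scorecard:
    """Pipeline-vs-ground-truth comparison on one simulated experiment."""

    n_traces: int
    accuracy: float
    confusion: dict
    best_threshold_accuracy: float
    best_threshold_um2_s: float
    per_trace: pd.DataFrame  # trace_id, molecule_id, true_bound, pred_bound, d_fit, d_true
    d_bias_median: float


def _majority(values: np.ndarray) -> int:
    vals, counts = np.unique(values, return_counts=True)
    return int(vals[np.argmax(counts)])


def ground_truth_compare(
    traces: list[Trace],
    classes: pd.DataFrame,
    truth: GroundTruth,
    frame_rate: float,
) -> Scorecard:
    """Score classification and mobility recovery against the ground truth.

    Each linked trace is attributed to the true molecule contributing the
    majority of its localizations (unambiguous at the generator's sparse
    activation rates). Classification is scored as binary bound-vs-not
    (partially bound counts as not bound, matching the searching/freely
    diffusing interpretation). The best achievable single
    diffusion-coefficient threshold is found by sweeping all midpoints of the
    sorted per-trace apparent D values, in both orientations.
    """
    label_by_id = classes.set_index("trace_id")["label"]
    mol = truth.molecules.set_index("molecule_id")
    rows = []
    for tr in traces:
        mid = _majority(truth.sm_truth.loc[tr.locs.index, "molecule_id"].to_numpy())
        fit = _mobility.fit_trace(tr, frame_rate)
        rows.append(
            {
                "trace_id": tr.id,
                "molecule_id": mid,
                "true_bound": mol.loc[mid, "cls"] == "bound",
                "pred_bound": label_by_id.loc[tr.id] == BOUND,
                "d_fit": fit.D_um2_s,
                "d_true": mol.loc[mid, "d_true"],
            }
        )
    per = pd.DataFrame(rows)
    if len(per) == 0:
        raise ValueError("no traces to score")
    acc = float((per["true_bound"] == per["pred_bound"]).mean())
    confusion = {
        "tp": int((per["true_bound"] & per["pred_bound"]).sum()),
        "fp": int((~per["true_bound"] & per["pred_bound"]).sum()),
        "fn": int((per["true_bound"] & ~per["pred_bound"]).sum()),
        "tn": int((~per["true_bound"] & ~per["pred_bound"]).sum()),
    }
    ds = per["d_fit"].to_numpy()
    yt = per["true_bound"].to_numpy()
    cand = np.unique(ds)
    thresholds = np.concatenate([[cand[0] - 1.0], (cand[:-1] + cand[1:]) / 2.0, [cand[-1] + 1.0]])
    best_acc, best_thr = 0.0, float("nan")
    for thr in thresholds:
        for pred in (ds <= thr, ds > thr):
            a = float((pred == yt).mean())
            if a > best_acc:
                best_acc, best_thr = a, float(thr)
    pos = per[(per["d_fit"] > 0) & (per["d_true"] > 0)]
    d_bias = float(np.median(pos["d_fit"] / pos["d_true"])) if len(pos) else float("nan")
    return Scorecard(
        n_traces=len(per),
        accuracy=acc,
        confusion=confusion,
        best_threshold_accuracy=best_acc,
        best_threshold_um2_s=best_thr,
        per_trace=per,
        d_bias_median=d_bias,
    )


def rg_recovery(
    corrected_clusters: list,
    registered_sm: pd.DataFrame,
    tracks: list[ClusterTrack],
    truth: GroundTruth,
    min_points: int = 10,
) -> pd.DataFrame:
    """Radius-of-gyration recovery before vs after motion correction.

    For each corrected cluster, compares the Rg of the corrected points with
    (a) the ground-truth Rg of the same localizations' true positions
    relative to the true cluster path, and (b) the Rg of the raw
    (uncorrected) registered positions. Requires motion-corrected tables that
    carry the source row index (``loc_index``).
    """
    from .structure import radius_of_gyration

    track_to_true = match_tracks_to_truth(tracks, truth)
    centers = truth.cluster_centers
    rows = []
    for cc in corrected_clusters:
        if cc.n_localizations < min_points:
            continue
        true_cid = track_to_true[cc.cluster_id]
        idx = cc.locs["loc_index"].to_numpy()
        frames = cc.locs["frame"].to_numpy()
        t = truth.sm_truth.loc[idx]
        path = centers[centers["cluster_id"] == true_cid].set_index("frame")
        px = path.loc[frames, "x"].to_numpy()
        py = path.loc[frames, "y"].to_numpy()
        rel_true = np.column_stack([t["x_true"].to_numpy() - px, t["y_true"].to_numpy() - py])
        raw = registered_sm.loc[idx, ["x", "y"]].to_numpy()
        rows.append(
            {
                "cluster_id": cc.cluster_id,
                "true_cluster_id": true_cid,
                "n": cc.n_localizations,
                "rg_corrected_nm": radius_of_gyration(cc.points) * 1e3,
                "rg_true_nm": radius_of_gyration(rel_true) * 1e3,
                "rg_uncorrected_nm": radius_of_gyration(raw) * 1e3,
                "displacement_um": float(
                    truth.clusters.set_index("cluster_id").loc[true_cid, "displacement_um"]
                ),
            }
        )
    return pd.DataFrame(rows)
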