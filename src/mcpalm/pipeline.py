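"""End-to-end orchestration: register -> link -> interpolate -> colocalize ->
classify -> motion-correct -> structure -> mobility.

:func:`run_pipeline` consumes localization tables (plus a bead calibration)
and writes every intermediate and final artifact as CSV/JSON together with a
run manifest (config hash, seed, input digests, per-stage counts) so any
downstream figure can be regenerated.
"""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .locio import ExperimentConfig, add_precision, read_localizations, write_localizations
from .registration import apply_transform, fit_transform, holdout_registration_error, read_bead_pairs
from .tracking import interpolate_track, link_clusters, link_single_molecules, traces_to_frame
from .correlate import BOUND, classify_traces, colocalize, motion_correct
from .structure import metrics_table
from .mobility import diffusion_table, export_displacements, fit_logd_mixture, relative_mobility

__all__ = ["PipelineResult", "run_pipeline", "run_pipeline_frames", "write_manifest"]


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


@dataclass
class PipelineResult:
    """In-memory handles to every pipeline stage output."""

    config: ExperimentConfig
    transform: object
    sm_registered: pd.DataFrame
    traces: list
    tracks: list
    assignments: pd.DataFrame
    classes: pd.DataFrame
    corrected: list
    metrics: pd.DataFrame
    diffusion: pd.DataFrame
    relative: pd.DataFrame
    counts: dict = field(default_factory=dict)


def run_pipeline_frames(
    sm_locs: pd.DataFrame,
    cluster_locs: pd.DataFrame,
    bead_pairs: pd.DataFrame | None,
    config: ExperimentConfig | None = None,
) -> PipelineResult:
    """Run the full analysis on in-memory tables.

    ``sm_locs``/``cluster_locs`` are canonical localization frames (see
    :mod:`mcpalm.locio`); ``bead_pairs`` may be None when the channels are
    already co-registered.
    """
    cfg = config or ExperimentConfig()
    shutter = cfg.shutter

    if "precision" not in sm_locs.columns:
        sm_locs = add_precision(sm_locs, cfg.pixel_size_nm)
    if "precision" not in cluster_locs.columns:
        cluster_locs = add_precision(cluster_locs, cfg.pixel_size_nm)

    if bead_pairs is not None:
        transform = fit_transform(bead_pairs, degree=3)
        sm_reg = apply_transform(transform, sm_locs)
    else:
        transform = None
        sm_reg = sm_locs.copy()
        sm_reg.attrs["channel"] = "conventional"

    traces = link_single_molecules(
        sm_reg, max_dist=cfg.sm_link_radius_um, min_length=cfg.sm_min_length, shutter=shutter
    )
    tracks = link_clusters(
        cluster_locs,
        max_dist=cfg.cluster_link_radius_um,
        min_length=cfg.cluster_min_length,
        width_tolerance_nm=cfg.width_tolerance_nm,
        shutter=shutter,
    )
    for tr in tracks:
        interpolate_track(tr)

    assignments = colocalize(sm_reg, tracks)
    classes = classify_traces(traces, assignments, tracks=tracks, min_defined=cfg.sm_min_length)

    by_id = {tr.id: tr for tr in traces}
    bound_ok = classes[(classes["label"] == BOUND) & (~classes["excluded_short"])]
    corrected = []
    relative_rows = []
    for track in tracks:
        ids = bound_ok.loc[bound_ok["cluster_id"] == track.id, "trace_id"].tolist()
        bound = [by_id[i] for i in ids]
        corrected.append(motion_correct(track, bound))
        if bound:
            try:
                relative_rows.append(relative_mobility(track, bound, shutter.frame_rate, cfg.max_fit_lags))
            except ValueError:
                pass
    metrics = metrics_table(corrected)
    diffusion = diffusion_table(traces, shutter.frame_rate, max_lags=cfg.max_fit_lags)
    diffusion = diffusion.merge(classes[["trace_id", "label", "cluster_id"]], on="trace_id")

    counts = {
        "sm_localizations": int(len(sm_locs)),
        "cluster_localizations": int(len(cluster_locs)),
        "traces": len(traces),
        "cluster_tracks": len(tracks),
        "traces_bound": int((classes["label"] == BOUND).sum()),
        "traces_partially_bound": int((classes["label"] == "partially_bound").sum()),
        "traces_unbound": int((classes["label"] == "unbound").sum()),
        "traces_excluded_short": int(classes["excluded_short"].sum()),
        "clusters_with_metrics": int(len(metrics)),
    }
    return PipelineResult(
        config=cfg,
        transform=transform,
        sm_registered=sm_reg,
        traces=traces,
        tracks=tracks,
        assignments=assignments,
        classes=classes,
        corrected=corrected,
        metrics=metrics,
        diffusion=diffusion,
        relative=pd.DataFrame(relative_rows),
        counts=counts,
    )


def write_manifest(outdir: Path, cfg: ExperimentConfig, counts: dict, inputs: dict[str, Path]) -> dict:
    manifest = {
        "mcpalm_version": __version__,
        "python": sys.version.split()[0],
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "inputs": {k: {"path": str(p), "sha256_16": _digest(Path(p))} for k, p in inputs.items()},
        "counts": counts,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def run_pipeline(
    sm_path,
    cluster_path,
    outdir,
    bead_path=None,
    config: ExperimentConfig | None = None,
    units: str = "um",
) -> PipelineResult:
    """File-to-file pipeline run; writes all stage outputs plus a manifest."""
    cfg = config or ExperimentConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    inputs = {"sm": Path(sm_path), "cluster": Path(cluster_path)}
    if bead_path is not None:
        inputs["beads"] = Path(bead_path)
    for p in inputs.values():
        if not p.exists():
            raise FileNotFoundError(p)

    sm = read_localizations(sm_path, units=units, pixel_size_nm=cfg.pixel_size_nm)
    clus = read_localizations(cluster_path, units=units, pixel_size_nm=cfg.pixel_size_nm)
    beads = read_bead_pairs(bead_path) if bead_path is not None else None

    res = run_pipeline_frames(sm, clus, beads, cfg)

    write_localizations(res.sm_registered, outdir / "sm_registered.csv")
    traces_to_frame(res.traces).to_csv(outdir / "traces.csv", index=False, float_format="%.9g")
    track_rows = []
    for t in res.tracks:
        track_rows.append(
            pd.DataFrame(
                {"track_id": t.id, "frame": t.frames, "x": t.x, "y": t.y, "width": t.width_nm,
                 "precision": t.precision_nm}
            )
        )
    (pd.concat(track_rows, ignore_index=True) if track_rows else pd.DataFrame()).to_csv(
        outdir / "cluster_tracks.csv", index=False, float_format="%.9g"
    )
    res.classes.to_csv(outdir / "trace_classes.csv", index=False)
    corr_rows = [cc.locs.assign(cluster_id=cc.cluster_id) for cc in res.corrected if cc.n_localizations]
    (pd.concat(corr_rows, ignore_index=True) if corr_rows else pd.DataFrame()).to_csv(
        outdir / "corrected_localizations.csv", index=False, float_format="%.9g"
    )
    res.metrics.to_csv(outdir / "cluster_metrics.csv", index=False, float_format="%.9g")
    res.diffusion.to_csv(outdir / "trace_diffusion.csv", index=False, float_format="%.9g")
    res.relative.to_csv(outdir / "relative_mobility.csv", index=False, float_format="%.9g")
    export_displacements(res.traces, cfg.shutter.frame_rate, outdir / "displacements.csv")
    if res.transform is not None:
        res.transform.to_json(outdir / "channel_transform.json")
        if beads is not None and "field_id" in beads.columns and beads["field_id"].nunique() >= 2:
            with open(outdir / "registration_error.json", "w") as fh:
                json.dump(holdout_registration_error(beads), fh, indent=1)
    valid = res.diffusion.loc[res.diffusion["valid"], "D_um2_s"]
    if len(valid) >= 10 and valid.nunique() > 1:
        mix = fit_logd_mixture(valid, k_candidates=cfg.gmm_components, seed=cfg.seed)
        with open(outdir / "mixture_model.json", "w") as fh:
            json.dump(mix.as_dict(), fh, indent=1)
    write_manifest(outdir, cfg, res.counts, inputs)
    return res
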