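"""Trajectory linking and cluster-track interpolation.

Single-molecule localizations are linked into traces when successive
localizations on the PALM-frame grid fall within a maximum jump distance
(default 0.48 um) with no dark frame allowed; conventional-channel cluster
localizations are linked across shutter cycles with a larger radius (default
0.68 um) plus a PSF-width continuity filter (default 200 nm) that rejects
axial excursions. Cluster trajectories are linearly interpolated across the
PALM frames of each cycle so that every single-molecule localization can be
referred to the instantaneous cluster position.

Linking is deterministic: per frame-pair, candidate links are resolved
globally by ascending distance (nearest-neighbour assignment), with ties
broken by trace id then localization order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .locio import ShutterSequence

__all__ = [
    "Trace",
    "ClusterTrack",
    "link_single_molecules",
    "link_clusters",
    "interpolate_track",
    "interpolation_error_experiment",
    "InterpolationErrorResult",
    "traces_to_frame",
]


@dataclass
class Trace:
    """Frame-consecutive chain of localizations from one emitter."""

    id: int
    locs: pd.DataFrame  # rows of the source table, original index preserved
    channel: str = "single_molecule"

    def __len__(self) -> int:
        return len(self.locs)

    @property
    def frames(self) -> np.ndarray:
        return self.locs["frame"].to_numpy(dtype=np.int64)

    @property
    def xy(self) -> np.ndarray:
        return self.locs[["x", "y"]].to_numpy(dtype=float)


@dataclass
class ClusterTrack:
    """Conventional-channel cluster trajectory with interpolated centers.

    ``frames``/``x``/``y``/``width_nm``/``precision_nm`` hold the conventional
    localizations (one per shutter cycle). After :func:`interpolate_track`,
    ``frames_full`` spans every camera frame between the first and last
    conventional localization, with linearly interpolated centers and a
    piecewise-constant radius taken from the last conventional localization
    before each frame.
    """

    id: int
    frames: np.ndarray
    x: np.ndarray
    y: np.ndarray
    width_nm: np.ndarray
    precision_nm: np.ndarray
    frame_rate: float = 20.0
    frames_full: np.ndarray | None = field(default=None, repr=False)
    cx: np.ndarray | None = field(default=None, repr=False)
    cy: np.ndarray | None = field(default=None, repr=False)
    radius_full_nm: np.ndarray | None = field(default=None, repr=False)
    precision_full_nm: np.ndarray | None = field(default=None, repr=False)

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def interpolated(self) -> bool:
        return self.frames_full is not None

    @property
    def duration_s(self) -> float:
        """Observed time in the field of view (s)."""
        return (self.frames[-1] - self.frames[0]) / self.frame_rate

    def defined_at(self, frames) -> np.ndarray:
        frames = np.asarray(frames)
        return (frames >= self.frames[0]) & (frames <= self.frames[-1])

    def center_at(self, frames) -> tuple[np.ndarray, np.ndarray]:
        """Interpolated center (um) at arbitrary frames inside the track span."""
        if not self.interpolated:
            raise ValueError("track not interpolated; call interpolate_track first")
        frames = np.asarray(frames)
        if not np.all(self.defined_at(frames)):
            raise ValueError("center requested outside the track's observation window")
        idx = np.asarray(frames) - self.frames_full[0]
        return self.cx[idx], self.cy[idx]

    def radius_at(self, frames) -> np.ndarray:
        if not self.interpolated:
            raise ValueError("track not interpolated; call interpolate_track first")
        idx = np.asarray(frames) - self.frames_full[0]
        return self.radius_full_nm[idx]

    def precision_at(self, frames) -> np.ndarray:
        if not self.interpolated:
            raise ValueError("track not interpolated; call interpolate_track first")
        idx = np.asarray(frames) - self.frames_full[0]
        return self.precision_full_nm[idx]


def _greedy_link(points_by_step: list[pd.DataFrame], max_dist: float, compatible) -> list[list[int]]:
    """Chain rows across successive grid steps by global nearest-neighbour.

    ``points_by_step`` holds the rows observed at each occupied grid step (a
    step is one PALM-grid position or one shutter cycle). Returns chains of
    absolute row labels. ``compatible(prev_row, new_rows)`` returns a boolean
    mask of admissible continuations beyond the distance rule.
    """
    open_traces: list[dict] = []  # {'rows': [...], 'step': int, 'x':, 'y':, 'row': Series}
    finished: list[list[int]] = []
    for step, pts in enumerate(points_by_step):
        if pts is None or len(pts) == 0:
            # close traces that cannot continue (gap)
            still = []
            for tr in open_traces:
                if tr["step"] == step - 1:
                    finished.append(tr["rows"])
                else:
                    still.append(tr)
            open_traces = still
            continue
        px = pts["x"].to_numpy()
        py = pts["y"].to_numpy()
        cand = [tr for tr in open_traces if tr["step"] == step - 1]
        links: list[tuple[float, int, int]] = []
        for ti, tr in enumerate(cand):
            d = np.hypot(px - tr["x"], py - tr["y"])
            ok = (d <= max_dist) & compatible(tr["row"], pts)
            for pi in np.flatnonzero(ok):
                links.append((float(d[pi]), ti, int(pi)))
        links.sort(key=lambda t: (t[0], t[1], t[2]))
        used_tr: set[int] = set()
        used_pt: set[int] = set()
        for d, ti, pi in links:
            if ti in used_tr or pi in used_pt:
                continue
            used_tr.add(ti)
            used_pt.add(pi)
            tr = cand[ti]
            tr["rows"].append(pts.index[pi])
            tr["step"] = step
            tr["x"] = px[pi]
            tr["y"] = py[pi]
            tr["row"] = pts.iloc[pi]
        # close unextended traces, open new ones
        still = []
        for tr in open_traces:
            if tr["step"] <= step - 1:
                finished.append(tr["rows"])
            else:
                still.append(tr)
        open_traces = still
        for pi in range(len(pts)):
            if pi not in used_pt:
                open_traces.append(
                    {"rows": [pts.index[pi]], "step": step, "x": px[pi], "y": py[pi], "row": pts.iloc[pi]}
                )
    finished.extend(tr["rows"] for tr in open_traces)
    return finished


def _group_by_grid(locs: pd.DataFrame, grid: np.ndarray) -> list[pd.DataFrame]:
    """Rows bucketed by 0-based grid index, empty steps as None."""
    if len(locs) == 0:
        return []
    n = int(grid.max()) + 1
    buckets: list = [None] * n
    order = np.argsort(grid, kind="stable")
    df = locs.iloc[order]
    g = grid[order]
    for value, sub in df.groupby(g, sort=True):
        buckets[int(value)] = sub
    return buckets


def link_single_molecules(
    locs: pd.DataFrame,
    max_dist: float = 0.48,
    min_length: int = 4,
    shutter: ShutterSequence | None = None,
) -> list[Trace]:
    """Link single-molecule localizations into traces.

    Localizations within ``max_dist`` (um) of each other in consecutive
    PALM-grid frames are chained; no dark frame is allowed, and chains
    shorter than ``min_length`` are discarded. Each localization belongs to
    at most one trace.
    """
    shutter = shutter or ShutterSequence()
    if len(locs) == 0:
        return []
    grid = shutter.palm_index(locs["frame"].to_numpy())
    chains = _greedy_link(_group_by_grid(locs, grid), max_dist, lambda row, pts: np.ones(len(pts), bool))
    traces = []
    for rows in chains:
        if len(rows) >= min_length:
            traces.append(Trace(id=len(traces), locs=locs.loc[rows], channel="single_molecule"))
    return traces


def link_clusters(
    locs: pd.DataFrame,
    max_dist: float = 0.68,
    min_length: int = 5,
    width_tolerance_nm: float = 200.0,
    shutter: ShutterSequence | None = None,
) -> list[ClusterTrack]:
    """Link conventional-channel cluster localizations into tracks.

    Successive members (one per shutter cycle) must lie within ``max_dist``
    (um) and have fitted widths within ``width_tolerance_nm`` of each other;
    the width-continuity rule rejects clusters drifting out of focus.
    """
    shutter = shutter or ShutterSequence()
    if len(locs) == 0:
        return []
    grid = shutter.conventional_index(locs["frame"].to_numpy())

    def width_ok(row, pts):
        return np.abs(pts["width"].to_numpy() - row["width"]) <= width_tolerance_nm

    chains = _greedy_link(_group_by_grid(locs, grid), max_dist, width_ok)
    tracks = []
    for rows in chains:
        if len(rows) < min_length:
            continue
        sub = locs.loc[rows]
        prec = (
            sub["precision"].to_numpy(dtype=float)
            if "precision" in sub.columns
            else np.full(len(sub), np.nan)
        )
        tracks.append(
            ClusterTrack(
                id=len(tracks),
                frames=sub["frame"].to_numpy(dtype=np.int64),
                x=sub["x"].to_numpy(dtype=float),
                y=sub["y"].to_numpy(dtype=float),
                width_nm=sub["width"].to_numpy(dtype=float),
                precision_nm=prec,
                frame_rate=shutter.frame_rate,
            )
        )
    return tracks


def interpolate_track(track: ClusterTrack) -> ClusterTrack:
    """Fill per-frame centers between the track's conventional localizations.

    Centers are linear in frame number between consecutive conventional
    localizations; radius (the fitted width) and precision are held from the
    last conventional localization before each frame. The interpolated
    trajectory passes exactly through every conventional localization.
    """
    if len(track) < 2:
        raise ValueError("interpolation needs at least two conventional localizations")
    f0, f1 = int(track.frames[0]), int(track.frames[-1])
    frames_full = np.arange(f0, f1 + 1, dtype=np.int64)
    track.frames_full = frames_full
    track.cx = np.interp(frames_full, track.frames, track.x)
    track.cy = np.interp(frames_full, track.frames, track.y)
    last = np.searchsorted(track.frames, frames_full, side="right") - 1
    track.radius_full_nm = track.width_nm[last]
    track.precision_full_nm = track.precision_nm[last]
    return track


@dataclass
class InterpolationErrorResult:
    """Distances between interpolated and observed positions at skipped frames."""

    errors_nm: np.ndarray
    median_nm: float
    gap_lengths: np.ndarray
    mean_error_by_gap_nm: np.ndarray
    n_tracks: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"gap_frames": self.gap_lengths, "mean_error_nm": self.mean_error_by_gap_nm})


def _interp_errors_for_gap(x: np.ndarray, y: np.ndarray, gap: int) -> np.ndarray:
    """Interpolate between every ``gap``-th sample; return errors (same units)."""
    n = len(x)
    n_seg = (n - 1) // gap
    if n_seg < 1:
        return np.empty(0)
    w = np.arange(1, gap) / gap  # fractional positions within a segment
    x0 = x[: n_seg * gap : gap, None]
    x1 = x[gap : n_seg * gap + 1 : gap, None]
    y0 = y[: n_seg * gap : gap, None]
    y1 = y[gap : n_seg * gap + 1 : gap, None]
    xin = x[: n_seg * gap + 1][:-1].reshape(n_seg, gap)[:, 1:]
    yin = y[: n_seg * gap + 1][:-1].reshape(n_seg, gap)[:, 1:]
    ix = x0 + w * (x1 - x0)
    iy = y0 + w * (y1 - y0)
    return np.hypot(ix - xin, iy - yin).ravel()


def interpolation_error_experiment(
    tracks: list[ClusterTrack],
    cycle_length: int = 10,
    max_gap: int = 20,
) -> InterpolationErrorResult:
    """Estimate the error of linear interpolation across a shutter cycle.

    ``tracks`` must be localized at the full camera frame rate (a dedicated
    calibration acquisition with the conventional channel in every frame).
    Positions at every ``cycle_length``-th frame are kept as interpolation
    anchors; the Euclidean distance between the interpolated and the observed
    position at each intermediate frame is pooled over all tracks. The mean
    error is also reported as a function of gap length (2..``max_gap``
    frames) to show how the error grows with sparser anchoring.
    """
    errors = []
    used = 0
    per_gap: dict[int, list[np.ndarray]] = {g: [] for g in range(2, max_gap + 1)}
    for tr in tracks:
        if len(tr) <= cycle_length:
            import warnings

            warnings.warn(f"track {tr.id} shorter than one cycle; skipped", stacklevel=2)
            continue
        if np.any(np.diff(tr.frames) != 1):
            raise ValueError("interpolation-error experiment requires full-rate tracks")
        used += 1
        errors.append(_interp_errors_for_gap(tr.x, tr.y, cycle_length))
        for g in per_gap:
            if len(tr) > g:
                per_gap[g].append(_interp_errors_for_gap(tr.x, tr.y, g))
    if not errors:
        raise ValueError("no track long enough for the interpolation-error experiment")
    errors_um = np.concatenate(errors)
    gaps = np.array(sorted(per_gap))
    means = np.array(
        [np.concatenate(per_gap[g]).mean() * 1e3 if per_gap[g] else np.nan for g in gaps]
    )
    return InterpolationErrorResult(
        errors_nm=errors_um * 1e3,
        median_nm=float(np.median(errors_um) * 1e3),
        gap_lengths=gaps,
        mean_error_by_gap_nm=means,
        n_tracks=used,
    )


def traces_to_frame(traces: list[Trace]) -> pd.DataFrame:
    """Flatten traces to a long table (trace_id, frame, x, y, ...)."""
    if not traces:
        return pd.DataFrame(columns=["trace_id", "frame", "x", "y"])
    parts = []
    for tr in traces:
        sub = tr.locs.copy()
        sub.insert(0, "trace_id", tr.id)
        parts.append(sub)
    return pd.concat(parts, ignore_index=True)
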