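"""Spatio-temporal correlation of single molecules with moving clusters.

The central idea of motion-correction PALM: a single-molecule localization is
co-localized with a cluster when its distance to the interpolated cluster
center is smaller than the cluster radius plus both localization precisions.
Traces are then classified bound / partially bound / unbound according to
whether all, some, or none of their localizations co-localize, and the
interpolated cluster trajectory is subtracted from bound localizations to
recover the time-averaged locus structure in the cluster's co-moving frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tracking import ClusterTrack, Trace

__all__ = [
    "BOUND",
    "PARTIALLY_BOUND",
    "UNBOUND",
    "colocalize",
    "classify_traces",
    "motion_correct",
    "CorrectedCluster",
]

BOUND = "bound"
PARTIALLY_BOUND = "partially_bound"
UNBOUND = "unbound"


def colocalize(sm_locs: pd.DataFrame, tracks: list[ClusterTrack]) -> pd.DataFrame:
    """Assign each single-molecule localization to the nearest cluster, or none.

    A localization at frame ``f`` co-localizes with track ``c`` when
    ``dist < radius_c(f) + sigma_c(f) + sigma_loc`` with all terms evaluated
    at the interpolated cluster position. Among co-localizing tracks the
    nearest wins; exact distance ties go to the lower track id.

    ``sm_locs`` must already be registered into the conventional channel
    (``attrs["channel"] == "conventional"``, set by
    :func:`mcpalm.registration.apply_transform`) and carry a ``precision``
    column in nm.

    Returns a DataFrame aligned with ``sm_locs`` (same index) with columns
    ``cluster_id`` (-1 for unassigned) and ``distance_um``.
    """
    if sm_locs.attrs.get("channel") != "conventional":
        raise ValueError(
            "single-molecule localizations are not registered into the conventional "
            "channel; apply the channel transform first"
        )
    if "precision" not in sm_locs.columns:
        raise ValueError("sm_locs needs a 'precision' column (nm); see locio.add_precision")
    n = len(sm_locs)
    best_d = np.full(n, np.inf)
    best_id = np.full(n, -1, dtype=np.int64)
    frames = sm_locs["frame"].to_numpy(dtype=np.int64)
    x = sm_locs["x"].to_numpy(dtype=float)
    y = sm_locs["y"].to_numpy(dtype=float)
    prec_um = sm_locs["precision"].to_numpy(dtype=float) * 1e-3
    for tr in sorted(tracks, key=lambda t: t.id):
        if not tr.interpolated:
            raise ValueError(f"cluster track {tr.id} is not interpolated")
        inside = tr.defined_at(frames)
        if not inside.any():
            continue
        idx = np.flatnonzero(inside)
        cx, cy = tr.center_at(frames[idx])
        d = np.hypot(x[idx] - cx, y[idx] - cy)
        thresh = (tr.radius_at(frames[idx]) + tr.precision_at(frames[idx])) * 1e-3 + prec_um[idx]
        hit = (d < thresh) & (d < best_d[idx])  # strict: ties keep the lower id
        upd = idx[hit]
        best_d[upd] = d[hit]
        best_id[upd] = tr.id
    return pd.DataFrame(
        {"cluster_id": best_id, "distance_um": np.where(np.isfinite(best_d), best_d, np.nan)},
        index=sm_locs.index,
    )


def classify_traces(
    traces: list[Trace],
    assignments: pd.DataFrame,
    tracks: list[ClusterTrack] | None = None,
    min_defined: int = 4,
) -> pd.DataFrame:
    """Three-way bound / partially bound / unbound classification of traces.

    A trace is *bound* when every localization co-localizes with the same
    cluster, *unbound* when none does, and *partially bound* otherwise — a
    molecule that enters and exits a locus is interpreted as searching or
    freely diffusing, not bound. Traces whose co-localized members touch more
    than one cluster are classified partially bound and flagged
    (``multi_cluster``). When ``tracks`` are given, a would-be bound trace
    overlapping the start/end of its host cluster's observation window is
    judged only on frames where the cluster is defined; with fewer than
    ``min_defined`` such frames it is flagged ``excluded_short`` and should
    be dropped from bound statistics.

    Returns one row per trace: ``trace_id, label, cluster_id, n_inside,
    n_total, multi_cluster, excluded_short``.
    """
    by_id = {tr.id: tr for tr in (tracks or [])}
    rows = []
    for tr in traces:
        ids = assignments.loc[tr.locs.index, "cluster_id"].to_numpy()
        inside = ids >= 0
        n_inside = int(inside.sum())
        hosts = np.unique(ids[inside])
        label, cluster_id, multi, excl = UNBOUND, -1, False, False
        if n_inside == 0:
            label = UNBOUND
        elif len(hosts) > 1:
            label, multi = PARTIALLY_BOUND, True
        else:
            host = int(hosts[0])
            if n_inside == len(tr):
                label, cluster_id = BOUND, host
            else:
                # members outside the footprint: bound only if every such frame
                # falls outside the host cluster's observation window
                track = by_id.get(host)
                if track is not None:
                    defined = track.defined_at(tr.frames)
                    if np.all(inside[defined]) and defined.any():
                        label, cluster_id = BOUND, host
                        if int(defined.sum()) < min_defined:
                            excl = True
                    else:
                        label = PARTIALLY_BOUND
                else:
                    label = PARTIALLY_BOUND
        rows.append(
            {
                "trace_id": tr.id,
                "label": label,
                "cluster_id": cluster_id,
                "n_inside": n_inside,
                "n_total": len(tr),
                "multi_cluster": multi,
                "excluded_short": excl,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class CorrectedCluster:
    """Motion-corrected localizations of one locus, in its co-moving frame.

    ``locs`` columns: ``trace_id, frame, dx, dy, precision`` with dx/dy in um
    relative to the interpolated cluster center (origin = cluster center).
    """

    cluster_id: int
    locs: pd.DataFrame
    duration_s: float
    trace_ids: list[int] = field(default_factory=list)
    n_excluded: int = 0

    @property
    def n_localizations(self) -> int:
        return len(self.locs)

    @property
    def localization_rate(self) -> float:
        """Duration-normalized localization count (1/s).

        With a constant photoactivation rate this makes clusters observed for
        different times comparable.
        """
        return self.n_localizations / self.duration_s

    @property
    def points(self) -> np.ndarray:
        return self.locs[["dx", "dy"]].to_numpy(dtype=float)


def motion_correct(track: ClusterTrack, bound_traces: list[Trace]) -> CorrectedCluster:
    """Subtract the interpolated cluster trajectory from bound localizations.

    Each corrected coordinate is the raw registered coordinate minus the
    interpolated cluster center at that localization's frame, so rigid locus
    motion cancels exactly and within-frame relative geometry is untouched.
    Localizations at frames where the cluster center is undefined are
    excluded (counted in ``n_excluded``).
    """
    if not track.interpolated:
        raise ValueError("cluster track must be interpolated before motion correction")
    rows = []
    n_excluded = 0
    for tr in bound_traces:
        frames = tr.frames
        ok = track.defined_at(frames)
        n_excluded += int((~ok).sum())
        if not ok.any():
            continue
        cx, cy = track.center_at(frames[ok])
        sub = tr.locs.loc[ok]
        prec = sub["precision"].to_numpy() if "precision" in sub.columns else np.full(ok.sum(), np.nan)
        rows.append(
            pd.DataFrame(
                {
                    "trace_id": tr.id,
                    "frame": frames[ok],
                    "dx": sub["x"].to_numpy() - cx,
                    "dy": sub["y"].to_numpy() - cy,
                    "precision": prec,
                    "loc_index": sub.index.to_numpy(),
                }
            )
        )
    locs = (
        pd.concat(rows, ignore_index=True)
        if rows
        else pd.DataFrame(columns=["trace_id", "frame", "dx", "dy", "precision", "loc_index"])
    )
    return CorrectedCluster(
        cluster_id=track.id,
        locs=locs,
        duration_s=track.duration_s,
        trace_ids=[tr.id for tr in bound_traces],
        n_excluded=n_excluded,
    )
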