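"""Time-averaged structural metrics of motion-corrected loci.

All functions take point sets in micrometres (the co-moving-frame coordinates
produced by :func:`mcpalm.correlate.motion_correct`); the aggregate
:func:`cluster_metrics` reports distances in nanometres and areas in um^2, the
scales on which sub-diffraction locus structure is quoted.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

from .correlate import CorrectedCluster

__all__ = [
    "DegenerateGeometryError",
    "hull_area",
    "extension",
    "radius_of_gyration",
    "ellipse_axes",
    "localization_density",
    "ClusterMetrics",
    "cluster_metrics",
    "metrics_table",
    "render",
    "save_render",
]


class DegenerateGeometryError(ValueError):
    """Point set too small or degenerate for the requested metric."""


def _points(points) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("expected an (n, 2) point array")
    return pts


def hull_area(points) -> float:
    """Convex-hull area (um^2) of the localization boundary."""
    pts = _points(points)
    if len(pts) < 3:
        raise DegenerateGeometryError("hull area needs at least 3 points")
    try:
        hull = ConvexHull(pts)
    except QhullError as exc:
        raise DegenerateGeometryError("degenerate (collinear) point set") from exc
    return float(hull.volume)  # in 2D, .volume is the area


def extension(points) -> float:
    """Maximal pairwise distance (same units as input).

    The diameter of a point set is attained between convex-hull vertices, so
    only those are searched when a hull exists; collinear sets fall back to
    the full pairwise search.
    """
    pts = _points(points)
    if len(pts) < 2:
        raise DegenerateGeometryError("extension needs at least 2 points")
    if len(pts) >= 3:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except QhullError:
            pass
    diff = pts[:, None, :] - pts[None, :, :]
    return float(np.sqrt((diff**2).sum(-1)).max())


def radius_of_gyration(points) -> float:
    """Root mean squared distance to the centroid (same units as input)."""
    pts = _points(points)
    if len(pts) < 2:
        raise DegenerateGeometryError("radius of gyration needs at least 2 points")
    c = pts.mean(axis=0)
    return float(np.sqrt(((pts - c) ** 2).sum(axis=1).mean()))


def ellipse_axes(points) -> tuple[float, float]:
    """(minor, major) axes of the covariance ellipse, 2x sqrt(eigenvalues).

    Rotation- and translation-invariant shape descriptor; an isotropic point
    cloud has axis ratio -> 1, an elongated one minor << major.
    """
    pts = _points(points)
    if len(pts) < 3:
        raise DegenerateGeometryError("ellipse fit needs at least 3 points")
    cov = np.cov(pts.T, ddof=1)
    ev = np.linalg.eigvalsh(cov)
    if ev[0] <= 0:
        raise DegenerateGeometryError("degenerate covariance (collinear points)")
    minor, major = 2.0 * np.sqrt(ev)
    return float(minor), float(major)


def localization_density(n_localizations: int, duration_s: float, area_um2: float) -> float:
    """Duration-normalized localization density (um^-2 s^-1).

    With a constant photoactivation rate the localization count grows
    linearly with observation time, so the count is first normalized by the
    cluster's duration in the field of view and then by its hull area.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    if area_um2 <= 0:
        raise ValueError("area must be positive")
    return n_localizations / duration_s / area_um2


@dataclass
class ClusterMetrics:
    cluster_id: int
    n_localizations: int
    duration_s: float
    area_um2: float
    extension_nm: float
    radius_of_gyration_nm: float
    minor_axis_nm: float
    major_axis_nm: float
    localization_rate_per_s: float
    localization_density_per_um2_s: float

    def as_dict(self) -> dict:
        return asdict(self)


def cluster_metrics(corrected: CorrectedCluster) -> ClusterMetrics:
    """All structural metrics of one motion-corrected cluster."""
    pts = corrected.points
    area = hull_area(pts)
    minor, major = ellipse_axes(pts)
    return ClusterMetrics(
        cluster_id=corrected.cluster_id,
        n_localizations=corrected.n_localizations,
        duration_s=corrected.duration_s,
        area_um2=area,
        extension_nm=extension(pts) * 1e3,
        radius_of_gyration_nm=radius_of_gyration(pts) * 1e3,
        minor_axis_nm=minor * 1e3,
        major_axis_nm=major * 1e3,
        localization_rate_per_s=corrected.localization_rate,
        localization_density_per_um2_s=localization_density(
            corrected.n_localizations, corrected.duration_s, area
        ),
    )


def metrics_table(corrected_clusters: list[CorrectedCluster], min_points: int = 3) -> pd.DataFrame:
    """Metrics of every cluster with at least ``min_points`` corrected points."""
    rows = [
        cluster_metrics(cc).as_dict()
        for cc in corrected_clusters
        if cc.n_localizations >= min_points
    ]
    return pd.DataFrame(rows)


def render(
    points,
    precision_nm,
    pixel_nm: float = 10.0,
    extent=None,
    truncate: float = 4.0,
) -> tuple[np.ndarray, tuple[float, float]]:
    """Render localizations as a sum of unit-integral Gaussians.

    Each localization contributes a 2D Gaussian of width equal to its
    localization precision, so the integrated image intensity equals the
    number of localizations — the standard super-resolution rendering.

    Parameters
    ----------
    points : (n, 2) array in um
    precision_nm : scalar or (n,) per-localization precision
    pixel_nm : rendering pixel size
    extent : optional (xmin, xmax, ymin, ymax) in um; default fits the data
        with a 3-sigma margin.

    Returns
    -------
    image : 2D float array indexed [row=y, col=x]
    origin : (x0, y0) of the lower-left pixel edge in um
    """
    pts = _points(points)
    sig_nm = np.broadcast_to(np.asarray(precision_nm, dtype=float), (len(pts),))
    sig_um = sig_nm * 1e-3
    px = pixel_nm * 1e-3
    if extent is None:
        m = 3.0 * sig_um.max() if len(pts) else 0.0
        extent = (
            pts[:, 0].min() - m,
            pts[:, 0].max() + m,
            pts[:, 1].min() - m,
            pts[:, 1].max() + m,
        )
    x0, x1, y0, y1 = extent
    nx = max(int(np.ceil((x1 - x0) / px)), 1)
    ny = max(int(np.ceil((y1 - y0) / px)), 1)
    img = np.zeros((ny, nx))
    xc = x0 + (np.arange(nx) + 0.5) * px
    yc = y0 + (np.arange(ny) + 0.5) * px
    for (x, y), s in zip(pts, sig_um):
        r = truncate * s
        ix = np.searchsorted(xc, [x - r, x + r])
        iy = np.searchsorted(yc, [y - r, y + r])
        gx = np.exp(-((xc[ix[0] : ix[1]] - x) ** 2) / (2 * s**2))
        gy = np.exp(-((yc[iy[0] : iy[1]] - y) ** 2) / (2 * s**2))
        patch = np.outer(gy, gx) * (px**2 / (2 * np.pi * s**2))
        img[iy[0] : iy[1], ix[0] : ix[1]] += patch
    return img, (x0, y0)


def save_render(img: np.ndarray, path, pixel_nm: float) -> None:
    """Write a rendered image as 16-bit TIFF with nm-per-pixel resolution tags.

    Intensities are scaled to the full 16-bit range; the pixel pitch is
    stored in the TIFF resolution tags (pixels per centimetre).
    """
    import tifffile

    peak = img.max()
    scaled = (img / peak * 65535).astype(np.uint16) if peak > 0 else img.astype(np.uint16)
    px_per_cm = 1e7 / pixel_nm
    tifffile.imwrite(
        path,
        scaled,
        resolution=(px_per_cm, px_per_cm),
        resolutionunit="CENTIMETER",
        metadata={"pixel_nm": pixel_nm},
    )
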