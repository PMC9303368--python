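"""Localization-table I/O, shutter-sequence bookkeeping and localization precision.

Canonical in-memory container is a :class:`pandas.DataFrame` with one row per
localization and columns

====================  =========================================================
``x``, ``y``          position in micrometres
``frame``             1-based acquisition frame index (int)
``photons``           fitted photon count
``width``             fitted PSF width in nanometres
``background``        background level in photons per pixel
``precision``         localization precision sigma_loc in nanometres (optional
                      on input; see :func:`add_precision`)
====================  =========================================================

Interleaved acquisitions record one conventional (e.g. GFP) frame and one
photoactivation frame per shutter cycle; the remaining frames carry
single-molecule (PALM) signal. :class:`ShutterSequence` maps absolute frame
numbers onto that cycle.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "REQUIRED_COLUMNS",
    "FormatError",
    "ParseError",
    "ShutterSequence",
    "ExperimentConfig",
    "read_localizations",
    "write_localizations",
    "thompson_precision",
    "add_precision",
]

#: mandatory columns of a localization table (after column-map renaming)
REQUIRED_COLUMNS = ("x", "y", "frame", "photons", "width", "background")

_UNIT_TO_UM = {"um": 1.0, "nm": 1e-3}


class FormatError(ValueError):
    """Input table does not have the expected columns."""


class ParseError(ValueError):
    """A table cell could not be interpreted as a number."""


@dataclass(frozen=True)
class ShutterSequence:
    """Repeating frame pattern of an interleaved acquisition.

    The default is a 10-frame cycle at 20 Hz: frame 1 of each cycle is the
    conventional-fluorescence image, frame 2 the photoactivation/bright-field
    frame, and the remaining 8 frames are PALM single-molecule frames.
    """

    cycle_length: int = 10
    conventional_slot: int = 1
    activation_slot: int = 2
    frame_rate: float = 20.0

    def __post_init__(self) -> None:
        if not (1 <= self.conventional_slot <= self.cycle_length):
            raise ValueError("conventional_slot outside cycle")
        if not (1 <= self.activation_slot <= self.cycle_length):
            raise ValueError("activation_slot outside cycle")
        if self.conventional_slot == self.activation_slot:
            raise ValueError("conventional and activation slots must differ")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    @property
    def palm_slots(self) -> tuple[int, ...]:
        reserved = {self.conventional_slot, self.activation_slot}
        return tuple(s for s in range(1, self.cycle_length + 1) if s not in reserved)

    @property
    def frames_per_cycle_palm(self) -> int:
        return self.cycle_length - 2

    @property
    def dt(self) -> float:
        """Time between successive camera frames (s)."""
        return 1.0 / self.frame_rate

    def slot(self, frame):
        """1-based slot within the cycle for absolute frame number(s)."""
        frame = np.asarray(frame)
        if np.any(frame < 1):
            raise ValueError("frame indices are 1-based")
        return (frame - 1) % self.cycle_length + 1

    def frame_role(self, frame: int) -> str:
        """Classify a frame as ``conventional``, ``activation`` or ``palm``."""
        s = int(self.slot(frame))
        if s == self.conventional_slot:
            return "conventional"
        if s == self.activation_slot:
            return "activation"
        return "palm"

    def is_conventional(self, frames) -> np.ndarray:
        return np.asarray(self.slot(frames)) == self.conventional_slot

    def is_palm(self, frames) -> np.ndarray:
        s = np.asarray(self.slot(frames))
        return (s != self.conventional_slot) & (s != self.activation_slot)

    def palm_index(self, frames) -> np.ndarray:
        """Sequential 0-based index of a frame on the PALM-frame grid.

        Two single-molecule localizations are "in consecutive frames" when
        their PALM indices differ by one; the conventional and activation
        slots do not count as dark frames.
        """
        frames = np.asarray(frames, dtype=np.int64)
        if not np.all(self.is_palm(frames)):
            raise ValueError("palm_index requested for a non-PALM frame")
        cycle = (frames - 1) // self.cycle_length
        slot = self.slot(frames)
        ranks = {s: i for i, s in enumerate(self.palm_slots)}
        rank = np.vectorize(ranks.__getitem__, otypes=[np.int64])(slot)
        return cycle * self.frames_per_cycle_palm + rank

    def conventional_index(self, frames) -> np.ndarray:
        """0-based cycle index of conventional frames."""
        frames = np.asarray(frames, dtype=np.int64)
        if not np.all(self.is_conventional(frames)):
            raise ValueError("conventional_index requested for a non-conventional frame")
        return (frames - 1) // self.cycle_length

    def conventional_frames(self, n_frames: int) -> np.ndarray:
        """All conventional frame numbers of an ``n_frames``-long movie."""
        f = np.arange(1, n_frames + 1)
        return f[self.is_conventional(f)]

    def palm_frames(self, n_frames: int) -> np.ndarray:
        f = np.arange(1, n_frames + 1)
        return f[self.is_palm(f)]


def thompson_precision(photons, width_nm, background, pixel_size_nm=160.0):
    """Localization precision (nm) from fitted-spot photometry.

    Uses the three-term expression for the variance of a 2D Gaussian fit

        sigma^2 = s^2/N + a^2/(12 N) + 8 pi s^4 b^2 / (a^2 N^2)

    with ``s`` the fitted PSF width (nm), ``N`` the photon count, ``a`` the
    back-projected pixel size (nm) and ``b`` the background noise
    (photons/pixel). With ``a == 0`` (idealized continuous detector) the
    pixelation and background terms vanish and the shot-noise limit
    ``s/sqrt(N)`` is returned, provided ``b == 0``.
    """
    photons = np.asarray(photons, dtype=float)
    width_nm = np.asarray(width_nm, dtype=float)
    background = np.asarray(background, dtype=float)
    if np.any(photons <= 0):
        raise ValueError("photon counts must be positive")
    if np.any(width_nm <= 0):
        raise ValueError("PSF widths must be positive")
    a = float(pixel_size_nm)
    if a == 0.0:
        if np.any(background != 0):
            raise ValueError("background term requires a positive pixel size")
        var = width_nm**2 / photons
    else:
        var = (
            width_nm**2 / photons
            + a**2 / (12.0 * photons)
            + 8.0 * np.pi * width_nm**4 * background**2 / (a**2 * photons**2)
        )
    out = np.sqrt(var)
    return float(out) if out.ndim == 0 else out


def add_precision(locs: pd.DataFrame, pixel_size_nm: float = 160.0) -> pd.DataFrame:
    """Return a copy of ``locs`` with the ``precision`` column (nm) filled in."""
    out = locs.copy()
    out["precision"] = thompson_precision(
        out["photons"].to_numpy(),
        out["width"].to_numpy(),
        out["background"].to_numpy(),
        pixel_size_nm,
    )
    return out


def _detect_sep(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","


def read_localizations(
    path,
    units: str = "um",
    column_map: dict[str, str] | None = None,
    pixel_size_nm: float = 160.0,
    sep: str | None = None,
) -> pd.DataFrame:
    """Read a delimited localization table into the canonical frame.

    Parameters
    ----------
    path
        CSV/TSV file with a header row.
    units
        Unit of the ``x``/``y`` columns in the file: ``um``, ``nm`` or
        ``pixel``. Positions are converted to micrometres. PSF widths are
        expected in nm, except in ``pixel`` dialects where they are camera
        pixels and are converted to nm.
    column_map
        Optional mapping from file column names to canonical names, e.g.
        ``{"Xc": "x", "Yc": "y"}`` for Insight3-style exports.
    pixel_size_nm
        Back-projected camera pixel size, used when ``units == "pixel"``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=sep if sep is not None else _detect_sep(path), dtype=str)
    df.columns = [c.strip() for c in df.columns]
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing mandatory column(s): {', '.join(missing)}")

    keep = list(REQUIRED_COLUMNS) + (["precision"] if "precision" in df.columns else [])
    df = df[keep]
    out = {}
    for col in df.columns:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(
                f"non-numeric value {df[col].iloc[row]!r} in column {col!r}, data row {row + 1}"
            )
        out[col] = numeric.to_numpy(dtype=float)
    res = pd.DataFrame(out)

    if units not in {"um", "nm", "pixel"}:
        raise ValueError(f"unknown units {units!r}")
    to_um = _UNIT_TO_UM.get(units, pixel_size_nm * 1e-3)
    res["x"] *= to_um
    res["y"] *= to_um
    # widths are PSF widths in nm in um/nm dialects; in camera pixels otherwise
    if units == "pixel":
        res["width"] *= pixel_size_nm
    res["frame"] = res["frame"].astype(np.int64)
    if np.any(res["frame"] < 1):
        raise ParseError("frame indices must be >= 1")
    res = res.sort_values("frame", kind="stable").reset_index(drop=True)
    return res


def write_localizations(locs: pd.DataFrame, path) -> None:
    """Write a canonical localization table (positions um, widths nm) as CSV."""
    path = Path(path)
    cols = [c for c in list(REQUIRED_COLUMNS) + ["precision"] if c in locs.columns]
    locs[cols].to_csv(path, index=False, float_format="%.9g")


@dataclass
class ExperimentConfig:
    """Analysis parameters of a correlative conventional + PALM experiment.

    Distances are micrometres unless suffixed ``_nm``. Defaults encode the
    canonical interleaved-acquisition analysis: 0.48 um single-molecule link
    radius with >= 4 localizations per trace, 0.68 um cluster link radius
    with >= 5 localizations and 200 nm width continuity, 10-frame shutter
    cycle at 20 Hz.
    """

    pixel_size_nm: float = 160.0
    sm_link_radius_um: float = 0.48
    sm_min_length: int = 4
    cluster_link_radius_um: float = 0.68
    cluster_min_length: int = 5
    width_tolerance_nm: float = 200.0
    shutter: ShutterSequence = field(default_factory=ShutterSequence)
    gmm_components: tuple[int, ...] = (1, 2, 3)
    max_fit_lags: int | None = 2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("pixel_size_nm", "sm_link_radius_um", "cluster_link_radius_um", "width_tolerance_nm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if isinstance(self.shutter, dict):
            self.shutter = ShutterSequence(**self.shutter)
        self.gmm_components = tuple(int(k) for k in self.gmm_components)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["gmm_components"] = list(self.gmm_components)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
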