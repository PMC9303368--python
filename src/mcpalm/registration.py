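"""Two-channel fiducial registration with a bivariate polynomial transform.

Dual-camera/dual-color localization microscopes image the single-molecule
channel and the conventional channel through different emission paths, so the
two coordinate systems differ by field-dependent (spherical/chromatic)
aberrations. Multi-field bead calibrations are fitted with a full bivariate
polynomial of total degree <= 3 per output axis (10 coefficients each),
mapping "top"-channel coordinates into the "bottom" (conventional) channel.

Bead-pair tables are DataFrames with columns ``x_top, y_top, x_bot, y_bot``
(micrometres) and optionally ``field_id`` identifying the calibration image.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "BEAD_COLUMNS",
    "PolynomialTransform",
    "polynomial_terms",
    "fit_transform",
    "apply_transform",
    "holdout_registration_error",
    "read_bead_pairs",
    "write_bead_pairs",
]

BEAD_COLUMNS = ("x_top", "y_top", "x_bot", "y_bot")


def _exponents(degree: int) -> list[tuple[int, int]]:
    """Monomial exponents (i, j) with i + j <= degree, in a fixed order."""
    return [(i, j) for total in range(degree + 1) for i in range(total + 1) for j in [total - i]]


def polynomial_terms(x, y, degree: int) -> np.ndarray:
    """Design matrix of bivariate monomials x^i y^j, total degree <= degree."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return np.column_stack([x**i * y**j for i, j in _exponents(degree)])


@dataclass
class PolynomialTransform:
    """Coordinate mapping x' = Px(x, y), y' = Py(x, y).

    ``coef_x``/``coef_y`` are the coefficients of the monomial basis returned
    by :func:`polynomial_terms` for the given ``degree``. Evaluation is
    deterministic; the identity transform reproduces its input exactly.
    """

    degree: int
    coef_x: np.ndarray
    coef_y: np.ndarray
    rms_residual_nm: float = float("nan")

    @classmethod
    def identity(cls, degree: int = 3) -> "PolynomialTransform":
        n = len(_exponents(degree))
        cx = np.zeros(n)
        cy = np.zeros(n)
        exps = _exponents(degree)
        cx[exps.index((1, 0))] = 1.0
        cy[exps.index((0, 1))] = 1.0
        return cls(degree=degree, coef_x=cx, coef_y=cy, rms_residual_nm=0.0)

    def apply(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        A = polynomial_terms(x, y, self.degree)
        return A @ self.coef_x, A @ self.coef_y

    def to_json(self, path=None) -> str:
        blob = json.dumps(
            {
                "degree": self.degree,
                "coef_x": list(self.coef_x),
                "coef_y": list(self.coef_y),
                "rms_residual_nm": self.rms_residual_nm,
            },
            indent=1,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(blob)
        return blob

    @classmethod
    def from_json(cls, src) -> "PolynomialTransform":
        if hasattr(src, "read"):
            d = json.load(src)
        elif isinstance(src, (str, bytes)) and str(src).lstrip().startswith("{"):
            d = json.loads(src)
        else:
            with open(src) as fh:
                d = json.load(fh)
        return cls(
            degree=int(d["degree"]),
            coef_x=np.asarray(d["coef_x"], dtype=float),
            coef_y=np.asarray(d["coef_y"], dtype=float),
            rms_residual_nm=float(d["rms_residual_nm"]),
        )


def fit_transform(pairs: pd.DataFrame, degree: int = 3) -> PolynomialTransform:
    """Least-squares fit of the top -> bottom channel mapping.

    Requires at least as many bead pairs as coefficients per axis (10 for
    degree 3) and a non-degenerate spatial layout; rank deficiency raises,
    poor conditioning warns.
    """
    for c in BEAD_COLUMNS:
        if c not in pairs.columns:
            raise ValueError(f"bead-pair table lacks column {c!r}")
    A = polynomial_terms(pairs["x_top"], pairs["y_top"], degree)
    n_terms = A.shape[1]
    if len(pairs) < n_terms:
        raise ValueError(
            f"underdetermined fit: {len(pairs)} bead pairs for {n_terms} coefficients per axis"
        )
    rank = np.linalg.matrix_rank(A)
    if rank < n_terms:
        raise ValueError("degenerate bead layout: design matrix is rank-deficient")
    cond = np.linalg.cond(A)
    if cond > 1e10:
        warnings.warn(f"ill-conditioned bead layout (cond={cond:.2g})", stacklevel=2)
    cx, *_ = np.linalg.lstsq(A, pairs["x_bot"].to_numpy(dtype=float), rcond=None)
    cy, *_ = np.linalg.lstsq(A, pairs["y_bot"].to_numpy(dtype=float), rcond=None)
    t = PolynomialTransform(degree=degree, coef_x=cx, coef_y=cy)
    px, py = t.apply(pairs["x_top"], pairs["y_top"])
    res2 = (px - pairs["x_bot"]) ** 2 + (py - pairs["y_bot"]) ** 2
    t.rms_residual_nm = float(np.sqrt(res2.mean()) * 1e3)
    return t


def apply_transform(transform: PolynomialTransform, locs: pd.DataFrame) -> pd.DataFrame:
    """Map localization coordinates into the conventional channel.

    Only ``x`` and ``y`` change; row order and all other columns are kept.
    The returned frame is tagged ``attrs["channel"] = "conventional"`` so
    downstream colocalization can assert registered input.
    """
    out = locs.copy()
    x, y = transform.apply(locs["x"].to_numpy(), locs["y"].to_numpy())
    out["x"] = x
    out["y"] = y
    out.attrs["channel"] = "conventional"
    return out


def holdout_registration_error(pairs: pd.DataFrame, degree: int = 3) -> dict[str, float]:
    """Registration precision by leave-one-field-out cross-validation.

    Fits the transform on all calibration fields but one, maps the held-out
    field's top-channel beads, and pools the residuals against the measured
    bottom-channel positions. Returns both the RMS and the mean Euclidean
    mapping error, in nanometres.
    """
    if "field_id" not in pairs.columns:
        raise ValueError("hold-out estimation requires a field_id column")
    fields = pairs["field_id"].unique()
    if len(fields) < 2:
        raise ValueError("need at least two calibration fields to hold one out")
    sq, dist = [], []
    for f in fields:
        train = pairs[pairs["field_id"] != f]
        test = pairs[pairs["field_id"] == f]
        t = fit_transform(train, degree=degree)
        px, py = t.apply(test["x_top"], test["y_top"])
        d2 = (px - test["x_bot"]) ** 2 + (py - test["y_bot"]) ** 2
        sq.extend(d2.tolist())
        dist.extend(np.sqrt(d2).tolist())
    return {
        "rms_nm": float(np.sqrt(np.mean(sq)) * 1e3),
        "mean_nm": float(np.mean(dist) * 1e3),
        "n_heldout": len(sq),
    }


def read_bead_pairs(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in BEAD_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"bead-pair table lacks column(s): {', '.join(missing)}")
    return df


def write_bead_pairs(pairs: pd.DataFrame, path) -> None:
    pairs.to_csv(path, index=False, float_format="%.9g")
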