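"""Control-point polynomial registration between global images and
profilometry scans.

An analyst picks corresponding points on damage features visible in both the
global photograph and the OP scan; a bivariate polynomial transform (degree 2
by default, six coefficients per axis, so six point pairs determine it
exactly) maps global coordinates into the scan frame.  More than the minimum
number of pairs is solved in the least-squares sense.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np


def _n_coeffs(degree: int) -> int:
    return (degree + 1) * (degree + 2) // 2


def _design_matrix(pts: np.ndarray, degree: int) -> np.ndarray:
    """Monomial basis, ordered by total degree: [1, x, y, x^2, xy, y^2, ...].

    The ordering is fixed for serialization stability.
    """
    x, y = pts[:, 0], pts[:, 1]
    cols = []
    for total in range(degree + 1):
        for j in range(total + 1):  # x^(total-j) * y^j
            cols.append(x ** (total - j) * y**j)
    return np.column_stack(cols)


@dataclass
class ControlPointSet:
    """Paired (global px, scan px) landmark coordinates."""

    global_pts: np.ndarray  # (n, 2)
    scan_pts: np.ndarray    # (n, 2)

    def __post_init__(self) -> None:
        self.global_pts = np.atleast_2d(np.asarray(self.global_pts, dtype=float))
        self.scan_pts = np.atleast_2d(np.asarray(self.scan_pts, dtype=float))
        if self.global_pts.shape != self.scan_pts.shape or self.global_pts.shape[1] != 2:
            raise ValueError("control points must be matched (n, 2) arrays")
        uniq = np.unique(self.global_pts, axis=0)
        if len(uniq) != len(self.global_pts):
            raise ValueError("duplicate global control points")

    def __len__(self) -> int:
        return len(self.global_pts)

    @classmethod
    def from_csv(cls, path) -> "ControlPointSet":
        arr = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        return cls(arr[:, :2], arr[:, 2:4])

    def to_csv(self, path) -> None:
        arr = np.hstack([self.global_pts, self.scan_pts])
        header = "gx,gy,sx,sy"
        np.savetxt(path, arr, delimiter=",", header=header, comments="", fmt="%.9g")


class DegenerateControlPointsError(ValueError):
    """Raised when the control-point configuration cannot determine the fit."""


@dataclass
class PolyTransform2D:
    """Bivariate polynomial warp x' = Px(x, y), y' = Py(x, y)."""

    degree: int
    coeffs_x: np.ndarray
    coeffs_y: np.ndarray
    rms_residual: float = 0.0

    def __post_init__(self) -> None:
        n = _n_coeffs(self.degree)
        self.coeffs_x = np.asarray(self.coeffs_x, dtype=float)
        self.coeffs_y = np.asarray(self.coeffs_y, dtype=float)
        if len(self.coeffs_x) != n or len(self.coeffs_y) != n:
            raise ValueError(f"degree {self.degree} needs {n} coefficients per axis")

    def __call__(self, points: np.ndarray) -> np.ndarray:
        return apply_transform(self, points)

    def to_json(self, path=None) -> str:
        obj = {
            "degree": self.degree,
            "basis": "total-degree order [1, x, y, x^2, xy, y^2, ...]",
            "coeffs_x": self.coeffs_x.tolist(),
            "coeffs_y": self.coeffs_y.tolist(),
            "rms_residual_px": self.rms_residual,
        }
        s = json.dumps(obj, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s

    @classmethod
    def from_json(cls, source) -> "PolyTransform2D":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            obj = json.loads(source)
        else:
            with open(source) as fh:
                obj = json.load(fh)
        return cls(
            degree=obj["degree"],
            coeffs_x=np.array(obj["coeffs_x"]),
            coeffs_y=np.array(obj["coeffs_y"]),
            rms_residual=obj.get("rms_residual_px", 0.0),
        )


def fit_poly_transform(cps: ControlPointSet, degree: int = 2) -> PolyTransform2D:
    """Least-squares fit of the polynomial warp to the control points.

    With exactly as many pairs as coefficients (six for degree 2) the fit
    interpolates and the RMS residual is ~0.  Rank-deficient configurations
    (e.g. collinear points at degree >= 1) raise
    :class:`DegenerateControlPointsError`.
    """
    n = _n_coeffs(degree)
    if len(cps) < n:
        raise ValueError(f"degree {degree} needs >= {n} control point pairs")
    A = _design_matrix(cps.global_pts, degree)
    if np.linalg.matrix_rank(A) < n:
        raise DegenerateControlPointsError(
            "control-point configuration is degenerate for this degree"
        )
    cx, *_ = np.linalg.lstsq(A, cps.scan_pts[:, 0], rcond=None)
    cy, *_ = np.linalg.lstsq(A, cps.scan_pts[:, 1], rcond=None)
    pred = np.column_stack([A @ cx, A @ cy])
    rms = float(np.sqrt(np.mean(np.sum((pred - cps.scan_pts) ** 2, axis=1))))
    return PolyTransform2D(degree=degree, coeffs_x=cx, coeffs_y=cy, rms_residual=rms)


def apply_transform(T: PolyTransform2D, points) -> np.ndarray:
    """Map (n, 2) points through the polynomial warp, preserving order."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    A = _design_matrix(pts, T.degree)
    return np.column_stack([A @ T.coeffs_x, A @ T.coeffs_y])


def identity_transform(degree: int = 2) -> PolyTransform2D:
    n = _n_coeffs(degree)
    cx = np.zeros(n)
    cy = np.zeros(n)
    cx[1] = 1.0  # x term
    cy[2] = 1.0  # y term
    return PolyTransform2D(degree=degree, coeffs_x=cx, coeffs_y=cy)


def scaling_transform(sx: float, sy: float | None = None, degree: int = 2) -> PolyTransform2D:
    """Pure scaling warp (used e.g. for the known mm -> um pixel mapping)."""
    if sy is None:
        sy = sx
    T = identity_transform(degree)
    T.coeffs_x[1] = sx
    T.coeffs_y[2] = sy
    return T
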