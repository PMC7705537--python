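"""Sub-pixel whisker centerline detection via second-order ridge analysis.

The cleaned frame is treated as a height map in which whiskers are bright
ridges.  At every pixel the 2x2 Hessian of the Gaussian-smoothed image is
eigen-decomposed; the eigenvector of the strongest negative eigenvalue gives
the ridge-normal direction, and a 1-D second-order Taylor model of the
intensity along that normal is solved for the zero of the first directional
derivative.  A pixel contributes a centerline point when that zero falls
within half a pixel of its centre along the normal, which yields at most one
point per pixel with sub-pixel position and local tangent direction.

Every step is an independent per-pixel computation (convolutions aside), so
results do not depend on any processing order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import ndimage as ndi

__all__ = [
    "DerivativeStack",
    "CenterlinePoint",
    "CenterlinePoints",
    "compute_derivatives",
    "detect_centerline_points",
    "strength_quantile",
]


@dataclass
class DerivativeStack:
    """The five Gaussian partial derivatives of a frame at scale sigma.

    ``x`` is the column coordinate, ``y`` the row coordinate (y down).
    """

    rx: np.ndarray
    ry: np.ndarray
    rxx: np.ndarray
    rxy: np.ndarray
    ryy: np.ndarray
    sigma: float


class CenterlinePoint(NamedTuple):
    x: float
    y: float
    direction: float  # tangent angle, radians in [0, pi)
    strength: float  # |second directional derivative| across the ridge
    pixel: tuple[int, int]  # (row, col) of the owning pixel


class CenterlinePoints:
    """Column-oriented container of centerline points.

    Behaves like a sequence of :class:`CenterlinePoint` but stores the
    coordinates, directions and strengths as flat arrays, which is what the
    clustering stage consumes.
    """

    __slots__ = ("x", "y", "direction", "strength", "rows", "cols")

    def __init__(self, x, y, direction, strength, rows, cols):
        self.x = np.asarray(x, float)
        self.y = np.asarray(y, float)
        self.direction = np.asarray(direction, float)
        self.strength = np.asarray(strength, float)
        self.rows = np.asarray(rows, int)
        self.cols = np.asarray(cols, int)

    @classmethod
    def empty(cls) -> "CenterlinePoints":
        z = np.empty(0)
        return cls(z, z, z, z, z.astype(int), z.astype(int))

    @property
    def xy(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])

    def __len__(self) -> int:
        return len(self.x)

    def __getitem__(self, i):
        if isinstance(i, (int, np.integer)):
            return CenterlinePoint(
                float(self.x[i]),
                float(self.y[i]),
                float(self.direction[i]),
                float(self.strength[i]),
                (int(self.rows[i]), int(self.cols[i])),
            )
        return CenterlinePoints(
            self.x[i], self.y[i], self.direction[i], self.strength[i],
            self.rows[i], self.cols[i],
        )

    def __iter__(self):
        for i in range(len(self)):
            yield self[i]

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "x": self.x,
                "y": self.y,
                "direction": self.direction,
                "strength": self.strength,
                "row": self.rows,
                "col": self.cols,
            }
        )


def compute_derivatives(image: np.ndarray, sigma: float = 1.5) -> DerivativeStack:
    """Separable Gaussian-derivative convolutions, reflected at borders."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    image = np.asarray(image, float)
    # ndi order is per-axis (row, col) = (y, x)
    rx = ndi.gaussian_filter(image, sigma, order=(0, 1), mode="reflect")
    ry = ndi.gaussian_filter(image, sigma, order=(1, 0), mode="reflect")
    rxx = ndi.gaussian_filter(image, sigma, order=(0, 2), mode="reflect")
    rxy = ndi.gaussian_filter(image, sigma, order=(1, 1), mode="reflect")
    ryy = ndi.gaussian_filter(image, sigma, order=(2, 0), mode="reflect")
    return DerivativeStack(rx, ry, rxx, rxy, ryy, float(sigma))


def strength_quantile(derivs: DerivativeStack, q: float = 0.99) -> float:
    """Calibration default for ``min_strength``: a quantile of the magnitude
    of the strongest negative Hessian eigenvalue over one frame."""
    lam = _min_eigenvalue(derivs)[0]
    neg = -lam[lam < 0]
    if neg.size == 0:
        return 0.0
    return float(np.quantile(neg, q))


def _min_eigenvalue(derivs: DerivativeStack):
    """Smaller (most negative) Hessian eigenvalue and its eigenvector."""
    rxx, rxy, ryy = derivs.rxx, derivs.rxy, derivs.ryy
    half_tr = 0.5 * (rxx + ryy)
    root = np.sqrt((0.5 * (rxx - ryy)) ** 2 + rxy * rxy)
    lam_min = half_tr - root
    lam_max = half_tr + root
    # eigenvector for lam_min: (rxy, lam_min - rxx), with a fallback when
    # rxy ~ 0 (axis-aligned Hessian)
    nx = rxy.copy()
    ny = lam_min - rxx
    degenerate = np.abs(nx) + np.abs(ny) < 1e-12
    nx = np.where(degenerate, np.where(rxx <= ryy, 1.0, 0.0), nx)
    ny = np.where(degenerate, np.where(rxx <= ryy, 0.0, 1.0), ny)
    norm = np.hypot(nx, ny)
    return lam_min, lam_max, nx / norm, ny / norm


def detect_centerline_points(
    derivs: DerivativeStack, min_strength: float
) -> CenterlinePoints:
    """Extract sub-pixel ridge points from a derivative stack.

    A pixel is accepted when the strongest-curvature direction has a negative
    second derivative of magnitude >= ``min_strength`` (bright ridge), the
    ridge is stronger across than along (|lam_min| >= |lam_max|), and the
    Taylor-model extremum lies within the pixel (|offset| <= 0.5 px along the
    normal).  Returns an empty container when nothing qualifies.
    """
    lam_min, lam_max, nx, ny = _min_eigenvalue(derivs)
    rx, ry = derivs.rx, derivs.ry
    strength = -lam_min
    candidate = (lam_min < 0) & (strength >= min_strength) & (
        strength >= np.abs(lam_max)
    )
    if not candidate.any():
        return CenterlinePoints.empty()
    # second directional derivative along the normal equals lam_min
    with np.errstate(divide="ignore", invalid="ignore"):
        t = -(rx * nx + ry * ny) / lam_min
    accept = candidate & np.isfinite(t) & (np.abs(t) <= 0.5)
    rows, cols = np.nonzero(accept)
    toff = t[rows, cols]
    nxs, nys = nx[rows, cols], ny[rows, cols]
    xs = cols + toff * nxs
    ys = rows + toff * nys
    # tangent = normal rotated by 90 degrees; ridge direction has no sign
    direction = np.arctan2(nxs, -nys) % np.pi
    return CenterlinePoints(xs, ys, direction, strength[rows, cols], rows, cols)
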