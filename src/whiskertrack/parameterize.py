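"""Parametric whisker description relative to a snout reference line.

A whisker in one frame is abstracted by four numbers {rho, theta, b, L}:

* ``rho``   -- position of the whisker base along the snout line (px from p0),
* ``theta`` -- angle of the basal whisker direction relative to the line,
  in the open interval (0, pi) radians,
* ``b``     -- bending coefficient of the quadratic shape model ``d = b x**2``,
  where ``x`` is the coordinate along the whisker's chord from the snout line
  and ``d`` the perpendicular deviation from that chord (px^-1),
* ``L``     -- straight-line distance from base to tip (px).

Image coordinates are ``(x, y)`` with ``x`` the column and ``y`` the row
(y grows downward).  The snout line carries an "along" unit vector ``u`` and
a normal ``n`` pointing toward the whisker side; whisker angles are measured
from ``u`` toward ``n`` so that every whisker on the normal side has
``theta`` in (0, pi).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "SnoutLine",
    "WhiskerParams",
    "FitConfig",
    "whisker_curve",
    "fit_whisker",
]


@dataclass(frozen=True)
class SnoutLine:
    """Reference line along the snout edge.

    Parameters
    ----------
    p0, p1:
        Endpoints in image coordinates ``(x, y)``.  ``rho`` is measured
        from ``p0`` toward ``p1``.
    flip_normal:
        The normal defaults to ``u`` rotated by -90 deg in image coordinates
        (for a left-to-right horizontal line this points up, i.e. toward
        smaller ``y``).  Set True if the whiskers lie on the other side.
    """

    p0: tuple[float, float]
    p1: tuple[float, float]
    flip_normal: bool = False

    def __post_init__(self) -> None:
        if np.allclose(self.p0, self.p1):
            raise ValueError("snout line endpoints must differ")

    @property
    def along(self) -> np.ndarray:
        u = np.asarray(self.p1, float) - np.asarray(self.p0, float)
        return u / np.linalg.norm(u)

    @property
    def normal(self) -> np.ndarray:
        ux, uy = self.along
        n = np.array([uy, -ux])
        return -n if self.flip_normal else n

    def point_at(self, rho: float | np.ndarray) -> np.ndarray:
        """Image point(s) at position ``rho`` along the line."""
        rho = np.asarray(rho, float)
        return np.asarray(self.p0, float) + np.multiply.outer(rho, self.along)

    def to_line_frame(self, points: np.ndarray) -> np.ndarray:
        """Project image points to (along, normal) coordinates."""
        rel = np.atleast_2d(np.asarray(points, float)) - np.asarray(self.p0, float)
        return np.column_stack([rel @ self.along, rel @ self.normal])

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        """Distance from the line, positive on the whisker side."""
        return self.to_line_frame(points)[:, 1]


@dataclass
class WhiskerParams:
    """The four-parameter description of one whisker in one frame."""

    rho: float
    theta: float
    b: float
    length: float
    rss: float = float("nan")
    frame_index: int = -1
    converged: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.theta < np.pi):
            raise ValueError(f"theta must lie in (0, pi), got {self.theta}")
        if self.length <= 0:
            raise ValueError("length must be positive")

    def as_array(self) -> np.ndarray:
        return np.array([self.rho, self.theta, self.b, self.length])

    @property
    def cot_theta(self) -> float:
        return 1.0 / np.tan(self.theta)


@dataclass
class FitConfig:
    max_iter: int = 100
    tol: float = 1e-10
    basal_fraction: float = 0.25
    min_points: int = 5


def _chord_limit(b: float, length: float) -> float:
    """Chord coordinate x_max at which |curve(x_max) - curve(0)| == length."""
    if b == 0.0:
        return length
    # solve x^2 + b^2 x^4 = L^2 for x >= 0
    b2 = b * b
    return float(np.sqrt((np.sqrt(1.0 + 4.0 * b2 * length * length) - 1.0) / (2.0 * b2)))


def whisker_curve(
    params: WhiskerParams, snout: SnoutLine, n_samples: int = 100
) -> np.ndarray:
    """Sample the forward model as ``(n_samples, 2)`` image points.

    The curve starts on the snout line at ``rho``, proceeds along the chord
    direction at angle ``theta`` and deviates perpendicularly by ``b x**2``;
    it ends where the straight base-to-tip distance reaches ``length``.
    """
    u, n = snout.along, snout.normal
    e = np.cos(params.theta) * u + np.sin(params.theta) * n
    m = -np.sin(params.theta) * u + np.cos(params.theta) * n
    x = np.linspace(0.0, _chord_limit(params.b, params.length), n_samples)
    base = snout.point_at(params.rho)
    return base + np.outer(x, e) + np.outer(params.b * x * x, m)


def _orient_base_first(points: np.ndarray, snout: SnoutLine) -> np.ndarray:
    """Return points ordered so the end closer to the snout line comes first."""
    d = np.abs(snout.signed_distance(points[[0, -1]]))
    return points[::-1] if d[1] < d[0] else points


def _initial_guess(points: np.ndarray, snout: SnoutLine, cfg: FitConfig):
    """Straight-line fit of the basal section -> (rho0, theta0)."""
    k = max(cfg.min_points, int(round(len(points) * cfg.basal_fraction)))
    basal = points[: min(k, len(points))]
    centroid = basal.mean(axis=0)
    centered = basal - centroid
    # principal direction of the basal section
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    d = vt[0]
    # orient tip-ward
    if np.dot(points[-1] - points[0], d) < 0:
        d = -d
    u, n = snout.along, snout.normal
    theta0 = float(np.arctan2(np.dot(d, n), np.dot(d, u))) % np.pi
    theta0 = float(np.clip(theta0, 0.05, np.pi - 0.05))
    c_u, c_n = float(np.dot(centroid - snout.p0, u)), float(
        np.dot(centroid - snout.p0, n)
    )
    d_u, d_n = float(np.dot(d, u)), float(np.dot(d, n))
    if abs(d_n) > 1e-9:
        rho0 = c_u - c_n * d_u / d_n
    else:  # basal section parallel to the snout line
        rho0 = float(np.dot(points[0] - snout.p0, u))
    return rho0, theta0


def _residuals(p: np.ndarray, pts: np.ndarray, snout: SnoutLine) -> np.ndarray:
    rho, theta, b = p
    u, n = snout.along, snout.normal
    base = np.asarray(snout.p0, float) + rho * u
    rel = pts - base
    e = np.cos(theta) * u + np.sin(theta) * n
    m = -np.sin(theta) * u + np.cos(theta) * n
    x = rel @ e
    d = rel @ m
    return d - b * x * x


def fit_whisker(
    cluster, snout: SnoutLine, cfg: FitConfig | None = None, frame_index: int = -1
) -> WhiskerParams:
    """Fit {rho, theta, b, L} to a cluster of centerline points.

    ``L`` is definitional (base-to-tip Euclidean distance); ``rho``, ``theta``
    and ``b`` minimise the squared perpendicular deviation of the points from
    the model curve, measured at matched chord coordinate.  The fit is
    invariant to reversal of the point order: orientation is re-derived from
    the snout line.

    ``cluster`` may be a ``WhiskerCluster`` or a plain ``(n, 2)`` array.
    """
    cfg = cfg or FitConfig()
    pts = np.asarray(getattr(cluster, "xy", cluster), float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("expected an (n, 2) array of image points")
    if len(pts) < cfg.min_points:
        raise ValueError(f"need at least {cfg.min_points} points, got {len(pts)}")
    pts = _orient_base_first(pts, snout)
    length = float(np.linalg.norm(pts[-1] - pts[0]))
    rho0, theta0 = _initial_guess(pts, snout, cfg)
    sol = least_squares(
        _residuals,
        np.array([rho0, theta0, 0.0]),
        args=(pts, snout),
        bounds=([-np.inf, 1e-3, -np.inf], [np.inf, np.pi - 1e-3, np.inf]),
        method="trf",
        xtol=cfg.tol,
        ftol=cfg.tol,
        gtol=cfg.tol,
        max_nfev=cfg.max_iter * 3,
    )
    rho, theta, b = sol.x
    return WhiskerParams(
        rho=float(rho),
        theta=float(theta),
        b=float(b),
        length=length,
        rss=float(np.sum(sol.fun**2)),
        frame_index=frame_index,
        converged=bool(sol.success),
    )
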