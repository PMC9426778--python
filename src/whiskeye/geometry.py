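"""Geometric fits: video keypoints -> whisker angles and normalized pupil positions.

The stages are: a hue-masked, luma-weighted centroid for whisker tracking
on raw frames; an algebraic circle fit converting whisker positions to
polar angles; a direct conic ellipse fit for the pupil; parabola fits to
the eyelids whose intersections define the eye corners and the eye-width
segment onto which pupil positions are projected and normalized.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import FitError, GeometryError

__all__ = [
    "CircleFit",
    "EllipseFit",
    "EyeGeometry",
    "hue_centroid",
    "fit_circle",
    "to_polar_angle",
    "fit_ellipse",
    "fit_parabola",
    "fit_eye_geometry",
    "normalize_pupil",
]


# ---------------------------------------------------------------------------
# hue-masked centroid


def hue_centroid(frame, hue_window, min_pixels: int = 1):
    """Luma-weighted centroid of pixels whose hue lies in ``hue_window``.

    ``frame`` is an RGB array of shape (rows, cols, 3) with values in [0, 1].
    ``hue_window`` is (lo, hi) on the [0, 1) hue circle; lo > hi wraps around.
    Returns (x, y) = (column, row) as floats, or ``None`` when fewer than
    ``min_pixels`` pixels fall inside the window.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.size == 0:
        raise FitError("empty image")
    if frame.ndim != 3 or frame.shape[2] != 3:
        raise FitError("expected an RGB image of shape (rows, cols, 3)")
    r, g, b = frame[..., 0], frame[..., 1], frame[..., 2]
    maxc = frame.max(axis=2)
    minc = frame.min(axis=2)
    delta = maxc - minc
    hue = np.zeros_like(maxc)
    nz = delta > 0
    rc = np.where(nz, (maxc - r) / np.where(nz, delta, 1.0), 0.0)
    gc = np.where(nz, (maxc - g) / np.where(nz, delta, 1.0), 0.0)
    bc = np.where(nz, (maxc - b) / np.where(nz, delta, 1.0), 0.0)
    hue = np.where(maxc == r, bc - gc, np.where(maxc == g, 2.0 + rc - bc, 4.0 + gc - rc))
    hue = (hue / 6.0) % 1.0
    hue[~nz] = 0.0
    lo, hi = hue_window
    if lo <= hi:
        mask = nz & (hue >= lo) & (hue <= hi)
    else:  # window wraps around the hue circle
        mask = nz & ((hue >= lo) | (hue <= hi))
    if int(mask.sum()) < min_pixels:
        return None
    # Rec.601 luma weighting
    luma = 0.299 * r + 0.587 * g + 0.114 * b
    w = luma[mask]
    if w.sum() <= 0:
        return None
    rows, cols = np.nonzero(mask)
    x = float(np.sum(cols * w) / np.sum(w))
    y = float(np.sum(rows * w) / np.sum(w))
    return (x, y)


# ---------------------------------------------------------------------------
# circle fit (whiskers)


@dataclass(frozen=True)
class CircleFit:
    center: tuple[float, float]
    radius: float
    residual: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise FitError("circle radius must be positive")
        if self.residual < 0:
            raise FitError("residual must be non-negative")


def fit_circle(points) -> CircleFit:
    """Algebraic (Kasa) least-squares circle through >=3 non-collinear points."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise FitError("fit_circle requires >=3 2D points")
    x, y = pts[:, 0], pts[:, 1]
    a = np.column_stack([x, y, np.ones_like(x)])
    rhs = x**2 + y**2
    # collinearity check on centered coordinates
    centered = pts - pts.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-9 * max(1.0, np.abs(centered).max())) < 2:
        raise FitError("points are collinear; no unique circle")
    sol, *_ = np.linalg.lstsq(a, rhs, rcond=None)
    cx, cy = sol[0] / 2.0, sol[1] / 2.0
    r2 = sol[2] + cx**2 + cy**2
    if r2 <= 0:
        raise FitError("degenerate circle fit")
    r = float(np.sqrt(r2))
    dist = np.hypot(x - cx, y - cy)
    residual = float(np.sqrt(np.mean((dist - r) ** 2)))
    return CircleFit((float(cx), float(cy)), r, residual)


def to_polar_angle(position, fit: CircleFit, protraction_sign: float = 1.0) -> float:
    """Polar angle (degrees) of a point about the fitted circle center.

    ``protraction_sign`` flips the axis so that increasing angle always
    means protraction regardless of which side of the face the whisker is on.
    """
    x, y = position
    cx, cy = fit.center
    ang = np.degrees(np.arctan2(y - cy, x - cx))
    return float(protraction_sign * ang)


# ---------------------------------------------------------------------------
# ellipse fit (pupil)


@dataclass(frozen=True)
class EllipseFit:
    center: tuple[float, float]
    semi_axes: tuple[float, float]  # (major, minor)
    orientation: float  # radians, angle of the major axis
    residual: float

    def __post_init__(self) -> None:
        if min(self.semi_axes) <= 0:
            raise FitError("ellipse semi-axes must be positive")

    @property
    def major_diameter(self) -> float:
        return 2.0 * self.semi_axes[0]

    @property
    def minor_diameter(self) -> float:
        return 2.0 * self.semi_axes[1]

    @property
    def equivalent_diameter(self) -> float:
        """Diameter of the circle with the same area."""
        return 2.0 * float(np.sqrt(self.semi_axes[0] * self.semi_axes[1]))


def fit_ellipse(points) -> EllipseFit:
    """Direct least-squares conic fit constrained to an ellipse.

    Uses the numerically stable partitioning of the ellipse-specific
    constraint (4AC - B^2 = 1).  Requires >=5 points in non-degenerate
    position; raises :class:`FitError` otherwise.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 5:
        raise FitError("fit_ellipse requires >=5 2D points")
    # centre and scale for conditioning
    mean = pts.mean(axis=0)
    scale = np.abs(pts - mean).max()
    if scale <= 0:
        raise FitError("all points coincide")
    x, y = ((pts - mean) / scale).T
    d1 = np.column_stack([x**2, x * y, y**2])
    d2 = np.column_stack([x, y, np.ones_like(x)])
    s1 = d1.T @ d1
    s2 = d1.T @ d2
    s3 = d2.T @ d2
    try:
        t = -np.linalg.solve(s3, s2.T)
    except np.linalg.LinAlgError as exc:
        raise FitError("degenerate point configuration for ellipse fit") from exc
    m = s1 + s2 @ t
    c1inv = np.array([[0.0, 0.0, 0.5], [0.0, -1.0, 0.0], [0.5, 0.0, 0.0]])
    m = c1inv @ m
    eigval, eigvec = np.linalg.eig(m)
    cond = 4.0 * eigvec[0] * eigvec[2] - eigvec[1] ** 2
    valid = np.where(np.isreal(eigval) & (cond > 0))[0]
    if len(valid) == 0:
        raise FitError("no elliptical solution for these points")
    a1 = np.real(eigvec[:, valid[0]])
    coeffs = np.concatenate([a1, t @ a1])  # A,B,C,D,E,F in scaled frame
    if coeffs[0] + coeffs[2] < 0:  # fix overall conic sign so A + C > 0
        coeffs = -coeffs
    A, B, C, D, E, F = coeffs
    disc = B**2 - 4 * A * C
    if disc >= 0:
        raise FitError("fitted conic is not an ellipse")
    # conic -> geometric parameters (scaled frame)
    cx = (2 * C * D - B * E) / disc
    cy = (2 * A * E - B * D) / disc
    num = 2 * (A * E**2 + C * D**2 + F * B**2 - B * D * E - 4 * A * C * F)
    s = np.sqrt((A - C) ** 2 + B**2)
    with np.errstate(invalid="raise"):
        try:
            ax1 = float(-np.sqrt(num * ((A + C) + s)) / disc)
            ax2 = float(-np.sqrt(num * ((A + C) - s)) / disc)
        except FloatingPointError as exc:
            raise FitError("degenerate ellipse geometry") from exc
    if B == 0:
        theta = 0.0 if A <= C else np.pi / 2
    else:
        theta = 0.5 * np.arctan2(-B, C - A)  # major-axis angle (A + C > 0)
    semi = sorted([ax1, ax2], reverse=True)
    center = (float(cx * scale + mean[0]), float(cy * scale + mean[1]))
    semi_axes = (semi[0] * scale, semi[1] * scale)
    residual = _ellipse_radial_residual(pts, center, semi_axes, theta)
    return EllipseFit(center, semi_axes, float(theta % np.pi), residual)


def _ellipse_radial_residual(pts, center, semi_axes, theta) -> float:
    """RMS radial distance from points to the ellipse along rays from center.

    Exactly zero iff all points lie on the ellipse.
    """
    d = pts - np.asarray(center)
    rot = np.array([[np.cos(theta), np.sin(theta)], [-np.sin(theta), np.cos(theta)]])
    u = d @ rot.T
    a, b = semi_axes
    r_pt = np.hypot(u[:, 0], u[:, 1])
    phi = np.arctan2(u[:, 1], u[:, 0])
    r_el = (a * b) / np.sqrt((b * np.cos(phi)) ** 2 + (a * np.sin(phi)) ** 2)
    return float(np.sqrt(np.mean((r_pt - r_el) ** 2)))


# ---------------------------------------------------------------------------
# eyelid parabolas, eye corners, pupil normalization


@dataclass(frozen=True)
class EyeGeometry:
    """Fitted eyelid parabolas and the eye-width segment they define.

    ``corners`` is ordered (nasal, temporal); normalized pupil position is
    0 at the nasal corner and 1 at the temporal corner.
    """

    top_parabola: tuple[float, float, float]  # y = a x^2 + b x + c
    bottom_parabola: tuple[float, float, float]
    corners: tuple[tuple[float, float], tuple[float, float]]
    width: float

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise GeometryError("eye width must be positive")


def fit_parabola(points) -> tuple[float, float, float]:
    """Least-squares parabola y = a x^2 + b x + c; needs >=3 distinct x."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise FitError("fit_parabola requires >=3 2D points")
    if len(np.unique(pts[:, 0])) < 3:
        raise FitError("fit_parabola requires >=3 distinct x values")
    a, b, c = np.polyfit(pts[:, 0], pts[:, 1], 2)
    return (float(a), float(b), float(c))


def fit_eye_geometry(top_points, bottom_points, nasal: str = "low_x") -> EyeGeometry:
    """Fit both eyelid parabolas and compute the eye corners.

    The corners are the real intersection points of the two parabolas;
    ``nasal`` ("low_x" or "high_x") selects which corner is nasal so that
    the normalized axis can be mapped into head-centered coordinates.
    """
    if nasal not in ("low_x", "high_x"):
        raise GeometryError(f"nasal must be 'low_x' or 'high_x', got {nasal!r}")
    top = fit_parabola(top_points)
    bottom = fit_parabola(bottom_points)
    da, db, dc = (top[0] - bottom[0], top[1] - bottom[1], top[2] - bottom[2])
    tol = 1e-12 * max(1.0, *(abs(v) for v in top + bottom))
    if abs(da) < tol and abs(db) < tol:
        raise GeometryError("eyelid parabolas are parallel or coincident")
    if abs(da) < tol:
        raise GeometryError("eyelid parabolas cross only once; no eye-width segment")
    disc = db * db - 4 * da * dc
    if disc <= 0:
        raise GeometryError("eyelid parabolas do not cross at two points")
    sq = np.sqrt(disc)
    x1 = (-db - sq) / (2 * da)
    x2 = (-db + sq) / (2 * da)
    xs = sorted([x1, x2])
    pts = [(float(x), float(top[0] * x * x + top[1] * x + top[2])) for x in xs]
    if nasal == "low_x":
        nasal_pt, temporal_pt = pts[0], pts[1]
    else:
        nasal_pt, temporal_pt = pts[1], pts[0]
    width = float(np.hypot(temporal_pt[0] - nasal_pt[0], temporal_pt[1] - nasal_pt[1]))
    return EyeGeometry(top, bottom, (nasal_pt, temporal_pt), width)


def normalize_pupil(position, geometry: EyeGeometry) -> float:
    """Project a pupil center onto the eye-width segment; fraction of width.

    0 at the nasal corner, 1 at the temporal corner; not clamped, so values
    outside [0, 1] indicate a pupil beyond the corners.
    """
    p = np.asarray(position, dtype=float)
    nasal = np.asarray(geometry.corners[0])
    temporal = np.asarray(geometry.corners[1])
    v = temporal - nasal
    return float(np.dot(p - nasal, v) / np.dot(v, v))
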