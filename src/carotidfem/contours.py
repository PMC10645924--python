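"""Planar cross-sectional contours and per-branch contour stacks.

The reconstruction procedure is contour-driven: every surface is cut by
evenly spaced planes perpendicular to a branch axis, processed as closed
planar polygons, and lofted back.  This module holds the polygon
primitives (area, centroid, resampling, polar parameterization, periodic
B-spline smoothing) and the :class:`ContourStack` container with its
plain-text serialization.

Polygons are ``(n, 2)`` float arrays of vertices in plane coordinates
(mm), implicitly closed (last vertex connects back to the first) and
oriented counter-clockwise.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline

__all__ = [
    "BranchFrame",
    "ContourStack",
    "polygon_area",
    "polygon_centroid",
    "ensure_ccw",
    "equivalent_radius",
    "resample_closed",
    "polar_radii",
    "polygon_from_polar",
    "is_simple_polygon",
    "smooth_closed_polygon",
]


def polygon_area(poly: np.ndarray) -> float:
    """Signed area by the shoelace formula (positive for CCW)."""
    x, y = poly[:, 0], poly[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def polygon_centroid(poly: np.ndarray) -> np.ndarray:
    """Area centroid of a simple closed polygon."""
    x, y = poly[:, 0], poly[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    a = 0.5 * np.sum(cross)
    if abs(a) < 1e-14:
        return poly.mean(axis=0)
    cx = np.sum((x + xn) * cross) / (6.0 * a)
    cy = np.sum((y + yn) * cross) / (6.0 * a)
    return np.array([cx, cy])


def ensure_ccw(poly: np.ndarray) -> np.ndarray:
    return poly if polygon_area(poly) >= 0 else poly[::-1].copy()


def equivalent_radius(poly: np.ndarray) -> float:
    """Radius of the circle with the polygon's area, sqrt(A / pi)."""
    return float(np.sqrt(abs(polygon_area(poly)) / np.pi))


def is_simple_polygon(poly: np.ndarray) -> bool:
    """True if no two non-adjacent edges intersect (O(n^2) segment test)."""
    n = len(poly)
    p = poly
    q = np.roll(poly, -1, axis=0)
    for i in range(n):
        for j in range(i + 1, n):
            if j == i or (j + 1) % n == i or (i + 1) % n == j:
                continue
            if _segments_intersect(p[i], q[i], p[j], q[j]):
                return False
    return True


def _segments_intersect(a, b, c, d) -> bool:
    def orient(p, q, r):
        return (q[0] - p[0]) * (r[1] - p[1]) - (q[1] - p[1]) * (r[0] - p[0])

    o1, o2 = orient(a, b, c), orient(a, b, d)
    o3, o4 = orient(c, d, a), orient(c, d, b)
    return (o1 * o2 < 0) and (o3 * o4 < 0)


def resample_closed(poly: np.ndarray, n: int) -> np.ndarray:
    """Resample a closed polygon to ``n`` vertices by arc length."""
    pts = np.vstack([poly, poly[:1]])
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total <= 0:
        return np.repeat(poly[:1], n, axis=0)
    t = np.linspace(0.0, total, n, endpoint=False)
    x = np.interp(t, s, pts[:, 0])
    y = np.interp(t, s, pts[:, 1])
    return np.column_stack([x, y])


def polar_radii(poly: np.ndarray, n_theta: int, center: np.ndarray | None = None):
    """Radii of a star-shaped polygon at ``n_theta`` uniform angles.

    The polygon boundary is intersected with rays from ``center`` (area
    centroid by default).  Sections in this workflow (lumen slices,
    convex merged curves, outer-wall curves) are star-shaped about their
    centroid; for a non-star-shaped input the outermost crossing is
    taken, which convexifies the hidden parts.

    Returns ``(radii, center)`` with ``radii`` of shape ``(n_theta,)`` at
    angles ``2*pi*j/n_theta``.
    """
    poly = ensure_ccw(np.asarray(poly, dtype=float))
    if center is None:
        center = polygon_centroid(poly)
    rel = poly - center
    ang = np.mod(np.arctan2(rel[:, 1], rel[:, 0]), 2 * np.pi)
    rad = np.linalg.norm(rel, axis=1)
    order = np.argsort(ang, kind="stable")
    ang_s = ang[order]
    rad_s = rad[order]
    # wrap for periodic interpolation
    ang_ext = np.concatenate([ang_s - 2 * np.pi, ang_s, ang_s + 2 * np.pi])
    rad_ext = np.concatenate([rad_s, rad_s, rad_s])
    theta = 2 * np.pi * np.arange(n_theta) / n_theta
    radii = np.interp(theta, ang_ext, rad_ext)
    return radii, center


def polygon_from_polar(radii: np.ndarray, center=(0.0, 0.0)) -> np.ndarray:
    n = len(radii)
    theta = 2 * np.pi * np.arange(n) / n
    return np.column_stack(
        [center[0] + radii * np.cos(theta), center[1] + radii * np.sin(theta)]
    )


def _periodic_bspline_design(t: np.ndarray, n_control: int) -> np.ndarray:
    """Design matrix of a periodic cubic B-spline with ``n_control`` coefficients.

    Parameter ``t`` in [0, 1); basis functions are uniform cubic B-splines
    wrapped around the period.
    """
    k = 3
    # uniform knots over one period, extended for wrap-around evaluation
    knots = np.arange(-k, n_control + k + 1) / n_control
    design = np.zeros((len(t), n_control))
    for j in range(-k, n_control + k):
        c = np.zeros(len(knots) - k - 1)
        idx = j + k
        if 0 <= idx < len(c):
            c[idx] = 1.0
        b = BSpline(knots, c, k, extrapolate=False)
        vals = b(t)
        vals = np.nan_to_num(vals)
        design[:, j % n_control] += vals
    return design


def smooth_closed_polygon(
    poly: np.ndarray, n_control: int = 16, n_out: int | None = None
) -> np.ndarray:
    """Least-squares periodic cubic B-spline rebuild of a closed polygon.

    The rational weights of a true NURBS curve are not needed here: the
    curve rebuild only has to smooth segmentation jaggedness, so a
    (non-rational) periodic cubic B-spline fit by least squares over the
    arc-length parameter is used.  If the smoothed curve self-intersects,
    the fit is retried with more control points; a still-intersecting
    result raises ``ValueError``.
    """
    if n_control < 4:
        raise ValueError("n_control must be >= 4")
    poly = ensure_ccw(np.asarray(poly, dtype=float))
    if n_out is None:
        n_out = len(poly)
    pts = np.vstack([poly, poly[:1]])
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    t = (s[:-1] / s[-1]) if s[-1] > 0 else np.linspace(0, 1, len(poly), endpoint=False)

    for nc in (n_control, 2 * n_control, 4 * n_control):
        nc = min(nc, max(4, len(poly) - 1))
        design = _periodic_bspline_design(t, nc)
        coef, *_ = np.linalg.lstsq(design, poly, rcond=None)
        t_out = np.linspace(0.0, 1.0, n_out, endpoint=False)
        out = _periodic_bspline_design(t_out, nc) @ coef
        if is_simple_polygon(out):
            return ensure_ccw(out)
        if nc >= len(poly) - 1:
            break
    raise ValueError("smoothed contour self-intersects even at maximum control count")


@dataclass
class BranchFrame:
    """Orthonormal frame of a straight branch axis.

    Points on the plane at axial station ``s`` are
    ``origin + s*axis + x*u + y*v``.
    """

    origin: np.ndarray
    axis: np.ndarray
    u: np.ndarray = None
    v: np.ndarray = None

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float)
        self.axis = np.asarray(self.axis, dtype=float)
        self.axis = self.axis / np.linalg.norm(self.axis)
        if self.u is None:
            ref = np.array([1.0, 0.0, 0.0])
            if abs(self.axis @ ref) > 0.9:
                ref = np.array([0.0, 1.0, 0.0])
            u = ref - (ref @ self.axis) * self.axis
            self.u = u / np.linalg.norm(u)
        else:
            self.u = np.asarray(self.u, dtype=float)
        if self.v is None:
            self.v = np.cross(self.axis, self.u)
        else:
            self.v = np.asarray(self.v, dtype=float)

    def to_world(self, station: float, xy: np.ndarray) -> np.ndarray:
        xy = np.atleast_2d(xy)
        return (
            self.origin
            + station * self.axis
            + xy[:, :1] * self.u
            + xy[:, 1:2] * self.v
        )

    def to_plane(self, points: np.ndarray):
        """Project world points to (station, x, y) coordinates."""
        rel = np.atleast_2d(points) - self.origin
        return rel @ self.axis, rel @ self.u, rel @ self.v


@dataclass
class ContourStack:
    """Ordered closed contours per branch at increasing axial stations."""

    frames: dict[str, BranchFrame]
    stations: dict[str, np.ndarray] = field(default_factory=dict)
    polygons: dict[str, list[np.ndarray]] = field(default_factory=dict)
    spacing: float = 0.5

    def add(self, branch: str, station: float, polygon: np.ndarray):
        self.stations.setdefault(branch, np.array([]))
        self.polygons.setdefault(branch, [])
        self.stations[branch] = np.append(self.stations[branch], station)
        self.polygons[branch].append(ensure_ccw(np.asarray(polygon, dtype=float)))

    def branches(self):
        return [b for b in self.polygons if len(self.polygons[b]) > 0]

    def validate(self):
        for b in self.branches():
            s = self.stations[b]
            if np.any(np.diff(s) <= 0):
                raise ValueError(f"stations not strictly increasing on branch {b}")

    # -- plain-text serialization ------------------------------------
    # One record per contour:
    #   > branch=<name> station=<mm> n=<vertex count>
    #   x y          (one vertex per line, mm, plane coordinates)
    def dumps(self) -> str:
        out = io.StringIO()
        out.write(f"# carotidfem contour stack, spacing={self.spacing}\n")
        for b in self.branches():
            f = self.frames[b]
            out.write(
                "@ branch=%s origin=%s axis=%s u=%s v=%s\n"
                % (
                    b,
                    ",".join(f"{x:.9g}" for x in f.origin),
                    ",".join(f"{x:.9g}" for x in f.axis),
                    ",".join(f"{x:.9g}" for x in f.u),
                    ",".join(f"{x:.9g}" for x in f.v),
                )
            )
            for s, poly in zip(self.stations[b], self.polygons[b]):
                out.write(f"> branch={b} station={s:.9g} n={len(poly)}\n")
                for x, y in poly:
                    out.write(f"{x:.9g} {y:.9g}\n")
        return out.getvalue()

    @classmethod
    def loads(cls, text: str, spacing: float = 0.5) -> "ContourStack":
        frames: dict[str, BranchFrame] = {}
        stack = None
        branch = None
        verts: list[list[float]] = []
        pending = None

        def flush():
            if pending is not None and verts:
                stack.add(pending[0], pending[1], np.array(verts))

        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("@"):
                kv = dict(tok.split("=", 1) for tok in line[1:].split())
                frames[kv["branch"]] = BranchFrame(
                    origin=np.array([float(x) for x in kv["origin"].split(",")]),
                    axis=np.array([float(x) for x in kv["axis"].split(",")]),
                    u=np.array([float(x) for x in kv["u"].split(",")]),
                    v=np.array([float(x) for x in kv["v"].split(",")]),
                )
                if stack is None:
                    stack = cls(frames=frames, spacing=spacing)
                continue
            if line.startswith(">"):
                flush()
                verts = []
                kv = dict(tok.split("=", 1) for tok in line[1:].split())
                branch = kv["branch"]
                pending = (branch, float(kv["station"]))
                continue
            verts.append([float(t) for t in line.split()])
        if stack is None:
            stack = cls(frames=frames, spacing=spacing)
        flush()
        return stack
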