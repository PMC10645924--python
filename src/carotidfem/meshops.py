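"""Surface-mesh construction and interrogation helpers.

All surfaces are ``trimesh.Trimesh`` objects in mm.  Solids built here
are watertight by construction: lofted skins over corresponding contour
rings with planar cap fans, annular (two-ring) lofts for wall-like
solids, and marching-cubes extraction of smooth level sets for general
Boolean-shaped regions (the route used instead of fragile 3D mesh
Booleans: Boolean logic is applied to 2D sections or analytic radii, and
the resulting signed field is contoured).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely
import trimesh
from skimage.measure import marching_cubes

from .contours import BranchFrame

__all__ = [
    "make_mesh",
    "empty_mesh",
    "is_watertight",
    "loft_rings",
    "annular_loft",
    "slice_mesh",
    "chain_segments",
    "solid_from_level_set",
    "region_stack_solid",
    "PolarTube",
    "smooth_max",
    "union_level_set",
    "tube_union_solid",
    "laplacian_smooth_local",
]


def make_mesh(vertices, faces, name: str | None = None) -> trimesh.Trimesh:
    """Build a Trimesh without automatic processing; orient outward.

    Face winding is flipped wholesale if the enclosed volume comes out
    negative, so watertight inputs always report positive volume.
    """
    mesh = trimesh.Trimesh(
        vertices=np.asarray(vertices, dtype=float),
        faces=np.asarray(faces, dtype=np.int64),
        process=False,
    )
    if mesh.is_watertight and mesh.volume < 0:
        mesh.invert()
    if name:
        mesh.metadata["name"] = name
    return mesh


def empty_mesh(name: str | None = None) -> trimesh.Trimesh:
    return make_mesh(np.zeros((0, 3)), np.zeros((0, 3), dtype=int), name=name)


def is_watertight(mesh: trimesh.Trimesh) -> bool:
    """Edge-manifold check: every edge shared by exactly two faces."""
    if mesh is None or len(mesh.faces) == 0:
        return False
    return bool(mesh.is_watertight and mesh.is_winding_consistent)


def loft_rings(rings, cap: bool = True, name: str | None = None) -> trimesh.Trimesh:
    """Skin a tube over ordered corresponding vertex rings.

    ``rings``: sequence of (M, 3) arrays with identical M and matched
    vertex correspondence.  With ``cap`` the ends are closed by triangle
    fans to the ring centroid, giving a watertight solid.
    """
    rings = [np.asarray(r, dtype=float) for r in rings]
    m = len(rings[0])
    if any(len(r) != m for r in rings):
        raise ValueError("all rings must have the same vertex count")
    n = len(rings)
    verts = np.vstack(rings)
    faces = []
    for i in range(n - 1):
        base0, base1 = i * m, (i + 1) * m
        j = np.arange(m)
        jn = (j + 1) % m
        faces.append(np.column_stack([base0 + j, base0 + jn, base1 + j]))
        faces.append(np.column_stack([base0 + jn, base1 + jn, base1 + j]))
    faces = np.vstack(faces)
    if cap:
        c0 = rings[0].mean(axis=0)
        c1 = rings[-1].mean(axis=0)
        i0, i1 = len(verts), len(verts) + 1
        verts = np.vstack([verts, c0[None], c1[None]])
        j = np.arange(m)
        jn = (j + 1) % m
        cap0 = np.column_stack([np.full(m, i0), jn, j])
        cap1 = np.column_stack([np.full(m, i1), (n - 1) * m + j, (n - 1) * m + jn])
        faces = np.vstack([faces, cap0, cap1])
    return make_mesh(verts, faces, name=name)


def annular_loft(inner_rings, outer_rings, name: str | None = None) -> trimesh.Trimesh:
    """Watertight solid between two corresponding ring stacks.

    Outer skin wound outward, inner skin inward, and quad-strip annular
    caps joining the first and last ring pairs.  This is the boundary of
    "outer minus inner" for tube-like solids without any 3D Boolean.
    """
    inner = [np.asarray(r, dtype=float) for r in inner_rings]
    outer = [np.asarray(r, dtype=float) for r in outer_rings]
    if len(inner) != len(outer):
        raise ValueError("ring stacks must have equal station counts")
    m = len(inner[0])
    n = len(inner)
    vi = np.vstack(inner)
    vo = np.vstack(outer)
    verts = np.vstack([vo, vi])
    off = n * m
    faces = []
    j = np.arange(m)
    jn = (j + 1) % m
    for i in range(n - 1):
        a0, a1 = i * m, (i + 1) * m
        # outer skin
        faces.append(np.column_stack([a0 + j, a0 + jn, a1 + j]))
        faces.append(np.column_stack([a0 + jn, a1 + jn, a1 + j]))
        # inner skin, reversed winding
        b0, b1 = off + i * m, off + (i + 1) * m
        faces.append(np.column_stack([b0 + jn, b0 + j, b1 + j]))
        faces.append(np.column_stack([b1 + jn, b0 + jn, b1 + j]))
    # caps: first station (outer ring 0 <-> inner ring 0)
    faces.append(np.column_stack([jn, j, off + j]))
    faces.append(np.column_stack([jn, off + j, off + jn]))
    e = (n - 1) * m
    faces.append(np.column_stack([e + j, e + jn, off + e + j]))
    faces.append(np.column_stack([e + jn, off + e + jn, off + e + j]))
    return make_mesh(verts, np.vstack(faces), name=name)


def chain_segments(segments: np.ndarray, tol: float = 1e-6):
    """Chain unordered 2-point segments into closed loops.

    ``segments``: (n, 2, k) endpoints.  Returns list of (m, k) loops
    (implicitly closed).  Open chains (from tangent planes) are dropped.
    """
    if len(segments) == 0:
        return []
    pts = segments.reshape(-1, segments.shape[2])
    key = np.round(pts / tol).astype(np.int64)
    _, inverse = np.unique(key, axis=0, return_inverse=True)
    ends = inverse.reshape(-1, 2)
    adj: dict[int, list[int]] = {}
    for si, (a, b) in enumerate(ends):
        adj.setdefault(a, []).append(si)
        adj.setdefault(b, []).append(si)
    used = np.zeros(len(segments), dtype=bool)
    loops = []
    for start in range(len(segments)):
        if used[start]:
            continue
        used[start] = True
        a, b = ends[start]
        loop_nodes = [a, b]
        cur = b
        closed = False
        while True:
            nxt_seg = None
            for si in adj.get(cur, []):
                if not used[si]:
                    nxt_seg = si
                    break
            if nxt_seg is None:
                break
            used[nxt_seg] = True
            x, y = ends[nxt_seg]
            cur = y if x == cur else x
            if cur == loop_nodes[0]:
                closed = True
                break
            loop_nodes.append(cur)
        if closed and len(loop_nodes) >= 3:
            # map node ids back to coordinates (first occurrence)
            coord = np.empty((len(loop_nodes), segments.shape[2]))
            first = {}
            for si, (a2, b2) in enumerate(ends):
                first.setdefault(a2, segments[si, 0])
                first.setdefault(b2, segments[si, 1])
            for i, nid in enumerate(loop_nodes):
                coord[i] = first[nid]
            loops.append(coord)
    return loops


def slice_mesh(mesh: trimesh.Trimesh, frame: BranchFrame, station: float,
               min_area: float = 1e-3):
    """Closed intersection polygons of a mesh with one cross-sectional plane.

    Returns a list of (m, 2) CCW polygons in the frame's plane
    coordinates.  Near-zero-area loops (plane tangent to the surface)
    are dropped.
    """
    from .contours import ensure_ccw, polygon_area

    origin = frame.origin + station * frame.axis
    segs = trimesh.intersections.mesh_plane(mesh, frame.axis, origin)
    if len(segs) == 0:
        return []
    loops3 = chain_segments(np.asarray(segs))
    out = []
    for loop in loops3:
        rel = loop - origin
        xy = np.column_stack([rel @ frame.u, rel @ frame.v])
        if abs(polygon_area(xy)) < min_area:
            continue
        out.append(ensure_ccw(xy))
    return out


def solid_from_level_set(
    phi: np.ndarray,
    origin: np.ndarray,
    pitch: float,
    name: str | None = None,
    keep_largest: bool = False,
) -> trimesh.Trimesh:
    """Marching-cubes surface of the region ``phi > 0`` on a regular grid.

    Duplicate vertices are welded and degenerate faces dropped so the
    result is edge-manifold.  ``keep_largest`` discards satellite
    bubbles (tiny disconnected bodies near grid-resolution tangencies).
    """
    if phi.max() <= 0:
        return empty_mesh(name)
    verts, faces, _, _ = marching_cubes(phi, level=0.0, spacing=(pitch,) * 3)
    mesh = make_mesh(verts + np.asarray(origin)[None, :], faces, name=name)
    mesh.merge_vertices(digits_vertex=7)
    mesh.update_faces(mesh.nondegenerate_faces())
    if keep_largest and mesh.body_count > 1:
        bodies = mesh.split(only_watertight=False)
        mesh = max(bodies, key=lambda b: abs(b.volume))
        mesh = make_mesh(mesh.vertices, mesh.faces, name=name)
    if mesh.is_watertight and mesh.volume < 0:
        mesh.invert()
    return mesh


def _region_signed_distance(region, x: np.ndarray, y: np.ndarray, far: float) -> np.ndarray:
    """Signed in-plane distance to a shapely region (positive inside)."""
    if region is None or region.is_empty:
        return np.full(x.shape, -far)
    pts = shapely.points(x.ravel(), y.ravel())
    d = shapely.distance(pts, region.boundary).reshape(x.shape)
    inside = shapely.contains_xy(region, x.ravel(), y.ravel()).reshape(x.shape)
    return np.where(inside, d, -d)


def region_stack_solid(
    frame: BranchFrame,
    stations: np.ndarray,
    regions,
    pitch: float = 0.15,
    name: str | None = None,
) -> trimesh.Trimesh:
    """Watertight solid swept through per-station planar regions.

    ``regions`` is a list of shapely geometries (or None) aligned with
    ``stations``.  A 3D level set is built by linear interpolation of
    per-station signed-distance fields and contoured with marching
    cubes; the solid is capped flat at the first and last stations.
    Empty everywhere returns an empty mesh.
    """
    stations = np.asarray(stations, dtype=float)
    live = [i for i, r in enumerate(regions) if r is not None and not r.is_empty]
    if not live:
        return empty_mesh(name)
    bounds = shapely.total_bounds([regions[i] for i in live])
    margin = 3 * pitch
    x0, y0, x1, y1 = bounds[0] - margin, bounds[1] - margin, bounds[2] + margin, bounds[3] + margin
    s0, s1 = stations[live[0]], stations[live[-1]]
    z0, z1 = s0 - margin, s1 + margin
    nx = max(4, int(np.ceil((x1 - x0) / pitch)) + 1)
    ny = max(4, int(np.ceil((y1 - y0) / pitch)) + 1)
    nz = max(4, int(np.ceil((z1 - z0) / pitch)) + 1)
    xs = x0 + pitch * np.arange(nx)
    ys = y0 + pitch * np.arange(ny)
    zs = z0 + pitch * np.arange(nz)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    far = 10 * pitch + max(x1 - x0, y1 - y0)
    dfields = np.stack(
        [_region_signed_distance(r, X, Y, far) for r in regions], axis=0
    )
    phi = np.empty((nz, nx, ny))
    for k, z in enumerate(zs):
        if z <= stations[0]:
            dpl = dfields[0]
        elif z >= stations[-1]:
            dpl = dfields[-1]
        else:
            i = int(np.searchsorted(stations, z, side="right") - 1)
            i = min(i, len(stations) - 2)
            lam = (z - stations[i]) / (stations[i + 1] - stations[i])
            dpl = (1 - lam) * dfields[i] + lam * dfields[i + 1]
        phi[k] = np.minimum(dpl, np.minimum(z - s0, s1 - z))
    # grid order (z, x, y) -> world mapping via frame
    mesh_local = solid_from_level_set(phi, origin=np.zeros(3), pitch=pitch, name=name)
    if len(mesh_local.faces) == 0:
        return mesh_local
    v = mesh_local.vertices
    zw = z0 + v[:, 0]
    xw = x0 + v[:, 1]
    yw = y0 + v[:, 2]
    world = (
        frame.origin[None, :]
        + zw[:, None] * frame.axis[None, :]
        + xw[:, None] * frame.u[None, :]
        + yw[:, None] * frame.v[None, :]
    )
    out = make_mesh(world, mesh_local.faces, name=name)
    if out.is_watertight and out.volume < 0:
        out.invert()
    return out


@dataclass
class PolarTube:
    """Star-shaped tube about a straight branch axis.

    ``radii[i, j]`` is the section radius at station ``stations[i]`` and
    angle ``2*pi*j/n_theta`` measured in the frame's (u, v) plane about
    the per-station section center ``centers[i]`` (the axis by default).
    """

    frame: BranchFrame
    stations: np.ndarray
    radii: np.ndarray
    centers: np.ndarray | None = None

    def __post_init__(self):
        self.stations = np.asarray(self.stations, dtype=float)
        self.radii = np.asarray(self.radii, dtype=float)
        if self.centers is None:
            self.centers = np.zeros((len(self.stations), 2))
        else:
            self.centers = np.asarray(self.centers, dtype=float)

    def center_at(self, s: np.ndarray) -> np.ndarray:
        s = np.clip(s, self.stations[0], self.stations[-1])
        cx = np.interp(s, self.stations, self.centers[:, 0])
        cy = np.interp(s, self.stations, self.centers[:, 1])
        return np.column_stack([cx, cy])

    def radius_at(self, s: np.ndarray, theta: np.ndarray) -> np.ndarray:
        """Bilinear interpolation in (station, angle), periodic in angle."""
        stations = self.stations
        r = self.radii
        n_theta = r.shape[1]
        s = np.clip(s, stations[0], stations[-1])
        i = np.clip(np.searchsorted(stations, s, side="right") - 1, 0, len(stations) - 2)
        lam = (s - stations[i]) / (stations[i + 1] - stations[i])
        tpos = np.mod(theta, 2 * np.pi) / (2 * np.pi) * n_theta
        j = np.floor(tpos).astype(int) % n_theta
        jn = (j + 1) % n_theta
        mu = tpos - np.floor(tpos)
        r0 = (1 - mu) * r[i, j] + mu * r[i, jn]
        r1 = (1 - mu) * r[i + 1, j] + mu * r[i + 1, jn]
        return (1 - lam) * r0 + lam * r1

    def level_set(self, points: np.ndarray) -> np.ndarray:
        """Signed field, positive inside the capped tube solid."""
        s, x, y = self.frame.to_plane(points)
        c = self.center_at(s)
        dx, dy = x - c[:, 0], y - c[:, 1]
        r = np.hypot(dx, dy)
        theta = np.arctan2(dy, dx)
        body = self.radius_at(s, theta) - r
        return np.minimum(body, np.minimum(s - self.stations[0], self.stations[-1] - s))

    def rings(self):
        n_theta = self.radii.shape[1]
        theta = 2 * np.pi * np.arange(n_theta) / n_theta
        out = []
        for s, rr, c in zip(self.stations, self.radii, self.centers):
            xy = np.column_stack(
                [c[0] + rr * np.cos(theta), c[1] + rr * np.sin(theta)]
            )
            out.append(self.frame.to_world(s, xy))
        return out

    def loft(self, name: str | None = None) -> trimesh.Trimesh:
        return loft_rings(self.rings(), cap=True, name=name)


def smooth_max(a: np.ndarray, b: np.ndarray, blend: float) -> np.ndarray:
    """Polynomial smooth maximum with blend width ``blend``.

    Equals ``max(a, b)`` wherever |a - b| >= blend; near-coincident
    fields are lifted by at most ``blend/4``, which rounds tangency
    creases so marching cubes cannot pinch where two surfaces graze.
    """
    if blend <= 0:
        return np.maximum(a, b)
    h = np.clip(blend - np.abs(a - b), 0.0, None)
    return np.maximum(a, b) + h * h / (4.0 * blend)


def union_level_set(tubes, points: np.ndarray, blend: float = 0.15) -> np.ndarray:
    """Smooth-max union of polar-tube level sets at the given points."""
    phi = tubes[0].level_set(points)
    for t in tubes[1:]:
        phi = smooth_max(phi, t.level_set(points), blend)
    return phi


def tube_union_solid(
    tubes, pitch: float = 0.2, name: str | None = None, blend: float = 0.15
) -> trimesh.Trimesh:
    """Union of capped polar tubes via their combined level set.

    The field of each tube is exact (analytic radii interpolation), the
    union is a smooth maximum (see :func:`smooth_max`), and the surface
    is extracted with marching cubes -- the counterpart of a CAD Boolean
    union for the bifurcated vessel.
    """
    mins, maxs = [], []
    for t in tubes:
        v = np.vstack(t.rings())
        mins.append(v.min(axis=0))
        maxs.append(v.max(axis=0))
    lo = np.min(mins, axis=0) - 3 * pitch
    hi = np.max(maxs, axis=0) + 3 * pitch
    ns = np.maximum(4, np.ceil((hi - lo) / pitch).astype(int) + 1)
    xs = [lo[k] + pitch * np.arange(ns[k]) for k in range(3)]
    X, Y, Z = np.meshgrid(*xs, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    phi = union_level_set(tubes, pts, blend).reshape(X.shape)
    return solid_from_level_set(phi, origin=lo, pitch=pitch, name=name, keep_largest=True)


def laplacian_smooth_local(
    mesh: trimesh.Trimesh,
    center: np.ndarray,
    radius: float,
    iterations: int = 10,
    lam: float = 0.5,
) -> trimesh.Trimesh:
    """Laplacian-smooth vertices within a sphere; the fillet stand-in.

    Smoothing strength fades linearly from the sphere center to its
    boundary so the blend joins the untouched surface continuously.
    """
    v = mesh.vertices.copy()
    edges = mesh.edges_unique
    d = np.linalg.norm(v - np.asarray(center)[None, :], axis=1)
    w = np.clip(1.0 - d / radius, 0.0, 1.0) * lam
    if not np.any(w > 0):
        return mesh
    n = len(v)
    for _ in range(iterations):
        acc = np.zeros_like(v)
        cnt = np.zeros(n)
        np.add.at(acc, edges[:, 0], v[edges[:, 1]])
        np.add.at(acc, edges[:, 1], v[edges[:, 0]])
        np.add.at(cnt, edges[:, 0], 1)
        np.add.at(cnt, edges[:, 1], 1)
        avg = acc / np.maximum(cnt, 1)[:, None]
        v = v + w[:, None] * (avg - v)
    return make_mesh(v, mesh.faces, name=mesh.metadata.get("name"))
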