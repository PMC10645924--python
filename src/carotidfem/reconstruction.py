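"""Semi-automatic CAD-style reconstruction of the vessel wall.

Turns a segmented stenotic lumen surface plus calcific/lipid plaque
component surfaces into:

i.   the wall inner surface (smoothed loft of the lumen sections),
ii.  the wall outer surface (per-section convex-hull merge of lumen and
     plaque contours, radially enlarged to the ideal outer radius, with
     narrowed sections removed and re-interpolated),
iii. the atherosclerotic wall solid (outer minus inner),
iv.  the fibrous plaque component (healthy lumen minus stenotic lumen
     minus the other components), where the healthy lumen is the
     shrink-back of the outer wall sections.

All Booleans are evaluated per cross-sectional plane as 2D polygon
operations and the results are re-lofted (or contoured from an
interpolated planar level set), which mirrors the contour-driven
construction and avoids 3D mesh Booleans.

The ideal outer wall radius of a branch is its distal inner equivalent
radius increased by 30%; the CCA, for which the rule gives no direct
radius, uses the larger of the ICA/ECA values.  The healthy lumen
applies the inverse rule (division by the same factor).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import shapely
import trimesh

from .contours import (
    BranchFrame,
    ContourStack,
    ensure_ccw,
    equivalent_radius,
    polar_radii,
    polygon_centroid,
    smooth_closed_polygon,
)
from .meshops import (
    PolarTube,
    annular_loft,
    empty_mesh,
    laplacian_smooth_local,
    loft_rings,
    region_stack_solid,
    slice_mesh,
    tube_union_solid,
)
from .synthetic import Branch, CenterlineSet

log = logging.getLogger(__name__)

ENLARGEMENT_FACTOR = 1.3  # outer wall radius = distal inner radius * 1.3

__all__ = [
    "WallModel",
    "plaque_hull",
    "slice_contours",
    "rebuild_smooth",
    "merge_lumen_plaque",
    "enlarge_section",
    "drop_narrowed_sections",
    "loft_branch",
    "build_wall_solid",
    "build_healthy_lumen",
    "build_fibrous_component",
    "reconstruct_wall",
]


@dataclass
class WallModel:
    """Product of the reconstruction procedure (all meshes in mm)."""

    inner: trimesh.Trimesh
    outer: trimesh.Trimesh
    wall_solid: trimesh.Trimesh
    fibrous: trimesh.Trimesh
    healthy_lumen: trimesh.Trimesh
    inner_stack: ContourStack | None = None
    outer_stack: ContourStack | None = None
    healthy_stack: ContourStack | None = None
    targets: dict[str, float] = field(default_factory=dict)
    narrowed: dict[str, list[int]] = field(default_factory=dict)


def plaque_hull(components) -> trimesh.Trimesh:
    """Single convex surface enclosing all plaque components (quickhull).

    Raises on degenerate (coplanar) input.
    """
    if not components:
        raise ValueError("at least one plaque component required")
    pts = np.vstack([np.asarray(c.vertices) for c in components])
    hull = trimesh.convex.convex_hull(pts)
    if hull.volume < 1e-9:
        raise ValueError(
            "plaque component vertices are (nearly) coplanar; convex hull "
            "has no volume"
        )
    hull.metadata["name"] = "plaque_hull"
    return hull


def _axis_pierce_point(frame: BranchFrame, station: float, other: Branch):
    """In-plane point where another branch axis pierces this plane, or None."""
    n = frame.axis
    origin = frame.origin + station * n
    denom = other.direction @ n
    if abs(denom) < 1e-9:
        return None
    t = ((origin - other.origin) @ n) / denom
    if t < -1e-9 or t > other.length + 1e-9:
        return None
    p = other.origin + t * other.direction
    rel = p - origin
    return np.array([rel @ frame.u, rel @ frame.v])


def _clip_to_branch(poly: shapely.Polygon, other_xy: np.ndarray) -> shapely.Polygon:
    """Keep the part of a section on this branch's side of the bisector.

    ``other_xy`` is the in-plane pierce point of a neighbouring branch
    axis; the clip half-plane is the perpendicular bisector between it
    and the own axis at the in-plane origin.
    """
    d = np.linalg.norm(other_xy)
    if d < 1e-9:
        return poly
    n = other_xy / d
    mid = other_xy / 2.0
    t = np.array([-n[1], n[0]])
    big = 1e3
    half = shapely.Polygon(
        [
            mid + big * t,
            mid - big * t,
            mid - big * t - big * n,
            mid + big * t - big * n,
        ]
    )
    clipped = poly.intersection(half)
    if clipped.is_empty:
        return clipped
    if clipped.geom_type == "MultiPolygon":
        own = shapely.Point(0.0, 0.0)
        parts = [g for g in clipped.geoms]
        parts.sort(key=lambda g: g.distance(own))
        return parts[0]
    return clipped


def _section_polygon(surface, branch: Branch, others, station: float,
                     min_area: float = 1e-2):
    """Closed section of a surface owned by one branch at one station.

    The plane is perpendicular to the branch axis; only the loop
    enclosing the axis is kept and, where a neighbouring branch pierces
    the same plane inside that loop, the section is clipped to the
    bisector half-plane so each branch keeps its own side of the
    junction.  Returns an (m, 2) polygon or None.
    """
    frame = branch.frame
    loops = slice_mesh(surface, frame, station, min_area=min_area)
    own = shapely.Point(0.0, 0.0)
    poly = None
    for xy in loops:
        p = shapely.Polygon(xy)
        if p.is_valid and p.contains(own):
            poly = p
            break
    if poly is None:
        return None
    for other in others:
        pt = _axis_pierce_point(frame, station, other)
        if pt is not None and poly.contains(shapely.Point(pt)):
            poly = _clip_to_branch(poly, pt)
            if poly.is_empty or not poly.contains(own):
                return None
    xy = np.asarray(poly.exterior.coords)[:-1]
    return ensure_ccw(xy)


def slice_contours(
    surface: trimesh.Trimesh,
    centerlines: CenterlineSet,
    spacing: float = 0.5,
    margin: float = 0.1,
) -> ContourStack:
    """Cut a surface with evenly spaced planes along every branch axis.

    Sections are assigned to the branch whose axis they enclose;
    degenerate (near-zero-area) sections from tangent planes are
    dropped and logged.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    frames = {n: b.frame for n, b in centerlines.branches.items()}
    stack = ContourStack(frames=frames, spacing=spacing)
    for name in sorted(centerlines.branches):
        branch = centerlines.branches[name]
        others = [b for n, b in centerlines.branches.items() if n != name]
        span = branch.length - 2 * margin
        n_st = max(2, int(round(span / spacing)) + 1)
        stations = np.linspace(margin, branch.length - margin, n_st)
        for s in stations:
            poly = _section_polygon(surface, branch, others, s)
            if poly is None:
                log.debug("branch %s station %.2f: no usable section", name, s)
                continue
            stack.add(name, s, poly)
    stack.validate()
    return stack


def rebuild_smooth(polygon: np.ndarray, n_control: int = 16) -> np.ndarray:
    """Rebuild a section as a smooth periodic cubic spline curve."""
    return smooth_closed_polygon(polygon, n_control=n_control)


def merge_lumen_plaque(lumen_polygon: np.ndarray, plaque_polygons) -> np.ndarray:
    """Convex-hull merge of lumen and plaque sections into a single curve."""
    pts = [np.asarray(lumen_polygon)]
    pts += [np.asarray(p) for p in plaque_polygons]
    allpts = np.vstack(pts)
    hull = shapely.MultiPoint(allpts).convex_hull
    if hull.geom_type != "Polygon":
        raise ValueError("degenerate section: hull is not a polygon")
    return ensure_ccw(np.asarray(hull.exterior.coords)[:-1])


def enlarge_section(merged_polygon: np.ndarray, target_outer_radius: float):
    """Radially enlarge a merged section to the ideal outer radius.

    Vertices are scaled about the section area centroid so the
    equivalent radius sqrt(A/pi) matches ``target_outer_radius``; the
    plaque region stays enclosed because the scale is never below 1.
    Returns ``(polygon, narrowed)`` where ``narrowed`` is True when the
    target is smaller than the section's own equivalent radius (the
    section would have to shrink -- it is flagged for removal by
    :func:`drop_narrowed_sections`).
    """
    poly = ensure_ccw(np.asarray(merged_polygon, dtype=float))
    r_eq = equivalent_radius(poly)
    if r_eq <= 0:
        raise ValueError("degenerate section")
    narrowed = target_outer_radius < r_eq * (1.0 - 1e-9)
    scale = max(1.0, target_outer_radius / r_eq)
    c = polygon_centroid(poly)
    return c + scale * (poly - c), narrowed


def _station_radii(stack: ContourStack, branch: str) -> np.ndarray:
    return np.array([equivalent_radius(p) for p in stack.polygons[branch]])


def drop_narrowed_sections(
    stack: ContourStack,
    threshold: float = 0.98,
    flagged: dict[str, list[int]] | None = None,
) -> ContourStack:
    """Remove narrowed outer sections and re-interpolate the gaps.

    A station is narrowed when its outer equivalent radius falls below
    ``threshold`` times the linear interpolation between the nearest
    retained neighbours (or when it was flagged by the enlargement
    step).  Removed stations are refilled at the original spacing by
    per-vertex linear blending of the adjacent retained contours, which
    models the ideal physiological outer wall.  Idempotent.
    """
    out = ContourStack(frames=dict(stack.frames), spacing=stack.spacing)
    for b in stack.branches():
        s = np.asarray(stack.stations[b], dtype=float)
        polys = stack.polygons[b]
        n = len(polys)
        if n < 2:
            raise ValueError(f"branch {b}: fewer than 2 stations")
        keep = np.ones(n, dtype=bool)
        for i in (flagged or {}).get(b, []):
            if 0 < i < n - 1:
                keep[i] = False
        radii = _station_radii(stack, b)
        changed = True
        while changed:
            changed = False
            kept = np.where(keep)[0]
            if len(kept) < 2:
                raise ValueError(f"branch {b}: fewer than 2 retained stations")
            # leave-one-out: each interior retained station against the
            # line through its retained neighbours; worst offender first,
            # endpoints always retained
            ratio = np.full(n, np.inf)
            for pos in range(1, len(kept) - 1):
                i, i0, i1 = kept[pos], kept[pos - 1], kept[pos + 1]
                lam = (s[i] - s[i0]) / (s[i1] - s[i0])
                interp = (1 - lam) * radii[i0] + lam * radii[i1]
                ratio[i] = radii[i] / max(interp, 1e-12)
            i = int(np.argmin(ratio))
            if ratio[i] < threshold:
                keep[i] = False
                changed = True
        kept = np.where(keep)[0]
        # refill dropped stations by per-vertex blending (polar form)
        n_theta = max(len(p) for p in polys)
        polar = {}
        for i in kept:
            r, c = polar_radii(polys[i], n_theta)
            polar[i] = (r, c)
        for i in range(n):
            if keep[i]:
                out.add(b, s[i], polys[i])
                continue
            i0 = kept[kept < i].max()
            i1 = kept[kept > i].min()
            lam = (s[i] - s[i0]) / (s[i1] - s[i0])
            r = (1 - lam) * polar[i0][0] + lam * polar[i1][0]
            c = (1 - lam) * polar[i0][1] + lam * polar[i1][1]
            theta = 2 * np.pi * np.arange(n_theta) / n_theta
            out.add(
                b,
                s[i],
                np.column_stack(
                    [c[0] + r * np.cos(theta), c[1] + r * np.sin(theta)]
                ),
            )
    return out


def _stack_tubes(stack: ContourStack, n_theta: int = 72) -> dict[str, PolarTube]:
    tubes = {}
    for b in stack.branches():
        radii = []
        centers = []
        for p in stack.polygons[b]:
            r, c = polar_radii(p, n_theta)
            radii.append(r)
            centers.append(c)
        tubes[b] = PolarTube(
            frame=stack.frames[b],
            stations=np.asarray(stack.stations[b], dtype=float),
            radii=np.asarray(radii),
            centers=np.asarray(centers),
        )
    return tubes


def _find_apex(tubes: dict[str, PolarTube], centerlines: CenterlineSet):
    """Crotch point of the bifurcation: march along the ICA/ECA bisector
    from the bifurcation until the point leaves every branch tube."""
    bif = centerlines.bifurcation
    if bif is None or not {"ICA", "ECA"} <= set(tubes):
        return None
    d = (
        centerlines.branches["ICA"].direction
        + centerlines.branches["ECA"].direction
    )
    d = d / np.linalg.norm(d)
    for t in np.arange(0.0, 12.0, 0.1):
        p = bif + t * d
        if all(tube.level_set(p[None])[0] < 0 for tube in tubes.values()):
            return p
    return bif


def loft_branch(
    stack: ContourStack,
    centerlines: CenterlineSet | None = None,
    fillet_radius: float = 1.5,
    union_pitch: float = 0.2,
    name: str | None = None,
) -> trimesh.Trimesh:
    """Triangulated skin over the contour stack.

    A single branch is lofted directly (watertight, planar cap fans).
    Several branches are lofted as polar tubes, unioned through their
    combined level set, and blended at the bifurcation apex by local
    Laplacian smoothing within ``fillet_radius``.
    """
    stack.validate()
    branches = stack.branches()
    if not branches:
        raise ValueError("empty contour stack")
    for b in branches:
        if len(stack.polygons[b]) < 2:
            raise ValueError(f"branch {b}: need >= 2 contours to loft")
    if len(branches) == 1:
        b = branches[0]
        frame = stack.frames[b]
        n_theta = max(len(p) for p in stack.polygons[b])
        rings = []
        for s, p in zip(stack.stations[b], stack.polygons[b]):
            r, c = polar_radii(p, n_theta)
            theta = 2 * np.pi * np.arange(n_theta) / n_theta
            xy = np.column_stack(
                [c[0] + r * np.cos(theta), c[1] + r * np.sin(theta)]
            )
            rings.append(frame.to_world(s, xy))
        return loft_rings(rings, cap=True, name=name)
    tubes = _stack_tubes(stack)
    mesh = tube_union_solid(list(tubes.values()), pitch=union_pitch, name=name)
    if centerlines is not None and fillet_radius > 0:
        apex = _find_apex(tubes, centerlines)
        if apex is not None:
            mesh = laplacian_smooth_local(mesh, apex, fillet_radius)
    return mesh


def _infer_frames(mesh: trimesh.Trimesh) -> CenterlineSet:
    """Single straight axis through a tube-like mesh by PCA."""
    v = np.asarray(mesh.vertices)
    c = v.mean(axis=0)
    _, _, vt = np.linalg.svd(v - c, full_matrices=False)
    axis = vt[0]
    t = (v - c) @ axis
    origin = c + t.min() * axis
    r = float(np.median(np.linalg.norm((v - c) - np.outer((v - c) @ axis, axis), axis=1)))
    return CenterlineSet(
        {"CCA": Branch("CCA", origin, axis, float(t.max() - t.min()), max(r, 0.1))}
    )


def build_wall_solid(
    inner: trimesh.Trimesh,
    outer: trimesh.Trimesh,
    centerlines: CenterlineSet | None = None,
    spacing: float = 0.5,
    n_theta: int = 72,
    union_pitch: float = 0.2,
) -> trimesh.Trimesh:
    """Closed solid between the inner and outer wall surfaces.

    Sections of both surfaces are taken on shared planes; the inner
    section must be strictly inside the outer everywhere (violating
    stations are reported).  One branch gives an exact annular loft;
    several give the level-set difference of the polar tube stacks.
    """
    centerlines = centerlines or _infer_frames(inner)
    s_in = slice_contours(inner, centerlines, spacing, margin=0.15)
    s_out = slice_contours(outer, centerlines, spacing, margin=0.15)
    bad = []
    rings_in: dict[str, list] = {}
    rings_out: dict[str, list] = {}
    stations: dict[str, list] = {}
    for b in s_out.branches():
        for s, po in zip(s_out.stations[b], s_out.polygons[b]):
            i = np.argmin(np.abs(np.asarray(s_in.stations.get(b, [1e9])) - s))
            if abs(s_in.stations[b][i] - s) > spacing / 2:
                continue
            pi = s_in.polygons[b][i]
            ro, co = polar_radii(po, n_theta)
            # inner radii measured about the outer section centroid
            ri, _ = polar_radii(pi, n_theta, center=co)
            if np.any(ri >= ro):
                bad.append((b, float(s)))
                continue
            theta = 2 * np.pi * np.arange(n_theta) / n_theta
            frame = centerlines.branches[b].frame
            rings_in.setdefault(b, []).append(
                frame.to_world(s, np.column_stack(
                    [co[0] + ri * np.cos(theta), co[1] + ri * np.sin(theta)]))
            )
            rings_out.setdefault(b, []).append(
                frame.to_world(s, np.column_stack(
                    [co[0] + ro * np.cos(theta), co[1] + ro * np.sin(theta)]))
            )
            stations.setdefault(b, []).append(float(s))
    if bad:
        raise ValueError(f"inner surface not strictly inside outer at stations {bad}")
    if not rings_out:
        raise ValueError("no shared sections between inner and outer surfaces")
    if len(rings_out) == 1:
        (b,) = rings_out.keys()
        return annular_loft(rings_in[b], rings_out[b], name="wall")
    # multi-branch: level-set difference of outer union and inner union
    frames = {b: centerlines.branches[b].frame for b in rings_out}

    def tubes_from(rings_dict):
        tubes = []
        for b, rr in rings_dict.items():
            frame = frames[b]
            rad = []
            cen = []
            for ring in rr:
                srel, x, y = frame.to_plane(ring)
                c = np.array([x.mean(), y.mean()])
                rad.append(np.hypot(x - c[0], y - c[1]))
                cen.append(c)
            tubes.append(
                PolarTube(frame, np.asarray(stations[b]), np.asarray(rad), np.asarray(cen))
            )
        return tubes

    to = tubes_from(rings_out)
    ti = tubes_from(rings_in)
    # extend the inner field past the outer caps so the difference has a
    # clean annular end face instead of two coincident cap disks
    for t in ti:
        t.stations = np.concatenate(
            [[t.stations[0] - 1.0], t.stations, [t.stations[-1] + 1.0]]
        )
        t.radii = np.vstack([t.radii[:1], t.radii, t.radii[-1:]])
        t.centers = np.vstack([t.centers[:1], t.centers, t.centers[-1:]])
    mins = np.min([np.vstack(t.rings()).min(axis=0) for t in to], axis=0) - 3 * union_pitch
    maxs = np.max([np.vstack(t.rings()).max(axis=0) for t in to], axis=0) + 3 * union_pitch
    ns = np.maximum(4, np.ceil((maxs - mins) / union_pitch).astype(int) + 1)
    xs = [mins[k] + union_pitch * np.arange(ns[k]) for k in range(3)]
    X, Y, Z = np.meshgrid(*xs, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    from .meshops import solid_from_level_set, union_level_set

    phi_o = union_level_set(to, pts)
    phi_i = union_level_set(ti, pts)
    phi = np.minimum(phi_o, -phi_i).reshape(X.shape)
    return solid_from_level_set(phi, mins, union_pitch, name="wall", keep_largest=True)


def build_healthy_lumen(
    outer_stack: ContourStack,
    factor: float = ENLARGEMENT_FACTOR,
    centerlines: CenterlineSet | None = None,
    union_pitch: float = 0.2,
    centers: dict[str, np.ndarray] | None = None,
) -> trimesh.Trimesh:
    """Healthy lumen: shrink-back of the outer wall sections.

    Each outer contour is scaled by ``1/factor`` -- the inverse of the
    enlargement rule -- and the sections are lofted.  The scaling
    center defaults to the outer section centroid; passing the lumen
    section centroids instead keeps the healthy lumen centered on the
    vessel where an eccentric plaque bulge shifts the merged outer
    centroid sideways.
    """
    shrunk = _scale_stack(outer_stack, 1.0 / factor, centers=centers)
    return loft_branch(shrunk, centerlines=centerlines, union_pitch=union_pitch,
                       name="healthy_lumen")


def _scale_stack(
    stack: ContourStack,
    scale: float,
    centers: dict[str, np.ndarray] | None = None,
) -> ContourStack:
    out = ContourStack(frames=dict(stack.frames), spacing=stack.spacing)
    for b in stack.branches():
        for i, (s, p) in enumerate(zip(stack.stations[b], stack.polygons[b])):
            c = polygon_centroid(p)
            if centers is not None and b in centers:
                target_c = centers[b][i]
            else:
                target_c = c
            out.add(b, s, target_c + scale * (p - c))
    return out


def build_fibrous_component(
    healthy_lumen: trimesh.Trimesh,
    stenotic_lumen: trimesh.Trimesh,
    other_components,
    centerlines: CenterlineSet | None = None,
    spacing: float = 0.5,
    pitch: float = 0.12,
    opening_tol: float = 0.08,
) -> trimesh.Trimesh:
    """Fibrous plaque solid: healthy minus stenotic lumen minus components.

    Per-plane 2D differences; a morphological opening with radius
    ``opening_tol`` removes tolerance-scale shells where the two lumina
    nearly coincide (healthy sections), so only the true stenotic gap
    survives.  Empty result (no stenosis) is allowed.
    """
    centerlines = centerlines or _infer_frames(stenotic_lumen)
    parts = []
    for name in sorted(centerlines.branches):
        branch = centerlines.branches[name]
        others = [b for n, b in centerlines.branches.items() if n != name]
        stations = np.arange(0.25, branch.length - 0.1, spacing)
        regions = []
        live = 0
        for s in stations:
            ph = _section_polygon(healthy_lumen, branch, others, s)
            pst = _section_polygon(stenotic_lumen, branch, others, s)
            if ph is None or pst is None:
                regions.append(None)
                continue
            region = shapely.Polygon(ph).difference(shapely.Polygon(pst))
            region = region.buffer(-opening_tol).buffer(opening_tol)
            for comp in other_components:
                for cp in slice_mesh(comp, branch.frame, s, min_area=1e-3):
                    region = region.difference(shapely.Polygon(cp))
            region = shapely.make_valid(region)
            if region.is_empty or region.area < 0.05:
                regions.append(None)
            else:
                regions.append(region)
                live += 1
        if live >= 2:
            mesh = region_stack_solid(
                branch.frame, stations, regions, pitch=pitch, name="fibrous"
            )
            if len(mesh.faces) > 0:
                parts.append(mesh)
    if not parts:
        return empty_mesh("fibrous")
    if len(parts) == 1:
        return parts[0]
    out = trimesh.util.concatenate(parts)
    out.metadata["name"] = "fibrous"
    return out


def reconstruct_wall(
    lumen: trimesh.Trimesh,
    components,
    centerlines: CenterlineSet,
    spacing: float = 0.5,
    n_control: int = 16,
    narrowing_threshold: float = 0.98,
    enlargement: float = ENLARGEMENT_FACTOR,
    fillet_radius: float = 1.5,
    union_pitch: float = 0.2,
    fibrous_pitch: float = 0.12,
) -> WallModel:
    """Run the full reconstruction procedure.

    Returns the wall model with inner/outer surfaces, wall solid,
    healthy lumen and fibrous component, plus the contour stacks used.
    """
    hull = plaque_hull(components) if components else None
    lumen_stack = slice_contours(lumen, centerlines, spacing)

    # smooth the lumen sections -> inner wall stack
    inner_stack = ContourStack(frames=dict(lumen_stack.frames), spacing=spacing)
    for b in lumen_stack.branches():
        for s, p in zip(lumen_stack.stations[b], lumen_stack.polygons[b]):
            try:
                smoothed = rebuild_smooth(p, n_control=n_control)
            except ValueError:
                # clipped junction slivers can defeat the spline fit;
                # fall back to the arc-length resampled raw section
                log.info("branch %s station %.2f: smoothing rejected, "
                         "using raw section", b, s)
                from .contours import resample_closed

                smoothed = resample_closed(p, max(len(p), 32))
            inner_stack.add(b, s, smoothed)

    # distal inner equivalent radii set the per-branch outer targets
    distal: dict[str, float] = {}
    for b in inner_stack.branches():
        distal[b] = equivalent_radius(inner_stack.polygons[b][-1])
    targets: dict[str, float] = {}
    for b in inner_stack.branches():
        if b == "CCA" and ("ICA" in distal or "ECA" in distal):
            ref = max(distal.get("ICA", 0.0), distal.get("ECA", 0.0))
        else:
            ref = distal[b]
        targets[b] = enlargement * ref

    # merged + enlarged outer sections
    merged_stack = ContourStack(frames=dict(inner_stack.frames), spacing=spacing)
    flagged: dict[str, list[int]] = {}
    for b in inner_stack.branches():
        branch = centerlines.branches[b]
        for i, (s, p) in enumerate(
            zip(inner_stack.stations[b], inner_stack.polygons[b])
        ):
            plaque_polys = []
            if hull is not None:
                plaque_polys = slice_mesh(hull, branch.frame, s, min_area=1e-3)
            merged = merge_lumen_plaque(p, plaque_polys)
            outer_poly, narrowed = enlarge_section(merged, targets[b])
            merged_stack.add(b, s, outer_poly)
            if narrowed:
                flagged.setdefault(b, []).append(i)
                log.info("branch %s station %.2f flagged as narrowed", b, s)
    outer_stack = drop_narrowed_sections(
        merged_stack, threshold=narrowing_threshold, flagged=flagged
    )

    multi = len(inner_stack.branches()) > 1
    cl = centerlines if multi else None
    inner = loft_branch(inner_stack, centerlines=cl, fillet_radius=fillet_radius,
                        union_pitch=union_pitch, name="inner")
    outer = loft_branch(outer_stack, centerlines=cl, fillet_radius=fillet_radius,
                        union_pitch=union_pitch, name="outer")
    inner_centers = {
        b: np.array([polygon_centroid(p) for p in inner_stack.polygons[b]])
        for b in inner_stack.branches()
    }
    healthy_stack = _scale_stack(outer_stack, 1.0 / enlargement, centers=inner_centers)
    healthy = loft_branch(healthy_stack, centerlines=cl, fillet_radius=fillet_radius,
                          union_pitch=union_pitch, name="healthy_lumen")
    wall = build_wall_solid(inner, outer, centerlines=centerlines, spacing=spacing,
                            union_pitch=union_pitch)
    fibrous = build_fibrous_component(
        healthy, inner, components, centerlines=centerlines,
        spacing=spacing, pitch=fibrous_pitch,
    )
    return WallModel(
        inner=inner,
        outer=outer,
        wall_solid=wall,
        fibrous=fibrous,
        healthy_lumen=healthy,
        inner_stack=inner_stack,
        outer_stack=outer_stack,
        healthy_stack=healthy_stack,
        targets=targets,
        narrowed=flagged,
    )
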