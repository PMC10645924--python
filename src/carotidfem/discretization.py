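"""Tetrahedral discretization of the wall solid.

Two meshers are provided:

* :func:`structured_wall_mesh` -- a structured (station, angle, radial
  layer) hex grid between the inner and outer wall contour tubes, split
  into 6 tetrahedra per cell (Kuhn/Freudenthal, face-conforming).  Exact
  boundary representation and good element quality; used for tube-like
  wall solids and the pressure-vessel verification fixtures.  Local
  refinement is axial: stations are spaced at the local size inside the
  plaque span and at the global size outside it, while the angular and
  radial resolution follow the local size throughout.

* :func:`tetrahedralize` -- a background-grid Delaunay mesher for
  arbitrary watertight solids: jittered interior lattice points (two
  nested lattices when a plaque refinement region is given) plus
  even surface samples, Delaunay-triangulated, keeping tetrahedra whose
  centroid lies inside the solid.

Element subsets are assigned with the minimum-distance-vector rule: for
each element the minimum distance vector to the nearest triangle of a
component surface is compared with that triangle's outward normal; the
element belongs to the component when the two oppose (the element
centroid is on the inner side).  Overlaps resolve by priority
calcific > lipid > fibrous; unclaimed elements are healthy wall.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh
from scipy.spatial import Delaunay

from .meshops import PolarTube, is_watertight
from .spatial import nearest_on_surface, points_in_mesh

SUBSETS = ("wall", "fibrous", "lipid", "calcific")
BOUNDARY_TAGS = ("outer", "lumen", "cca_end", "ica_end", "eca_end")

__all__ = [
    "SUBSETS",
    "BOUNDARY_TAGS",
    "TetMesh",
    "tet_volumes",
    "structured_wall_mesh",
    "tube_wall_mesh",
    "tetrahedralize",
    "assign_subsets",
    "tag_boundary",
]


def tet_volumes(nodes: np.ndarray, tets: np.ndarray) -> np.ndarray:
    a = nodes[tets[:, 1]] - nodes[tets[:, 0]]
    b = nodes[tets[:, 2]] - nodes[tets[:, 0]]
    c = nodes[tets[:, 3]] - nodes[tets[:, 0]]
    return np.einsum("ij,ij->i", np.cross(a, b), c) / 6.0


@dataclass
class TetMesh:
    """4-node tetrahedral mesh with subset labels and boundary tags.

    ``labels[e]`` indexes :data:`SUBSETS`; ``boundary_tags[f]`` indexes
    :data:`BOUNDARY_TAGS` for the boundary triangle ``boundary_faces[f]``.
    """

    nodes: np.ndarray
    tets: np.ndarray
    labels: np.ndarray = None
    boundary_faces: np.ndarray = None
    boundary_tags: np.ndarray = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.tets = np.asarray(self.tets, dtype=np.int64)
        vols = tet_volumes(self.nodes, self.tets)
        flip = vols < 0
        if np.any(flip):
            self.tets[flip] = self.tets[flip][:, [0, 1, 3, 2]]
        if self.labels is None:
            self.labels = np.zeros(len(self.tets), dtype=np.int8)
        if self.boundary_faces is None:
            self.boundary_faces, self.boundary_tags = self._find_boundary()

    def _find_boundary(self):
        faces = np.vstack(
            [
                self.tets[:, [1, 2, 3]],
                self.tets[:, [0, 3, 2]],
                self.tets[:, [0, 1, 3]],
                self.tets[:, [0, 2, 1]],
            ]
        )
        key = np.sort(faces, axis=1)
        _, idx, counts = np.unique(key, axis=0, return_index=True, return_counts=True)
        boundary = faces[idx[counts == 1]]
        return boundary, np.zeros(len(boundary), dtype=np.int8)

    @property
    def volumes(self) -> np.ndarray:
        return tet_volumes(self.nodes, self.tets)

    @property
    def centroids(self) -> np.ndarray:
        return self.nodes[self.tets].mean(axis=1)

    def subset_volume(self, name: str) -> float:
        return float(self.volumes[self.labels == SUBSETS.index(name)].sum())

    def tagged_faces(self, tag: str) -> np.ndarray:
        return self.boundary_faces[self.boundary_tags == BOUNDARY_TAGS.index(tag)]

    def validate(self):
        v = self.volumes
        if np.any(v <= 0):
            raise ValueError(f"{int((v <= 0).sum())} non-positive element volumes")
        if len(self.labels) != len(self.tets):
            raise ValueError("label/element count mismatch")

    # -- writers ------------------------------------------------------
    def save_vtk(self, path: str | Path):
        """Legacy ASCII VTK unstructured grid with labels as cell data."""
        path = Path(path)
        with path.open("w") as f:
            f.write("# vtk DataFile Version 3.0\ncarotidfem tet mesh\nASCII\n")
            f.write("DATASET UNSTRUCTURED_GRID\n")
            f.write(f"POINTS {len(self.nodes)} double\n")
            for p in self.nodes:
                f.write(f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g}\n")
            f.write(f"CELLS {len(self.tets)} {5 * len(self.tets)}\n")
            for t in self.tets:
                f.write(f"4 {t[0]} {t[1]} {t[2]} {t[3]}\n")
            f.write(f"CELL_TYPES {len(self.tets)}\n")
            f.write("\n".join(["10"] * len(self.tets)) + "\n")
            f.write(f"CELL_DATA {len(self.tets)}\n")
            f.write("SCALARS subset int 1\nLOOKUP_TABLE default\n")
            f.write("\n".join(str(int(x)) for x in self.labels) + "\n")

    def save_gmsh(self, path: str | Path):
        """Gmsh 2.2 ASCII: tets tagged by subset, boundary tris by tag."""
        path = Path(path)
        with path.open("w") as f:
            f.write("$MeshFormat\n2.2 0 8\n$EndMeshFormat\n$Nodes\n")
            f.write(f"{len(self.nodes)}\n")
            for i, p in enumerate(self.nodes, 1):
                f.write(f"{i} {p[0]:.9g} {p[1]:.9g} {p[2]:.9g}\n")
            f.write("$EndNodes\n$Elements\n")
            f.write(f"{len(self.tets) + len(self.boundary_faces)}\n")
            eid = 1
            for face, tag in zip(self.boundary_faces, self.boundary_tags):
                f.write(
                    f"{eid} 2 2 {int(tag)} {int(tag)} "
                    f"{face[0]+1} {face[1]+1} {face[2]+1}\n"
                )
                eid += 1
            for t, lab in zip(self.tets, self.labels):
                f.write(
                    f"{eid} 4 2 {int(lab)} {int(lab)} "
                    f"{t[0]+1} {t[1]+1} {t[2]+1} {t[3]+1}\n"
                )
                eid += 1
            f.write("$EndElements\n")


# Kuhn 6-tet split of a hex given corner ids c[bx][by][bz]; every path
# from c000 to c111 along the axes gives one tet -> face-conforming
# across a structured grid.
_PERMS = [(0, 1, 2), (0, 2, 1), (1, 0, 2), (1, 2, 0), (2, 0, 1), (2, 1, 0)]


def _hex_to_tets(corner_ids: np.ndarray) -> np.ndarray:
    """corner_ids: (n, 2, 2, 2) node ids -> (6n, 4) tets."""
    n = corner_ids.shape[0]
    out = np.empty((6 * n, 4), dtype=np.int64)
    for p, perm in enumerate(_PERMS):
        bits = np.zeros((4, 3), dtype=int)
        for step in range(3):
            bits[step + 1] = bits[step]
            bits[step + 1, perm[step]] = 1
        cols = [corner_ids[:, b[0], b[1], b[2]] for b in bits]
        out[p * n : (p + 1) * n] = np.column_stack(cols)
    return out


def _graded_stations(s0: float, s1: float, global_size: float,
                     local_size: float, span) -> np.ndarray:
    """Axial stations at local size inside ``span``, global size outside."""
    out = [s0]
    s = s0
    while s < s1 - 1e-9:
        step = global_size
        if span is not None and (span[0] - global_size) <= s <= span[1]:
            step = local_size
        s = min(s + step, s1)
        out.append(s)
    return np.array(out)


def structured_wall_mesh(
    inner: PolarTube,
    outer: PolarTube,
    global_size: float = 0.8,
    local_size: float = 0.3,
    plaque_span: tuple[float, float] | None = None,
    end_tags: tuple[str, str] = ("cca_end", "ica_end"),
) -> TetMesh:
    """Structured tet mesh of the wall between two polar contour tubes.

    Boundary facets are tagged by construction: the inner skin is the
    ``lumen`` load surface, the first/last stations are the constrained
    end planes, the outer skin is ``outer``.
    """
    if not (0 < local_size <= global_size):
        raise ValueError("need 0 < local_size <= global_size")
    s0 = max(inner.stations[0], outer.stations[0])
    s1 = min(inner.stations[-1], outer.stations[-1])
    stations = _graded_stations(s0, s1, global_size, local_size, plaque_span)
    r_mid = float(np.mean(outer.radii))
    n_theta = max(12, int(np.ceil(2 * np.pi * r_mid / local_size)))
    thickness = float(np.mean(outer.radii) - np.mean(inner.radii))
    n_r = max(2, int(round(thickness / local_size)))
    theta = 2 * np.pi * np.arange(n_theta) / n_theta

    nz = len(stations)
    nodes = np.empty((nz, n_theta, n_r + 1, 3))
    frame = inner.frame
    for i, s in enumerate(stations):
        sv = np.full(n_theta, s)
        a = inner.radius_at(sv, theta)
        b = outer.radius_at(sv, theta)
        ca = inner.center_at(sv)[0]
        cb = outer.center_at(sv)[0]
        for k in range(n_r + 1):
            f = k / n_r
            r = a + (b - a) * f
            c = ca + (cb - ca) * f
            xy = np.column_stack(
                [c[0] + r * np.cos(theta), c[1] + r * np.sin(theta)]
            )
            nodes[i, :, k] = frame.to_world(s, xy)
    node_id = np.arange(nz * n_theta * (n_r + 1)).reshape(nz, n_theta, n_r + 1)

    i = np.arange(nz - 1)
    j = np.arange(n_theta)
    k = np.arange(n_r)
    I, J, K = np.meshgrid(i, j, k, indexing="ij")
    I, J, K = I.ravel(), J.ravel(), K.ravel()
    Jn = (J + 1) % n_theta
    corners = np.empty((len(I), 2, 2, 2), dtype=np.int64)
    for bi in (0, 1):
        for bj in (0, 1):
            for bk in (0, 1):
                jj = np.where(bj == 0, J, Jn)
                corners[:, bi, bj, bk] = node_id[I + bi, jj, K + bk]
    tets = _hex_to_tets(corners)
    mesh = TetMesh(nodes=nodes.reshape(-1, 3), tets=tets)

    # tag boundary facets geometrically (all nodes share the feature)
    nid = mesh.boundary_faces
    coords = mesh.nodes
    k_of = np.tile(np.arange(n_r + 1), nz * n_theta).reshape(nz, n_theta, n_r + 1)
    i_of = np.repeat(np.arange(nz), n_theta * (n_r + 1)).reshape(nz, n_theta, n_r + 1)
    k_flat = k_of.ravel()
    i_flat = i_of.ravel()
    tags = np.zeros(len(nid), dtype=np.int8)
    on_inner = np.all(k_flat[nid] == 0, axis=1)
    on_outer = np.all(k_flat[nid] == n_r, axis=1)
    on_lo = np.all(i_flat[nid] == 0, axis=1)
    on_hi = np.all(i_flat[nid] == nz - 1, axis=1)
    tags[on_outer] = BOUNDARY_TAGS.index("outer")
    tags[on_inner] = BOUNDARY_TAGS.index("lumen")
    tags[on_lo] = BOUNDARY_TAGS.index(end_tags[0])
    tags[on_hi] = BOUNDARY_TAGS.index(end_tags[1])
    mesh.boundary_tags = tags
    mesh.metadata.update(
        {
            "n_theta": n_theta,
            "n_r": n_r,
            "stations": stations,
            "frame": frame,
            "end_planes": {
                end_tags[0]: (frame.to_world(stations[0], np.zeros((1, 2)))[0], -frame.axis),
                end_tags[1]: (frame.to_world(stations[-1], np.zeros((1, 2)))[0], frame.axis),
            },
        }
    )
    mesh.validate()
    return mesh


def tube_wall_mesh(a: float, b: float, length: float, size: float = 0.3) -> TetMesh:
    """Thick-walled cylinder fixture (inner radius a, outer b, along z)."""
    from .contours import BranchFrame

    frame = BranchFrame(origin=[0.0, 0.0, 0.0], axis=[0.0, 0.0, 1.0])
    stations = np.linspace(0.0, length, max(2, int(round(length / size)) + 1))
    n_theta = max(12, int(np.ceil(np.pi * (a + b) / size)))
    inner = PolarTube(frame, stations, np.full((len(stations), n_theta), a))
    outer = PolarTube(frame, stations, np.full((len(stations), n_theta), b))
    return structured_wall_mesh(inner, outer, global_size=size, local_size=size)


def tetrahedralize(
    solid: trimesh.Trimesh,
    global_size: float = 0.8,
    local_size: float | None = None,
    plaque_region: trimesh.Trimesh | None = None,
    seed: int = 0,
    dilation: float = 1.0,
) -> TetMesh:
    """Background-grid Delaunay mesh of a watertight solid.

    Interior lattice points (spacing ``global_size``, jittered) are
    combined with even surface samples; inside the ``dilation``-expanded
    bounding box of ``plaque_region`` a finer lattice at ``local_size``
    replaces the coarse one.  Tetrahedra of the Delaunay triangulation
    are kept when their centroid lies inside the solid.
    """
    if not is_watertight(solid):
        raise ValueError("solid must be watertight")
    local_size = local_size or global_size
    if not (0 < local_size <= global_size):
        raise ValueError("need 0 < local_size <= global_size")
    rng = np.random.default_rng(seed)
    lo, hi = solid.bounds
    box = None
    if plaque_region is not None and len(plaque_region.vertices):
        blo, bhi = plaque_region.bounds
        box = (blo - dilation, bhi + dilation)

    def lattice(step, lo, hi):
        axes = [np.arange(lo[d] + step / 2, hi[d], step) for d in range(3)]
        X, Y, Z = np.meshgrid(*axes, indexing="ij")
        pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
        return pts + rng.uniform(-0.1 * step, 0.1 * step, pts.shape)

    pts = lattice(global_size, lo, hi)
    if box is not None:
        inside_box = np.all((pts > box[0]) & (pts < box[1]), axis=1)
        pts = pts[~inside_box]
        fine = lattice(local_size, np.maximum(box[0], lo), np.minimum(box[1], hi))
        pts = np.vstack([pts, fine])
    # keep interior points clear of the surface to avoid slivers
    inside = points_in_mesh(solid, pts)
    pts = pts[inside]
    d, _, _ = nearest_on_surface(solid, pts)
    step_of = np.full(len(pts), global_size)
    if box is not None:
        step_of[np.all((pts > box[0]) & (pts < box[1]), axis=1)] = local_size
    pts = pts[d > 0.35 * step_of]

    def surface_points(mesh, step):
        n = max(64, int(np.ceil(3.0 * mesh.area / step**2)))
        s, _ = trimesh.sample.sample_surface_even(mesh, n, seed=int(seed) + 1)
        return s

    surf = [surface_points(solid, global_size), np.asarray(solid.vertices)]
    if box is not None:
        fine_s = surface_points(solid, local_size)
        keep = np.all((fine_s > box[0]) & (fine_s < box[1]), axis=1)
        surf.append(fine_s[keep])
    points = np.vstack([pts] + surf)

    tri = Delaunay(points)
    tets = tri.simplices
    cent = points[tets].mean(axis=1)
    keep = points_in_mesh(solid, cent)
    tets = tets[keep]
    vols = np.abs(tet_volumes(points, tets))
    tets = tets[vols > 1e-6]
    used = np.unique(tets)
    remap = np.full(len(points), -1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    mesh = TetMesh(nodes=points[used], tets=remap[tets])
    mesh.validate()
    return mesh


def assign_subsets(
    mesh: TetMesh,
    component_surfaces: dict[str, trimesh.Trimesh],
    priority: tuple[str, ...] = ("calcific", "lipid", "fibrous"),
) -> TetMesh:
    """Label elements by the minimum-distance-vector rule.

    For each element centroid the nearest triangle of a component
    surface is found; the element is inside the component when the
    minimum distance vector (centroid to closest surface point) has the
    same direction as the triangle's outward normal, i.e. the vector
    *from* the surface to the centroid opposes the normal.  Lower
    priority never overwrites higher.  Surfaces must be watertight and
    outward-oriented.
    """
    cent = mesh.centroids
    labels = np.zeros(len(cent), dtype=np.int8)  # wall
    for name in reversed(priority):
        surf = component_surfaces.get(name)
        if surf is None or len(surf.faces) == 0:
            continue
        if not is_watertight(surf):
            raise ValueError(f"component surface {name!r} is not watertight")
        # centroids outside the surface bounding box cannot be inside
        lo, hi = surf.bounds
        near = np.all((cent >= lo) & (cent <= hi), axis=1)
        if not np.any(near):
            continue
        d, closest, tri_idx = nearest_on_surface(surf, cent[near])
        normals = np.asarray(surf.face_normals)[tri_idx]
        to_surface = closest - cent[near]  # the minimum distance vector
        inside = np.einsum("ij,ij->i", to_surface, normals) > 0.0
        sub = labels[near]
        sub[inside] = SUBSETS.index(name)
        labels[near] = sub
    mesh.labels = labels
    return mesh


def tag_boundary(
    mesh: TetMesh,
    stenotic_lumen: trimesh.Trimesh,
    end_planes: dict[str, tuple[np.ndarray, np.ndarray]],
    tol: float = 0.2,
) -> TetMesh:
    """Tag boundary facets: lumen by surface proximity, ends by plane.

    ``end_planes`` maps tag name to (point on plane, outward normal).
    Every boundary facet gets exactly one tag; untagged facets are
    ``outer``.  An empty lumen set is rejected (the pressure load would
    vanish).
    """
    faces = mesh.boundary_faces
    cent = mesh.nodes[faces].mean(axis=1)
    tags = np.zeros(len(faces), dtype=np.int8)
    d, _, _ = nearest_on_surface(stenotic_lumen, cent)
    tags[d < tol] = BOUNDARY_TAGS.index("lumen")
    for name, (p0, n) in end_planes.items():
        n = np.asarray(n, dtype=float)
        n = n / np.linalg.norm(n)
        on_plane = np.abs((cent - np.asarray(p0)) @ n) < tol
        # require the facet to actually face the plane normal
        v1 = mesh.nodes[faces[:, 1]] - mesh.nodes[faces[:, 0]]
        v2 = mesh.nodes[faces[:, 2]] - mesh.nodes[faces[:, 0]]
        fn = np.cross(v1, v2)
        fn /= np.maximum(np.linalg.norm(fn, axis=1), 1e-30)[:, None]
        aligned = np.abs(fn @ n) > 0.7
        tags[on_plane & aligned] = BOUNDARY_TAGS.index(name)
    if not np.any(tags == BOUNDARY_TAGS.index("lumen")):
        raise ValueError("no boundary facet within tolerance of the lumen surface")
    mesh.boundary_tags = tags
    return mesh
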