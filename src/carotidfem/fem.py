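"""Linear-elastic static FEM on labelled tetrahedral meshes.

Small-deformation, isotropic linear elasticity with 4-node
(constant-strain) displacement tetrahedra, solved as a single static
analysis:

* unit system mm / N / MPa (stresses come out in MPa);
* per-subset Young's modulus (kPa input, converted) and a shared
  Poisson ratio, default 0.49 (nearly incompressible) -- note that
  displacement-only P1 tetrahedra lock volumetrically as nu -> 0.5,
  which the test suite demonstrates on the pressure-vessel benchmark;
* uniform dead pressure on the tagged lumen facets (no follower
  update), magnitude the systolic-diastolic differential pressure;
* end planes constrained in the longitudinal and circumferential
  directions through per-node cylindrical frames, radial direction
  free;
* direct sparse factorization, iterative fallback with a diagnostic.

Per-element von Mises stress is recovered from the constant element
strain through each subset's elasticity matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .discretization import BOUNDARY_TAGS, SUBSETS, TetMesh

MMHG_TO_MPA = 133.322387415e-6

__all__ = [
    "MaterialTable",
    "LoadCase",
    "StressField",
    "mmhg_to_mpa",
    "assemble",
    "apply_pressure",
    "apply_constraints",
    "solve_static",
    "element_stress_voigt",
    "element_vm",
    "run_static",
    "von_mises",
]


def mmhg_to_mpa(p: float) -> float:
    """Convert a pressure from mmHg to MPa (1 mmHg = 133.322387415 Pa)."""
    return p * MMHG_TO_MPA


@dataclass
class MaterialTable:
    """Young's moduli (kPa) per subset and a shared Poisson ratio."""

    young_kpa: dict[str, float] = field(
        default_factory=lambda: {
            "calcific": 20000.0,
            "lipid": 4.0,
            "fibrous": 400.0,
            "wall": 550.0,
        }
    )
    poisson: float = 0.49

    def __post_init__(self):
        for name, e in self.young_kpa.items():
            if e <= 0:
                raise ValueError(f"E({name}) must be positive")
        if not (0.0 <= self.poisson < 0.5):
            raise ValueError("Poisson ratio must be in [0, 0.5)")

    def elasticity_matrix(self, subset: str) -> np.ndarray:
        """6x6 isotropic elasticity matrix in MPa (Voigt, engineering shear)."""
        e = self.young_kpa[subset] * 1e-3  # kPa -> MPa
        nu = self.poisson
        lam = e * nu / ((1 + nu) * (1 - 2 * nu))
        mu = e / (2 * (1 + nu))
        d = np.zeros((6, 6))
        d[:3, :3] = lam
        d[np.arange(3), np.arange(3)] = lam + 2 * mu
        d[np.arange(3, 6), np.arange(3, 6)] = mu
        return d

    def scaled(self, subset: str, factor: float) -> "MaterialTable":
        young = dict(self.young_kpa)
        young[subset] = young[subset] * factor
        return MaterialTable(young_kpa=young, poisson=self.poisson)


@dataclass
class LoadCase:
    """Differential lumen pressure and end constraints.

    ``pressure_mmhg`` is the systolic-diastolic differential local
    pressure; ends listed in ``constrained_ends`` (present in the mesh)
    are fixed longitudinally and circumferentially, radially free.
    """

    pressure_mmhg: float
    constrained_ends: tuple[str, ...] = ("cca_end", "ica_end", "eca_end")

    def __post_init__(self):
        if self.pressure_mmhg < 0:
            raise ValueError("differential pressure must be non-negative")


@dataclass
class StressField:
    """Per-element von Mises stress (MPa) with volume, centroid, label."""

    vm: np.ndarray
    volume: np.ndarray
    centroid: np.ndarray
    labels: np.ndarray

    def subset(self, name: str) -> "StressField":
        m = self.labels == SUBSETS.index(name)
        return StressField(self.vm[m], self.volume[m], self.centroid[m], self.labels[m])

    def __len__(self):
        return len(self.vm)


@dataclass
class LinearSystem:
    mesh: TetMesh
    K: sp.csr_matrix
    f: np.ndarray
    B: np.ndarray  # (E, 6, 12) strain-displacement operators
    D: np.ndarray  # (E, 6, 6) elasticity matrices
    T: sp.csr_matrix | None = None  # reduction to free dofs
    constrained: bool = False


def _element_operators(mesh: TetMesh, mat: MaterialTable):
    """Constant B and D per element, plus volumes."""
    x = mesh.nodes[mesh.tets]  # (E, 4, 3)
    e = len(x)
    m = np.stack([x[:, 1] - x[:, 0], x[:, 2] - x[:, 0], x[:, 3] - x[:, 0]], axis=1)
    vol = np.linalg.det(m) / 6.0
    if np.any(vol <= 0):
        raise ValueError("inverted element(s) in mesh")
    minv = np.linalg.inv(m)  # rows of minv.T are grad(lambda_1..3)
    grads = np.empty((e, 4, 3))
    grads[:, 1:] = np.transpose(minv, (0, 2, 1))
    grads[:, 0] = -grads[:, 1:].sum(axis=1)
    B = np.zeros((e, 6, 12))
    for a in range(4):
        gx, gy, gz = grads[:, a, 0], grads[:, a, 1], grads[:, a, 2]
        c = 3 * a
        B[:, 0, c] = gx
        B[:, 1, c + 1] = gy
        B[:, 2, c + 2] = gz
        B[:, 3, c] = gy
        B[:, 3, c + 1] = gx
        B[:, 4, c + 1] = gz
        B[:, 4, c + 2] = gy
        B[:, 5, c] = gz
        B[:, 5, c + 2] = gx
    d_by_label = np.stack([mat.elasticity_matrix(s) for s in SUBSETS])
    D = d_by_label[mesh.labels]
    return B, D, vol


def assemble(mesh: TetMesh, mat: MaterialTable) -> LinearSystem:
    """Assemble the global stiffness operator.

    Before constraints the operator annihilates exactly the six
    rigid-body modes (symmetric positive semi-definite).
    """
    B, D, vol = _element_operators(mesh, mat)
    ke = np.einsum("eki,ekl,elj->eij", B, D, B) * vol[:, None, None]
    dof = (3 * mesh.tets[:, :, None] + np.arange(3)[None, None, :]).reshape(-1, 12)
    rows = np.repeat(dof, 12, axis=1).ravel()
    cols = np.tile(dof, (1, 12)).ravel()
    n = 3 * len(mesh.nodes)
    K = sp.coo_matrix((ke.ravel(), (rows, cols)), shape=(n, n)).tocsr()
    return LinearSystem(mesh=mesh, K=K, f=np.zeros(n), B=B, D=D)


def apply_pressure(system: LinearSystem, load: LoadCase) -> LinearSystem:
    """Uniform dead pressure on the lumen facets.

    Each tagged facet contributes a force p*A along the inward surface
    normal (into the wall material), split equally among its nodes.
    """
    mesh = system.mesh
    faces = mesh.tagged_faces("lumen")
    if len(faces) == 0:
        raise ValueError("mesh has no lumen-tagged facets; pressure load is zero")
    p = mmhg_to_mpa(load.pressure_mmhg)
    v1 = mesh.nodes[faces[:, 1]] - mesh.nodes[faces[:, 0]]
    v2 = mesh.nodes[faces[:, 2]] - mesh.nodes[faces[:, 0]]
    # outward area vector of the solid; traction on the wall is -p*n
    area_vec = 0.5 * np.cross(v1, v2)
    if float(np.linalg.norm(area_vec.sum(axis=0))) > 0 and len(faces) and (
        np.linalg.norm(area_vec, axis=1).sum() == 0
    ):
        raise ValueError("degenerate lumen facets")
    force = -p * area_vec / 3.0
    f = system.f
    for a in range(3):
        np.add.at(f.reshape(-1, 3), faces[:, a], force)
    return system


def _end_frames(mesh: TetMesh, tags):
    """Per-node orthonormal frames (axial, circumferential, radial)."""
    frames = {}
    planes = mesh.metadata.get("end_planes", {})
    for tag in tags:
        if tag not in [BOUNDARY_TAGS[i] for i in np.unique(mesh.boundary_tags)]:
            continue
        faces = mesh.tagged_faces(tag)
        nodes = np.unique(faces)
        if len(nodes) == 0:
            continue
        coords = mesh.nodes[nodes]
        if tag in planes:
            _, normal = planes[tag]
            normal = np.asarray(normal, dtype=float)
        else:
            # fit the plane normal from the facet geometry
            f0 = faces[0]
            normal = np.cross(
                mesh.nodes[f0[1]] - mesh.nodes[f0[0]],
                mesh.nodes[f0[2]] - mesh.nodes[f0[0]],
            )
        normal = normal / np.linalg.norm(normal)
        center = coords.mean(axis=0)
        rad = coords - center
        rad -= np.outer(rad @ normal, normal)
        norms = np.linalg.norm(rad, axis=1)
        if np.any(norms < 1e-12):
            raise ValueError(f"end {tag}: node on the section axis")
        rad /= norms[:, None]
        tang = np.cross(normal, rad)
        frames[tag] = (nodes, normal, rad, tang)
    return frames


def apply_constraints(system: LinearSystem, load: LoadCase) -> LinearSystem:
    """Fix longitudinal + circumferential displacement at the end planes.

    Builds the reduction matrix T whose columns span the free dofs:
    standard basis for unconstrained nodes, the radial direction only
    for end-plane nodes.  The reduced operator T' K T must be positive
    definite; a residual rigid mode is reported as an error.
    """
    mesh = system.mesh
    frames = _end_frames(mesh, load.constrained_ends)
    if not frames:
        raise ValueError("no constrained end planes found in mesh")
    n_nodes = len(mesh.nodes)
    constrained_nodes = {}
    for tag, (nodes, normal, rad, tang) in frames.items():
        for i, nid in enumerate(nodes):
            constrained_nodes[int(nid)] = rad[i]
    free_nodes = np.setdiff1d(np.arange(n_nodes), np.fromiter(constrained_nodes, int))
    rows, cols, vals = [], [], []
    col = 0
    for nid in free_nodes:
        for c in range(3):
            rows.append(3 * nid + c)
            cols.append(col)
            vals.append(1.0)
            col += 1
    for nid, rdir in constrained_nodes.items():
        for c in range(3):
            rows.append(3 * nid + c)
            cols.append(col)
            vals.append(rdir[c])
        col += 1
    T = sp.csr_matrix((vals, (rows, cols)), shape=(3 * n_nodes, col))
    system.T = T
    system.constrained = True
    return system


def solve_static(system: LinearSystem, rtol: float = 1e-9) -> np.ndarray:
    """Direct sparse solve of the constrained system; returns full dofs.

    Falls back to conjugate gradients with a Jacobi preconditioner if
    the factorization fails, and rejects solutions whose relative
    residual exceeds ``rtol``.
    """
    if not system.constrained or system.T is None:
        raise ValueError("apply_constraints must run before solve_static")
    T = system.T
    K = (T.T @ system.K @ T).tocsc()
    f = T.T @ system.f
    if not np.any(f):
        return np.zeros(3 * len(system.mesh.nodes))
    try:
        lu = spla.splu(K)
        u_red = lu.solve(f)
    except RuntimeError as err:  # singular factorization
        diag = K.diagonal()
        if np.any(diag <= 0):
            raise ValueError(f"constrained system not positive definite: {err}")
        m = sp.diags(1.0 / diag)
        u_red, info = spla.cg(K, f, M=m, rtol=1e-10, maxiter=20000)
        if info != 0:
            raise ValueError(f"iterative fallback failed (info={info})")
    res = np.linalg.norm(K @ u_red - f) / np.linalg.norm(f)
    if res > rtol:
        raise ValueError(f"solver residual {res:.2e} exceeds {rtol:.0e}")
    return T @ u_red


def von_mises(stress_voigt: np.ndarray) -> np.ndarray:
    """Von Mises invariant of Voigt stresses [s11 s22 s33 s12 s23 s31]."""
    s = np.atleast_2d(stress_voigt)
    return np.sqrt(
        0.5
        * (
            (s[:, 0] - s[:, 1]) ** 2
            + (s[:, 1] - s[:, 2]) ** 2
            + (s[:, 2] - s[:, 0]) ** 2
        )
        + 3.0 * (s[:, 3] ** 2 + s[:, 4] ** 2 + s[:, 5] ** 2)
    )


def element_stress_voigt(system: LinearSystem, u: np.ndarray) -> np.ndarray:
    """Constant per-element Voigt stresses [s11 s22 s33 s12 s23 s31], MPa."""
    mesh = system.mesh
    ue = u.reshape(-1, 3)[mesh.tets].reshape(len(mesh.tets), 12)
    strain = np.einsum("eij,ej->ei", system.B, ue)
    return np.einsum("eij,ej->ei", system.D, strain)


def element_vm(system: LinearSystem, u: np.ndarray) -> StressField:
    """Constant per-element stress recovery and von Mises evaluation."""
    mesh = system.mesh
    stress = element_stress_voigt(system, u)
    return StressField(
        vm=von_mises(stress),
        volume=mesh.volumes,
        centroid=mesh.centroids,
        labels=mesh.labels.copy(),
    )


def run_static(mesh: TetMesh, mat: MaterialTable, load: LoadCase):
    """Assemble, load, constrain, solve; returns (displacements, stresses)."""
    system = assemble(mesh, mat)
    apply_pressure(system, load)
    apply_constraints(system, load)
    u = solve_static(system)
    return u, element_vm(system, u)
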