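"""Summary statistics of the simulated stress fields.

Implements the quantities reported per patient: the differential local
pressure, the cumulative volume-stress curve of a plaque subset, the
VM_99 statistic (the von Mises stress below which 99% of the subset
volume lies, located at a specific element), plaque composition
percentages, percentage differences between the proposed and reference
models, the signed mutual distance between two fibrous surfaces, the
fibrous-cap thickness on the VM_99 section, and the fibrous-modulus
sensitivity sweep.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely
import trimesh

from .contours import BranchFrame
from .discretization import SUBSETS, TetMesh
from .fem import LoadCase, MaterialTable, StressField, run_static
from .meshops import is_watertight, slice_mesh
from .spatial import nearest_on_surface, points_in_mesh

__all__ = [
    "PressureRecord",
    "VolumeStressCurve",
    "VM99Result",
    "DistanceReport",
    "differential_pressure",
    "volume_stress_curve",
    "vm99",
    "composition_percentages",
    "percentage_difference",
    "signed_distance_report",
    "fc_thickness",
    "sensitivity_sweep",
    "locate_vm99",
]


@dataclass
class PressureRecord:
    patient: int | str
    p_systolic: float
    p_diastolic: float

    def __post_init__(self):
        if not (self.p_systolic > self.p_diastolic > 0):
            raise ValueError("need P_S > P_D > 0")

    @property
    def differential(self) -> float:
        return differential_pressure(self.p_systolic, self.p_diastolic)


def differential_pressure(p_systolic: float, p_diastolic: float) -> float:
    """Differential local pressure P_S - P_D (mmHg), the lumen load."""
    if p_systolic < p_diastolic:
        raise ValueError("systolic pressure below diastolic")
    return p_systolic - p_diastolic


@dataclass
class VolumeStressCurve:
    """Stresses sorted increasingly vs cumulative normalized volume."""

    stresses: np.ndarray  # kPa, non-decreasing
    cumulative_volume: np.ndarray  # fraction, ends at 1
    subset: str = "fibrous"

    def to_csv(self, path):
        np.savetxt(
            path,
            np.column_stack([self.stresses, self.cumulative_volume]),
            delimiter=",",
            header="vm_kpa,cumulative_volume_fraction",
            comments="",
        )


@dataclass
class VM99Result:
    vm99_kpa: float
    element: int
    centroid: np.ndarray
    z_station: float
    location: str | None = None


@dataclass
class DistanceReport:
    """Signed distances from reference vertices to the proposed surface.

    Positive where the reference lies outside the proposed solid.
    """

    distances: np.ndarray
    mean: float
    sd: float
    p5: float
    p95: float


def volume_stress_curve(field: StressField, subset: str = "fibrous") -> VolumeStressCurve:
    """Sort subset elements by stress and accumulate normalized volume."""
    sub = field.subset(subset) if subset is not None else field
    if len(sub) == 0:
        raise ValueError(f"subset {subset!r} is empty")
    order = np.argsort(sub.vm, kind="stable")
    vm_kpa = sub.vm[order] * 1e3  # MPa -> kPa
    cum = np.cumsum(sub.volume[order])
    return VolumeStressCurve(vm_kpa, cum / cum[-1], subset=subset or "all")


def vm99(field: StressField, subset: str = "fibrous", fraction: float = 0.99) -> VM99Result:
    """VM_99: first element (in increasing-stress order) at which the
    cumulative subset volume reaches 99% of the total.

    Ties in stress break by element index; no interpolation is applied.
    Also reports that element's centroid and axial (z) station.
    """
    sub = field.subset(subset) if subset is not None else field
    if len(sub) == 0:
        raise ValueError(f"subset {subset!r} is empty")
    order = np.argsort(sub.vm, kind="stable")
    cum = np.cumsum(sub.volume[order])
    i = int(np.searchsorted(cum, fraction * cum[-1] - 1e-12))
    i = min(i, len(order) - 1)
    e = order[i]
    return VM99Result(
        vm99_kpa=float(sub.vm[e] * 1e3),
        element=int(e),
        centroid=sub.centroid[e],
        z_station=float(sub.centroid[e][2]),
    )


def locate_vm99(
    result: VM99Result,
    lipid: trimesh.Trimesh | None,
    calcific: trimesh.Trimesh | None,
    bifurcation: np.ndarray | None,
    cap_tol: float = 1.0,
    bif_tol: float = 3.0,
) -> VM99Result:
    """Attach an anatomical location tag to a VM_99 element.

    Rule-based stand-in for visual classification: within ``cap_tol``
    of the lipid surface -> fibrous cap; within ``cap_tol`` of the
    calcific surface -> calcific plaque shoulder; within ``bif_tol`` of
    the bifurcation apex -> bifurcation.
    """
    c = np.atleast_2d(result.centroid)
    loc = None
    if bifurcation is not None and np.linalg.norm(c[0] - bifurcation) < bif_tol:
        loc = "bifurcation"
    if calcific is not None and len(calcific.faces) and loc is None:
        if nearest_on_surface(calcific, c)[0][0] < cap_tol:
            loc = "calcific plaque shoulder"
    if lipid is not None and len(lipid.faces):
        if nearest_on_surface(lipid, c)[0][0] < cap_tol:
            loc = "fibrous cap"
    result.location = loc
    return result


def composition_percentages(volumes: dict[str, float]) -> dict[str, float]:
    """Component volumes as % of the plaque total (calcific+lipid+fibrous)."""
    total = sum(volumes.get(k, 0.0) for k in ("calcific", "lipid", "fibrous"))
    if total <= 0:
        raise ValueError("plaque total volume is zero")
    return {
        k: 100.0 * volumes.get(k, 0.0) / total for k in ("calcific", "lipid", "fibrous")
    }


def percentage_difference(proposed: float, reference: float) -> float:
    """(proposed - reference) / reference * 100."""
    if reference == 0:
        raise ValueError("reference value is zero")
    return (proposed - reference) / reference * 100.0


def signed_distance_report(
    reference: trimesh.Trimesh, proposed: trimesh.Trimesh
) -> DistanceReport:
    """Mutual-distance analysis between two fibrous models.

    For every reference vertex: unsigned minimum distance to the
    proposed surface, signed positive when the vertex lies outside the
    proposed solid (ray-parity test).  Reports mean, SD and the 5th /
    95th percentiles.
    """
    if not is_watertight(proposed):
        raise ValueError("proposed mesh must be watertight (sign undefined)")
    pts = np.asarray(reference.vertices, dtype=float)
    d, _, _ = nearest_on_surface(proposed, pts)
    inside = points_in_mesh(proposed, pts)
    signed = np.where(inside, -d, d)
    return DistanceReport(
        distances=signed,
        mean=float(signed.mean()),
        sd=float(signed.std(ddof=0)),
        p5=float(np.percentile(signed, 5)),
        p95=float(np.percentile(signed, 95)),
    )


def fc_thickness(
    result: VM99Result,
    lumen: trimesh.Trimesh,
    lipid: trimesh.Trimesh | None,
    frame: BranchFrame | None = None,
    angular_window: float = np.pi / 6,
) -> float | None:
    """Fibrous-cap thickness on the VM_99 cross-sectional plane.

    The lumen and lipid surfaces are cut with the transversal plane at
    the VM_99 axial station; the thickness is the minimum distance
    between the lumen contour and the lipid contour, restricted to an
    angular window (default +/-30 deg) about the VM_99 centroid
    direction.  Returns None (the "not applicable" marker) when no
    lipid section exists on that plane.
    """
    if lipid is None or len(lipid.faces) == 0:
        return None
    frame = frame or BranchFrame(origin=[0.0, 0.0, 0.0], axis=[0.0, 0.0, 1.0])
    s, cx, cy = frame.to_plane(np.atleast_2d(result.centroid))
    station = float(s[0])
    lumen_polys = slice_mesh(lumen, frame, station)
    lipid_polys = slice_mesh(lipid, frame, station)
    if not lumen_polys or not lipid_polys:
        return None
    # section centroid from the lumen contour nearest the VM99 element
    best = min(
        lumen_polys,
        key=lambda p: np.hypot(p[:, 0].mean() - cx[0], p[:, 1].mean() - cy[0]),
    )
    center = best.mean(axis=0)
    phi0 = np.arctan2(cy[0] - center[1], cx[0] - center[0])
    ang = np.arctan2(best[:, 1] - center[1], best[:, 0] - center[0])
    dphi = np.mod(ang - phi0 + np.pi, 2 * np.pi) - np.pi
    window = best[np.abs(dphi) <= angular_window]
    if len(window) == 0:
        return None
    lipid_b = shapely.unary_union(
        [shapely.LineString(np.vstack([p, p[:1]])) for p in lipid_polys]
    )
    pts = shapely.points(window[:, 0], window[:, 1])
    return float(np.min(shapely.distance(pts, lipid_b)))


def sensitivity_sweep(
    mesh: TetMesh,
    materials: MaterialTable,
    load: LoadCase,
    multipliers=(0.5, 0.8, 0.9, 1.0, 1.1, 1.2, 1.5),
    subset: str = "fibrous",
) -> dict[float, dict]:
    """Re-solve with the fibrous Young's modulus scaled by each multiplier.

    Returns per multiplier the VM_99 result and volume-stress curve of
    the analysed subset.  A failed solve aborts the sweep; partial
    results are returned with the failure recorded under ``"error"``.
    """
    out: dict[float, dict] = {}
    has_subset = np.any(mesh.labels == SUBSETS.index(subset))
    for m in multipliers:
        mat = materials.scaled(subset, m)
        try:
            _, field = run_static(mesh, mat, load)
        except ValueError as err:
            out[m] = {"error": str(err)}
            break
        target = subset if has_subset else None
        out[m] = {
            "vm99": vm99(field, subset=target),
            "curve": volume_stress_curve(field, subset=target),
        }
    return out
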