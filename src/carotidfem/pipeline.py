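"""End-to-end orchestration: synth -> (image) -> reconstruct -> mesh ->
solve -> post, plus the proposed-vs-reference model comparison.

Every stage writes its artifacts into the run directory together with a
manifest (stage timings, parameter hash, content hashes of outputs).
Re-running with an identical configuration is bit-reproducible for the
deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import trimesh

from . import discretization as disc
from .config import RunConfig
from .contours import BranchFrame
from .fem import LoadCase, MaterialTable, run_static
from .imaging import threshold_segment, voxelize_to_hu
from .meshops import PolarTube
from .postprocess import (
    fc_thickness,
    locate_vm99,
    percentage_difference,
    sensitivity_sweep,
    signed_distance_report,
    vm99,
    volume_stress_curve,
)
from .reconstruction import reconstruct_wall
from .synthetic import Anatomy, StenosisSpec, default_centerlines, make_anatomy

log = logging.getLogger(__name__)

STAGES = ("synth", "segment", "reconstruct", "mesh", "solve", "post")

__all__ = ["run_pipeline", "compare_models", "PipelineResult", "STAGES"]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _export_stl(mesh, path: Path):
    path.parent.mkdir(parents=True, exist_ok=True)
    mesh.export(path, file_type="stl_ascii")


class PipelineResult:
    """Accumulates stage products; attribute access mirrors stage names."""

    def __init__(self, outdir: Path):
        self.outdir = outdir
        self.anatomy: Anatomy | None = None
        self.wall_model = None
        self.tet_mesh = None
        self.field = None
        self.vm99_result = None
        self.report: dict = {}
        self.manifest: dict = {"stages": {}, "files": {}}


def _polar_tubes_from_stack(stack, n_theta: int = 96):
    from .contours import polar_radii

    tubes = {}
    for b in stack.branches():
        radii, centers = [], []
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


def _mesh_stage(config: RunConfig, res: PipelineResult):
    wm = res.wall_model
    anatomy = res.anatomy
    single = len(anatomy.centerlines.branches) == 1
    span = None
    if anatomy.stenoses:
        lo = min(s.span[0] for s in anatomy.stenoses)
        hi = max(s.span[1] for s in anatomy.stenoses)
        span = (lo, hi)
    if single:
        inner = _polar_tubes_from_stack(wm.inner_stack)
        outer = _polar_tubes_from_stack(wm.outer_stack)
        (b,) = inner.keys()
        mesh = disc.structured_wall_mesh(
            inner[b],
            outer[b],
            global_size=config.mesh.global_size,
            local_size=config.mesh.local_size,
            plaque_span=span,
            end_tags=("cca_end", "ica_end"),
        )
    else:
        hull = None
        if anatomy.components:
            from .reconstruction import plaque_hull

            hull = plaque_hull(anatomy.components)
        mesh = disc.tetrahedralize(
            wm.wall_solid,
            global_size=config.mesh.global_size,
            local_size=config.mesh.local_size,
            plaque_region=hull,
            seed=config.seed,
        )
        end_planes = {}
        for name, br in anatomy.centerlines.branches.items():
            tag = f"{name.lower()}_end"
            point = br.origin if name == "CCA" else br.end
            normal = -br.direction if name == "CCA" else br.direction
            end_planes[tag] = (point, normal)
        mesh.metadata["end_planes"] = end_planes
        disc.tag_boundary(mesh, wm.inner, end_planes)
    components = {"fibrous": wm.fibrous}
    cal = anatomy.calcific
    lip = anatomy.lipid
    if cal:
        components["calcific"] = trimesh.util.concatenate(cal) if len(cal) > 1 else cal[0]
    if lip:
        components["lipid"] = trimesh.util.concatenate(lip) if len(lip) > 1 else lip[0]
    disc.assign_subsets(mesh, components)
    res.tet_mesh = mesh
    return mesh


def _post_stage(config: RunConfig, res: PipelineResult):
    anatomy = res.anatomy
    mesh = res.tet_mesh
    field = res.field
    has_fibrous = bool(np.any(mesh.labels == disc.SUBSETS.index("fibrous")))
    subset = "fibrous" if has_fibrous else None
    curve = volume_stress_curve(field, subset=subset)
    r = vm99(field, subset=subset, fraction=config.post.volume_fraction)
    cal = anatomy.calcific
    lip = anatomy.lipid
    cal_m = trimesh.util.concatenate(cal) if cal else None
    lip_m = trimesh.util.concatenate(lip) if lip else None
    locate_vm99(r, lip_m, cal_m, anatomy.centerlines.bifurcation)
    res.vm99_result = r

    volumes = {s: mesh.subset_volume(s) for s in ("calcific", "lipid", "fibrous")}
    composition = None
    if sum(volumes.values()) > 0:
        from .postprocess import composition_percentages

        composition = composition_percentages(volumes)
    frame = anatomy.centerlines.branches[sorted(anatomy.centerlines.branches)[0]].frame
    thickness = fc_thickness(
        r,
        anatomy.lumen,
        lip_m,
        frame=frame,
        angular_window=np.deg2rad(config.post.angular_window_deg),
    )
    report = {
        "seed": config.seed,
        "differential_pressure_mmhg": config.load.differential(),
        "subset_volumes_mm3": volumes,
        "wall_volume_mm3": mesh.subset_volume("wall"),
        "composition_pct": composition,
        "vm99_kpa": r.vm99_kpa,
        "vm99_location": r.location,
        "vm99_z_mm": r.z_station,
        "fc_thickness_mm": thickness,
        "n_elements": len(mesh.tets),
        "n_nodes": len(mesh.nodes),
    }
    if config.post.run_sensitivity and has_fibrous:
        sweep = sensitivity_sweep(
            mesh,
            config.materials.table(),
            LoadCase(config.load.differential(), _ends(mesh)),
            multipliers=config.post.sensitivity_multipliers,
        )
        report["sensitivity_vm99_kpa"] = {
            str(m): (v["vm99"].vm99_kpa if "vm99" in v else v.get("error"))
            for m, v in sweep.items()
        }
    res.report = report
    curve.to_csv(res.outdir / "volume_stress_curve.csv")
    (res.outdir / "report.json").write_text(json.dumps(report, indent=1, default=str))
    return report


def _ends(mesh) -> tuple[str, ...]:
    present = {disc.BOUNDARY_TAGS[t] for t in np.unique(mesh.boundary_tags)}
    return tuple(t for t in ("cca_end", "ica_end", "eca_end") if t in present)


def run_pipeline(config: RunConfig, upto: str = "post") -> PipelineResult:
    """Execute the workflow up to (and including) the given stage."""
    if upto not in STAGES:
        raise ValueError(f"unknown stage {upto!r}")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    res = PipelineResult(outdir)
    res.manifest["config"] = config.model_dump()
    last = STAGES.index(upto)

    def record(stage, t0, files):
        res.manifest["stages"][stage] = {"seconds": round(time.time() - t0, 2)}
        for f in files:
            if f.exists():
                res.manifest["files"][str(f.relative_to(outdir))] = _sha256(f)
        (outdir / "manifest.json").write_text(
            json.dumps(res.manifest, indent=1, default=str)
        )

    # synth
    t0 = time.time()
    centerlines = default_centerlines(config.anatomy.mode)
    stenoses = [StenosisSpec(**s.model_dump()) for s in config.anatomy.stenoses]
    anatomy = make_anatomy(
        config.seed,
        centerlines=centerlines,
        stenoses=stenoses,
        spacing=config.anatomy.spacing,
        n_theta=config.anatomy.n_theta,
        noise_amplitude=config.anatomy.noise_amplitude,
    )
    res.anatomy = anatomy
    files = []
    _export_stl(anatomy.lumen, outdir / "lumen.stl")
    files.append(outdir / "lumen.stl")
    for i, c in enumerate(anatomy.components):
        f = outdir / f"component_{i}_{c.metadata.get('name', 'comp')}.stl"
        _export_stl(c, f)
        files.append(f)
    if len(anatomy.reference_fibrous.faces):
        _export_stl(anatomy.reference_fibrous, outdir / "reference_fibrous.stl")
        files.append(outdir / "reference_fibrous.stl")
    record("synth", t0, files)
    if last == 0:
        return res

    # segment (optional round trip through the HU volume)
    if config.imaging.enabled:
        t0 = time.time()
        vol = voxelize_to_hu(
            anatomy.lumen,
            anatomy.components,
            spacing=config.imaging.spacing,
            seed=config.seed,
        )
        vol.save(outdir / "hu_volume")
        lum, cal, lip = threshold_segment(vol)
        seg_files = [outdir / "hu_volume.json", outdir / "hu_volume.raw"]
        if lum is not None:
            _export_stl(lum, outdir / "segmented_lumen.stl")
            seg_files.append(outdir / "segmented_lumen.stl")
        record("segment", t0, seg_files)
    if last == 1:
        return res

    # reconstruct
    t0 = time.time()
    wm = reconstruct_wall(
        anatomy.lumen,
        anatomy.components,
        anatomy.centerlines,
        spacing=config.reconstruction.spacing,
        n_control=config.reconstruction.n_control,
        narrowing_threshold=config.reconstruction.narrowing_threshold,
        enlargement=config.reconstruction.enlargement,
        fillet_radius=config.reconstruction.fillet_radius,
    )
    res.wall_model = wm
    files = []
    for name in ("inner", "outer", "wall_solid", "healthy_lumen", "fibrous"):
        m = getattr(wm, name)
        if len(m.faces):
            f = outdir / f"{name}.stl"
            _export_stl(m, f)
            files.append(f)
    (outdir / "contours.txt").write_text(wm.outer_stack.dumps())
    files.append(outdir / "contours.txt")
    record("reconstruct", t0, files)
    if last == 2:
        return res

    # mesh
    t0 = time.time()
    mesh = _mesh_stage(config, res)
    mesh.save_vtk(outdir / "wall_mesh.vtk")
    mesh.save_gmsh(outdir / "wall_mesh.msh")
    record("mesh", t0, [outdir / "wall_mesh.vtk", outdir / "wall_mesh.msh"])
    if last == 3:
        return res

    # solve
    t0 = time.time()
    load = LoadCase(config.load.differential(), _ends(mesh))
    u, field = run_static(mesh, config.materials.table(), load)
    res.field = field
    header = "element,label,volume_mm3,cx,cy,cz,vm_mpa"
    rows = np.column_stack(
        [
            np.arange(len(field)),
            field.labels,
            field.volume,
            field.centroid,
            field.vm,
        ]
    )
    np.savetxt(outdir / "element_stress.csv", rows, delimiter=",", header=header,
               comments="", fmt="%.9g")
    record("solve", t0, [outdir / "element_stress.csv"])
    if last == 4:
        return res

    # post
    t0 = time.time()
    _post_stage(config, res)
    record("post", t0, [outdir / "report.json", outdir / "volume_stress_curve.csv"])
    return res


def compare_models(config: RunConfig, res: PipelineResult | None = None) -> dict:
    """Proposed vs reference fibrous model on the shared wall geometry.

    The two simulations differ only in the fibrous subset (elements are
    relabelled with the reference fibrous surface); both share the same
    spatial reference system, so curves, VM_99 values, percentage
    differences and the mutual distance report are directly comparable.
    """
    if res is None:
        res = run_pipeline(config, upto="solve")
    anatomy = res.anatomy
    mesh = res.tet_mesh
    reference = anatomy.reference_fibrous
    if len(reference.faces) == 0:
        raise ValueError("anatomy has no reference fibrous model to compare")
    wm = res.wall_model

    # reference-model relabelling on the same mesh
    comp_ref = {"fibrous": reference}
    cal, lip = anatomy.calcific, anatomy.lipid
    if cal:
        comp_ref["calcific"] = trimesh.util.concatenate(cal) if len(cal) > 1 else cal[0]
    if lip:
        comp_ref["lipid"] = trimesh.util.concatenate(lip) if len(lip) > 1 else lip[0]
    import copy

    mesh_ref = copy.deepcopy(mesh)
    disc.assign_subsets(mesh_ref, comp_ref)

    load = LoadCase(config.load.differential(), _ends(mesh))
    mat = config.materials.table()
    if res.field is None:
        _, field_prop = run_static(mesh, mat, load)
    else:
        field_prop = res.field
    _, field_ref = run_static(mesh_ref, mat, load)

    vm_p = vm99(field_prop, subset="fibrous")
    vm_r = vm99(field_ref, subset="fibrous")
    vol_p = mesh.subset_volume("fibrous")
    vol_r = mesh_ref.subset_volume("fibrous")
    dist = signed_distance_report(reference, wm.fibrous)
    out = {
        "vm99_proposed_kpa": vm_p.vm99_kpa,
        "vm99_reference_kpa": vm_r.vm99_kpa,
        "fibrous_volume_proposed_mm3": vol_p,
        "fibrous_volume_reference_mm3": vol_r,
        "vm99_pct_difference": percentage_difference(vm_p.vm99_kpa, vm_r.vm99_kpa),
        "volume_pct_difference": percentage_difference(vol_p, vol_r),
        "distance_mean_mm": dist.mean,
        "distance_sd_mm": dist.sd,
        "distance_p5_mm": dist.p5,
        "distance_p95_mm": dist.p95,
    }
    outdir = res.outdir
    volume_stress_curve(field_prop, "fibrous").to_csv(outdir / "curve_proposed.csv")
    volume_stress_curve(field_ref, "fibrous").to_csv(outdir / "curve_reference.csv")
    (outdir / "comparison.json").write_text(json.dumps(out, indent=1))
    return out
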