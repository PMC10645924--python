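"""Synthetic Hounsfield-unit volumes and threshold segmentation.

Emulates the imaging step of the workflow on synthetic anatomies: a
labelled HU volume is rasterized from watertight surfaces with
voxel-center inside tests, and segmented back with the standard CTA
threshold classes

========================  =============
material                  HU range
========================  =============
plaque calcific           >= 800
plaque lipid              <= 60
contrast-enhanced blood   200 - 700
========================  =============

Background soft tissue (which stands in for the unlabelled fibrous /
muscular wall, not distinguishable from its surroundings on CTA) is a
constant 100 HU, strictly between the lipid and blood classes, so the
classification is unambiguous.  No CT noise or beam-hardening model is
attempted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage.measure import marching_cubes

from .meshops import is_watertight, make_mesh
from .spatial import points_in_mesh

__all__ = ["HU_RANGES", "HUVolume", "voxelize_to_hu", "threshold_segment"]

HU_RANGES = {
    "calcific": (800.0, np.inf),
    "lipid": (-np.inf, 60.0),
    "blood": (200.0, 700.0),
}

_SOFT_TISSUE_HU = 100.0


@dataclass
class HUVolume:
    """Regular scalar grid of Hounsfield units.

    ``values[i, j, k]`` is the voxel centered at
    ``origin + spacing * (i, j, k)`` (mm).
    """

    values: np.ndarray
    spacing: float
    origin: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float32)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("HU values must be finite")

    # Layout on disk: <prefix>.json holds shape/spacing/origin/dtype,
    # <prefix>.raw the C-ordered float32 grid.
    def save(self, prefix: str | Path):
        prefix = Path(prefix)
        meta = {
            "shape": list(self.values.shape),
            "spacing": self.spacing,
            "origin": self.origin.tolist(),
            "dtype": "float32",
            "order": "C",
        }
        prefix.with_suffix(".json").write_text(json.dumps(meta, indent=1))
        self.values.astype(np.float32).tofile(prefix.with_suffix(".raw"))

    @classmethod
    def load(cls, prefix: str | Path) -> "HUVolume":
        prefix = Path(prefix)
        meta = json.loads(prefix.with_suffix(".json").read_text())
        values = np.fromfile(prefix.with_suffix(".raw"), dtype=np.float32).reshape(
            meta["shape"]
        )
        return cls(values=values, spacing=meta["spacing"], origin=np.array(meta["origin"]))

    def voxel_centers(self) -> np.ndarray:
        nx, ny, nz = self.values.shape
        ii, jj, kk = np.meshgrid(
            np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
        )
        return self.origin + self.spacing * np.column_stack(
            [ii.ravel(), jj.ravel(), kk.ravel()]
        )


def voxelize_to_hu(
    lumen,
    components,
    spacing: float = 0.5,
    seed: int = 0,
    padding: float = 2.0,
) -> HUVolume:
    """Rasterize surfaces into a synthetic HU volume.

    Voxel centers inside the lumen draw contrast-blood values in
    [200, 700]; inside calcific components >= 800; inside lipid <= 60;
    everything else is 100 HU soft tissue.  Deterministic for a given
    seed.  Inputs must be watertight.
    """
    meshes = [("lumen", lumen)] + [
        (c.metadata.get("name", "calcific"), c) for c in components
    ]
    for name, m in meshes:
        if not is_watertight(m):
            raise ValueError(f"{name} surface is not watertight")
    lo = np.min([m.vertices.min(axis=0) for _, m in meshes], axis=0) - padding
    hi = np.max([m.vertices.max(axis=0) for _, m in meshes], axis=0) + padding
    shape = np.ceil((hi - lo) / spacing).astype(int) + 1
    vol = HUVolume(
        values=np.full(shape, _SOFT_TISSUE_HU, dtype=np.float32),
        spacing=spacing,
        origin=lo,
    )
    centers = vol.voxel_centers()
    rng = np.random.default_rng(seed)
    flat = vol.values.ravel()
    inside_lumen = points_in_mesh(lumen, centers)
    flat[inside_lumen] = rng.uniform(200.0, 700.0, inside_lumen.sum())
    for name, m in meshes[1:]:
        inside = points_in_mesh(m, centers)
        if name == "lipid":
            flat[inside] = rng.uniform(0.0, 60.0, inside.sum())
        else:
            flat[inside] = 800.0 + rng.uniform(0.0, 400.0, inside.sum())
    vol.values = flat.reshape(shape)
    return vol


def _extract_regions(mask: np.ndarray, vol: HUVolume, name: str, min_voxels: int = 1):
    """Marching-cubes surface per connected voxel region of a class mask."""
    labels, n = ndimage.label(mask)
    out = []
    for lab in range(1, n + 1):
        region = labels == lab
        if region.sum() < min_voxels:
            continue
        padded = np.pad(region.astype(np.float32), 1)
        verts, faces, _, _ = marching_cubes(padded, level=0.5)
        world = vol.origin + vol.spacing * (verts - 1.0)
        mesh = make_mesh(world, faces, name=name)
        mesh.merge_vertices(digits_vertex=7)
        mesh.update_faces(mesh.nondegenerate_faces())
        mesh.metadata["voxel_count"] = int(region.sum())
        out.append(mesh)
    out.sort(key=lambda m: -m.metadata["voxel_count"])
    return out


def threshold_segment(vol: HUVolume):
    """Threshold classification of an HU volume into surfaces.

    Returns ``(lumen, calcific_list, lipid_list)``: the largest
    contrast-blood region is taken as the lumen (None when no voxel is
    in range), and every connected calcific / lipid region yields one
    surface.  Segmenting the output of :func:`voxelize_to_hu` recovers
    each component's volume up to voxelization error.
    """
    v = vol.values
    blood = (v >= HU_RANGES["blood"][0]) & (v <= HU_RANGES["blood"][1])
    calcific = v >= HU_RANGES["calcific"][0]
    lipid = v <= HU_RANGES["lipid"][1]
    lumens = _extract_regions(blood, vol, "lumen")
    return (
        lumens[0] if lumens else None,
        _extract_regions(calcific, vol, "calcific"),
        _extract_regions(lipid, vol, "lipid"),
    )
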