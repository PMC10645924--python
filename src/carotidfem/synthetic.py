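"""Seeded synthetic atherosclerotic carotid anatomies.

Generates the geometry a CTA segmentation would hand to the
reconstruction stage: a watertight stenotic lumen surface, watertight
calcific / lipid plaque component surfaces hugging the lumen, and a
ground-truth fibrous solid (the tissue filling the stenotic gap between
the nominal healthy lumen and the stenotic lumen, around the other
components) that plays the role of an expert's manual segmentation in
comparison studies.

Geometry model
--------------
Each branch (CCA, ICA, ECA) is a straight axis with a constant nominal
lumen radius plus a small smooth seeded perturbation.  A stenosis on a
branch reduces the local cross-sectional area by the requested fraction
with a cosine-squared axial profile and an eccentric angular profile::

    r(s, theta) = r_base(s, theta) * sqrt(1 - A * h(s) * g(theta))
    g(theta)    = 1 + e * cos(theta - angle)        (mean over theta = 1)

so the maximal area reduction at the stenosis center equals ``A``
exactly (up to the base perturbation).  Plaque components are polar
bands inside the stenotic gap: the lipid core sits against the stenotic
lumen, the calcific component towards the outer edge of the gap, both
confined to the angular window of the plaque bulk and scaled to the
requested volume fractions of the gap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely

from .contours import BranchFrame
from .meshops import PolarTube, empty_mesh, region_stack_solid, tube_union_solid
import trimesh

__all__ = [
    "Branch",
    "CenterlineSet",
    "StenosisSpec",
    "Anatomy",
    "default_centerlines",
    "make_anatomy",
]


@dataclass
class Branch:
    """Straight branch axis with constant nominal lumen radius (mm)."""

    name: str
    origin: np.ndarray
    direction: np.ndarray
    length: float
    radius: float

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float)
        d = np.asarray(self.direction, dtype=float)
        self.direction = d / np.linalg.norm(d)
        if self.length <= 0 or self.radius <= 0:
            raise ValueError("branch length and radius must be positive")

    @property
    def frame(self) -> BranchFrame:
        return BranchFrame(origin=self.origin, axis=self.direction)

    @property
    def end(self) -> np.ndarray:
        return self.origin + self.length * self.direction


@dataclass
class CenterlineSet:
    branches: dict[str, Branch]

    def __post_init__(self):
        if not self.branches:
            raise ValueError("at least one branch required")
        if "CCA" in self.branches:
            bif = self.branches["CCA"].end
            for name in ("ICA", "ECA"):
                if name in self.branches:
                    if not np.allclose(self.branches[name].origin, bif, atol=1e-9):
                        raise ValueError(
                            f"{name} must start at the CCA endpoint (bifurcation)"
                        )

    @property
    def bifurcation(self) -> np.ndarray | None:
        if "CCA" in self.branches and len(self.branches) > 1:
            return self.branches["CCA"].end
        return None


def default_centerlines(mode: str = "bifurcation") -> CenterlineSet:
    """Carotid-like defaults, desk scale.

    ``bifurcation``: CCA (r 2.7 mm) splitting into a bulb-like ICA
    (r 2.7 mm) and a narrower ECA (r 2.0 mm); branches untapered so the
    distal-radius outer-wall rule is self-consistent.  ``tube``: a
    single straight CCA-to-ICA style vessel, the fixture geometry for
    analytic checks.
    """
    if mode == "tube":
        return CenterlineSet(
            {"CCA": Branch("CCA", [0.0, 0.0, 0.0], [0.0, 0.0, 1.0], 24.0, 3.0)}
        )
    if mode != "bifurcation":
        raise ValueError(f"unknown centerline mode {mode!r}")
    cca = Branch("CCA", [0.0, 0.0, 0.0], [0.0, 0.0, 1.0], 14.0, 2.7)
    bif = cca.end
    ica = Branch("ICA", bif, [np.sin(0.38), 0.0, np.cos(0.38)], 13.0, 2.7)
    eca = Branch("ECA", bif, [-np.sin(0.50), 0.05, np.cos(0.50)], 11.0, 2.0)
    return CenterlineSet({"CCA": cca, "ICA": ica, "ECA": eca})


@dataclass
class StenosisSpec:
    """One stenotic lesion on a branch.

    ``area_reduction`` is the maximal cross-sectional area reduction in
    (0, 1); ``angle`` the angular position (rad) of the plaque bulk in
    the branch frame; ``calcific_fraction`` / ``lipid_fraction`` the
    target volume fractions of the stenotic gap occupied by those
    components (the remainder is fibrous tissue).
    """

    branch: str = "CCA"
    center: float = 10.0
    extent: float = 8.0
    area_reduction: float = 0.5
    angle: float = 0.0
    calcific_fraction: float = 0.25
    lipid_fraction: float = 0.15
    eccentricity: float = 0.8

    def validate(self, branch: Branch):
        if not (0.0 < self.area_reduction < 1.0):
            raise ValueError("area_reduction must be in (0, 1)")
        for f in (self.calcific_fraction, self.lipid_fraction):
            if f < 0 or f >= 1:
                raise ValueError("component fractions must be in [0, 1)")
        if self.calcific_fraction + self.lipid_fraction >= 1:
            raise ValueError("component fractions must sum below 1")
        if self.extent <= 0:
            raise ValueError("extent must be positive")
        lo, hi = self.center - self.extent / 2, self.center + self.extent / 2
        if lo < 0 or hi > branch.length:
            raise ValueError("stenosis extent exceeds branch length")
        if not (0 <= self.eccentricity <= 1):
            raise ValueError("eccentricity must be in [0, 1]")
        if self.area_reduction * (1 + self.eccentricity) >= 0.97:
            raise ValueError("stenosis too deep for its eccentricity")

    @property
    def span(self):
        return (self.center - self.extent / 2, self.center + self.extent / 2)


@dataclass
class Anatomy:
    """Everything the generator knows about one synthetic case."""

    lumen: trimesh.Trimesh
    components: list[trimesh.Trimesh]
    reference_fibrous: trimesh.Trimesh
    centerlines: CenterlineSet
    stenoses: list[StenosisSpec]
    lumen_tubes: dict[str, PolarTube] = field(default_factory=dict)
    healthy_tubes: dict[str, PolarTube] = field(default_factory=dict)
    seed: int = 0

    @property
    def calcific(self):
        return [c for c in self.components if c.metadata.get("name") == "calcific"]

    @property
    def lipid(self):
        return [c for c in self.components if c.metadata.get("name") == "lipid"]


def _base_radius_field(rng, branch: Branch, stations, theta, amplitude: float):
    """Smooth seeded perturbation of the nominal radius, |dr| <~ amplitude*r."""
    S, T = np.meshgrid(stations / branch.length, theta, indexing="ij")
    r = np.full(S.shape, branch.radius)
    # theta-dependent modes only: ovality/eccentricity wobble that keeps
    # the section area neutral to first order (branches are untapered)
    modes = [(1, 0), (2, 0), (1, 1), (2, 1)]
    for k_theta, k_s in modes:
        a = rng.normal(0.0, amplitude / len(modes) ** 0.5)
        ph_t = rng.uniform(0, 2 * np.pi)
        ph_s = rng.uniform(0, 2 * np.pi)
        r *= 1.0 + a * np.cos(k_theta * T + ph_t) * np.cos(np.pi * k_s * S + ph_s)
    return r


def _stenosis_profile(spec: StenosisSpec, stations, theta):
    """Multiplicative factor on r_base implementing the lesion."""
    S, T = np.meshgrid(stations, theta, indexing="ij")
    h = np.zeros(S.shape)
    inside = np.abs(S - spec.center) < spec.extent / 2
    h[inside] = np.cos(np.pi * (S[inside] - spec.center) / spec.extent) ** 2
    g = 1.0 + spec.eccentricity * np.cos(T - spec.angle)
    reduction = np.clip(spec.area_reduction * h * g, 0.0, 0.97)
    return np.sqrt(1.0 - reduction)


def _component_regions(
    spec: StenosisSpec,
    stations: np.ndarray,
    theta: np.ndarray,
    r_base: np.ndarray,
    r_sten: np.ndarray,
):
    """Shapely regions per station for the calcific and lipid bands."""
    gap = r_base - r_sten
    win = np.cos(theta - spec.angle)
    win = np.clip(win, 0.0, None) ** 0.5  # angular taper of the bands
    dtheta = 2 * np.pi / len(theta)
    ds = np.gradient(stations)

    def band_volume(lo_f, width):
        r_in = r_sten + lo_f * gap
        w = width[None, :] * gap
        r_out = r_in + w
        area = 0.5 * (r_out**2 - r_in**2) * dtheta
        return float(np.sum(area.sum(axis=1) * ds))

    gap_area = 0.5 * (r_base**2 - r_sten**2) * dtheta
    v_gap = float(np.sum(gap_area.sum(axis=1) * ds))
    if v_gap <= 0:
        return {}, v_gap

    out: dict[str, list] = {}
    # scale band widths to the requested gap-volume fractions
    lam = {}
    for name, frac in (("lipid", spec.lipid_fraction), ("calcific", spec.calcific_fraction)):
        if frac <= 0:
            continue
        unit = band_volume(0.10, win)  # volume of a unit-width band
        lam[name] = min(0.38, frac * v_gap / max(unit, 1e-12))
    if "lipid" in lam or "calcific" in lam:
        for name in lam:
            lo_f = 0.08 if name == "lipid" else 0.90 - lam[name]
            width = lam[name] * win
            r_in = r_sten + lo_f * gap
            r_out = r_in + width[None, :] * gap
            regions = []
            for i in range(len(stations)):
                thick = r_out[i] - r_in[i]
                keep = thick > 0.05
                if keep.sum() < 4:
                    regions.append(None)
                    continue
                # order the kept angles across the plaque bulk so the
                # band polygon does not fold at the 0/2pi seam
                idx = np.where(keep)[0]
                delta = np.mod(theta[idx] - spec.angle + np.pi, 2 * np.pi) - np.pi
                idx = idx[np.argsort(delta)]
                outer_pts = np.column_stack(
                    [r_out[i, idx] * np.cos(theta[idx]), r_out[i, idx] * np.sin(theta[idx])]
                )
                inner_pts = np.column_stack(
                    [r_in[i, idx] * np.cos(theta[idx]), r_in[i, idx] * np.sin(theta[idx])]
                )
                poly = shapely.Polygon(np.vstack([outer_pts, inner_pts[::-1]]))
                poly = shapely.make_valid(poly)
                if poly.is_empty or poly.area < 0.05:
                    regions.append(None)
                else:
                    regions.append(poly)
            out[name] = regions
    return out, v_gap


def make_anatomy(
    seed: int,
    centerlines: CenterlineSet | None = None,
    stenoses: list[StenosisSpec] | None = None,
    spacing: float = 0.5,
    n_theta: int = 72,
    noise_amplitude: float = 0.012,
    component_pitch: float = 0.12,
    union_pitch: float = 0.2,
) -> Anatomy:
    """Generate one seeded synthetic anatomy.

    Identical arguments give bit-identical meshes.  With no stenoses the
    result is a healthy vessel: smooth lumen, no components, empty
    ground-truth fibrous solid.
    """
    centerlines = centerlines or default_centerlines()
    stenoses = list(stenoses or [])
    for spec in stenoses:
        if spec.branch not in centerlines.branches:
            raise ValueError(f"stenosis on unknown branch {spec.branch!r}")
        spec.validate(centerlines.branches[spec.branch])
    by_branch: dict[str, list[StenosisSpec]] = {}
    for spec in stenoses:
        by_branch.setdefault(spec.branch, []).append(spec)
    for branch, specs in by_branch.items():
        spans = sorted(s.span for s in specs)
        for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
            if b0 < a1:
                raise ValueError(f"overlapping stenoses on branch {branch}")

    rng = np.random.default_rng(seed)
    theta = 2 * np.pi * np.arange(n_theta) / n_theta

    lumen_tubes: dict[str, PolarTube] = {}
    healthy_tubes: dict[str, PolarTube] = {}
    comp_meshes: list[trimesh.Trimesh] = []
    fibrous_parts: list[trimesh.Trimesh] = []

    # deterministic branch order
    for name in sorted(centerlines.branches):
        branch = centerlines.branches[name]
        frame = branch.frame
        ns = int(round(branch.length / spacing)) + 1
        stations = np.linspace(0.0, branch.length, ns)
        r_base = _base_radius_field(rng, branch, stations, theta, noise_amplitude)
        r_sten = r_base.copy()
        for spec in by_branch.get(name, []):
            r_sten = r_sten * _stenosis_profile(spec, stations, theta)
        healthy_tubes[name] = PolarTube(frame, stations, r_base)
        lumen_tubes[name] = PolarTube(frame, stations, r_sten)

        # plaque components and ground-truth fibrous gap filler
        fib_regions = [None] * ns
        comp_regions_all: list[list] = []
        for spec in by_branch.get(name, []):
            comp_regions, _ = _component_regions(spec, stations, theta, r_base, r_sten)
            for cname, regions in comp_regions.items():
                live = [i for i, r in enumerate(regions) if r is not None]
                if not live:
                    continue
                mesh = region_stack_solid(
                    frame, stations, regions, pitch=component_pitch, name=cname
                )
                if len(mesh.faces) > 0:
                    comp_meshes.append(mesh)
                comp_regions_all.append(regions)
        if by_branch.get(name):
            for i in range(ns):
                gap = r_base[i] - r_sten[i]
                if gap.max() < 0.05:
                    continue
                outer = shapely.Polygon(
                    np.column_stack(
                        [r_base[i] * np.cos(theta), r_base[i] * np.sin(theta)]
                    )
                )
                inner = shapely.Polygon(
                    np.column_stack(
                        [r_sten[i] * np.cos(theta), r_sten[i] * np.sin(theta)]
                    )
                )
                region = shapely.make_valid(outer.difference(inner))
                for regions in comp_regions_all:
                    if regions[i] is not None:
                        region = region.difference(regions[i])
                region = shapely.make_valid(region)
                if not region.is_empty and region.area > 0.05:
                    fib_regions[i] = region
            if any(r is not None for r in fib_regions):
                fib = region_stack_solid(
                    frame, stations, fib_regions, pitch=component_pitch,
                    name="fibrous_reference",
                )
                if len(fib.faces) > 0:
                    fibrous_parts.append(fib)

    if len(lumen_tubes) == 1:
        (tube,) = lumen_tubes.values()
        lumen = tube.loft(name="lumen")
    else:
        lumen = tube_union_solid(
            list(lumen_tubes.values()), pitch=union_pitch, name="lumen"
        )

    if fibrous_parts:
        reference_fibrous = trimesh.util.concatenate(fibrous_parts)
        reference_fibrous.metadata["name"] = "fibrous_reference"
    else:
        reference_fibrous = empty_mesh("fibrous_reference")

    return Anatomy(
        lumen=lumen,
        components=comp_meshes,
        reference_fibrous=reference_fibrous,
        centerlines=centerlines,
        stenoses=stenoses,
        lumen_tubes=lumen_tubes,
        healthy_tubes=healthy_tubes,
        seed=seed,
    )
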