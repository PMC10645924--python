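import numpy as np
import pytest
import trimesh

from carotidfem.contours import (
    BranchFrame,
    ContourStack,
    equivalent_radius,
    polygon_area,
    polygon_centroid,
)
from carotidfem.meshops import PolarTube, is_watertight, loft_rings, slice_mesh
from carotidfem.reconstruction import (
    build_fibrous_component,
    build_healthy_lumen,
    build_wall_solid,
    drop_narrowed_sections,
    enlarge_section,
    loft_branch,
    merge_lumen_plaque,
    plaque_hull,
    slice_contours,
)
from carotidfem.spatial import points_in_mesh
from carotidfem.synthetic import Branch, CenterlineSet


def circle(r=2.0, n=64, center=(0.0, 0.0)):
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([center[0] + r * np.cos(th), center[1] + r * np.sin(th)])


def z_frame():
    return BranchFrame(origin=[0, 0, 0], axis=[0, 0, 1])


def cylinder_mesh(r, length, n=96, nz=21):
    frame = z_frame()
    rings = [frame.to_world(z, circle(r, n)) for z in np.linspace(0, length, nz)]
    return loft_rings(rings, cap=True)


def tube_centerlines(length=10.0, radius=2.0):
    return CenterlineSet({"CCA": Branch("CCA", [0, 0, 0], [0, 0, 1], length, radius)})


class TestPlaqueHull:
    def test_hull_of_convex_mesh_is_itself(self):
        sph = trimesh.creation.icosphere(3, radius=1.5)
        hull = plaque_hull([sph])
        assert hull.volume == pytest.approx(sph.volume, rel=1e-6)

    def test_hull_bridges_separated_components(self):
        a = trimesh.creation.box(extents=[1, 1, 1])
        b = trimesh.creation.box(extents=[1, 1, 1])
        b.apply_translation([3.0, 0, 0])
        hull = plaque_hull([a, b])
        assert hull.volume > 2.0

    def test_tetrahedron_volume_is_det_over_six(self):
        pts = np.array(
            [[0, 0, 0], [2, 0, 0], [0, 3, 0], [0, 0, 4]], dtype=float
        )
        tet = trimesh.Trimesh(vertices=pts, faces=[[0, 1, 2], [0, 1, 3], [0, 2, 3], [1, 2, 3]])
        hull = plaque_hull([tet])
        det = np.linalg.det(pts[1:] - pts[0])
        assert hull.volume == pytest.approx(abs(det) / 6.0, rel=1e-9)

    def test_coplanar_input_rejected(self):
        flat = trimesh.Trimesh(
            vertices=[[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]],
            faces=[[0, 1, 2], [1, 3, 2]],
        )
        with pytest.raises(ValueError, match="coplanar"):
            plaque_hull([flat])

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            plaque_hull([])


class TestSliceContours:
    def test_cylinder_sections_approach_circle_area(self):
        mesh = cylinder_mesh(2.0, 10.0, n=192)
        stack = slice_contours(mesh, tube_centerlines(), spacing=1.0)
        for poly in stack.polygons["CCA"]:
            assert polygon_area(poly) == pytest.approx(np.pi * 4, rel=0.01)

    def test_tangent_plane_section_dropped(self):
        sph = trimesh.creation.icosphere(3, radius=1.0)
        sph.apply_translation([0, 0, 5.0])
        polys = slice_mesh(sph, z_frame(), 4.0 + 1e-9, min_area=1e-2)
        # plane essentially tangent at the pole: nothing usable survives
        assert polys == []

    def test_bifurcated_plane_above_apex_yields_two_loops(self, bif_anatomy):
        bif = bif_anatomy.centerlines.bifurcation
        polys = slice_mesh(bif_anatomy.lumen, z_frame(), bif[2] + 8.0)
        assert len(polys) == 2

    def test_invalid_spacing_rejected(self):
        with pytest.raises(ValueError):
            slice_contours(cylinder_mesh(1, 5), tube_centerlines(), spacing=0.0)


class TestMergeAndEnlarge:
    def test_plaque_inside_lumen_hull_is_identity(self):
        lumen = circle(2.0)
        plaque = circle(0.5, center=(0.5, 0.0))
        merged = merge_lumen_plaque(lumen, [plaque])
        assert polygon_area(merged) == pytest.approx(polygon_area(lumen), rel=1e-6)

    def test_external_plaque_grows_the_hull(self):
        merged = merge_lumen_plaque(circle(2.0), [circle(0.8, center=(2.5, 0))])
        assert polygon_area(merged) > polygon_area(circle(2.0))

    def test_hull_matches_brute_force_support(self):
        rng = np.random.default_rng(2)
        pts = rng.uniform(-1, 1, (30, 2))
        merged = merge_lumen_plaque(circle(1.5, 32), [pts])
        cloud = np.vstack([circle(1.5, 32), pts])
        # brute force: every point inside; hull vertices are support points
        from shapely import Point, Polygon

        hull_poly = Polygon(merged)
        assert all(hull_poly.distance(Point(p)) < 1e-9 for p in cloud)
        # every hull vertex is a support point of the cloud in its
        # outward direction (exhaustive pairwise-support check)
        center = cloud.mean(axis=0)
        for v in merged:
            d = v - center
            assert (cloud @ d).max() <= v @ d + 1e-9

    def test_circle_30pct_rule(self):
        out, narrowed = enlarge_section(circle(2.0, 256), 2.6)
        assert not narrowed
        assert equivalent_radius(out) == pytest.approx(2.6, abs=1e-9)
        assert np.hypot(out[:, 0], out[:, 1]) == pytest.approx(2.6, rel=1e-4)

    def test_identity_when_target_equals_radius(self):
        c = circle(2.0, 128)
        out, narrowed = enlarge_section(c, equivalent_radius(c))
        assert not narrowed
        assert np.allclose(out, c, atol=1e-12)

    def test_noncircular_section_area_matches_target(self):
        th = np.linspace(0, 2 * np.pi, 256, endpoint=False)
        r = 2.0 * (1 + 0.25 * np.cos(2 * th))
        poly = np.column_stack([r * np.cos(th), r * np.sin(th)])
        out, _ = enlarge_section(poly, 3.1)
        assert abs(polygon_area(out)) == pytest.approx(np.pi * 3.1**2, rel=0.01)

    def test_smaller_target_flags_narrowed_without_shrinking(self):
        c = circle(2.0, 128)
        out, narrowed = enlarge_section(c, 1.5)
        assert narrowed
        assert equivalent_radius(out) == pytest.approx(equivalent_radius(c))

    def test_output_contains_input(self):
        poly = circle(1.8, 64, center=(0.3, -0.2))
        out, _ = enlarge_section(poly, 2.6)
        from shapely import Polygon

        assert Polygon(out).buffer(1e-9).contains(Polygon(poly))


def _stack_of_radii(radii, spacing=1.0):
    frame = z_frame()
    stack = ContourStack(frames={"CCA": frame}, spacing=spacing)
    for i, r in enumerate(radii):
        stack.add("CCA", i * spacing, circle(r, 48))
    return stack


class TestDropNarrowed:
    def test_monotone_taper_untouched(self):
        radii = np.linspace(3.0, 2.5, 8)
        out = drop_narrowed_sections(_stack_of_radii(radii))
        for r, poly in zip(radii, out.polygons["CCA"]):
            # rel 3e-3 absorbs the 48-gon area deficit vs the circle
            assert equivalent_radius(poly) == pytest.approx(r, rel=3e-3)

    def test_dipping_station_removed_and_refilled(self):
        radii = np.full(9, 3.0)
        radii[4] = 2.4  # 20% below the neighbour interpolation
        out = drop_narrowed_sections(_stack_of_radii(radii))
        assert equivalent_radius(out.polygons["CCA"][4]) == pytest.approx(3.0, rel=3e-3)
        assert len(out.polygons["CCA"]) == 9  # original spacing preserved

    def test_idempotent(self):
        radii = np.full(9, 3.0)
        radii[4] = 2.4
        once = drop_narrowed_sections(_stack_of_radii(radii))
        twice = drop_narrowed_sections(once)
        for a, b in zip(once.polygons["CCA"], twice.polygons["CCA"]):
            assert np.allclose(a, b, atol=1e-9)

    def test_flagged_station_removed(self):
        radii = np.full(7, 3.0)
        out = drop_narrowed_sections(_stack_of_radii(radii), flagged={"CCA": [3]})
        assert equivalent_radius(out.polygons["CCA"][3]) == pytest.approx(3.0, rel=3e-3)

    def test_too_few_stations_rejected(self):
        with pytest.raises(ValueError):
            drop_narrowed_sections(_stack_of_radii([3.0]))


class TestLoft:
    def test_cylinder_volume(self):
        stack = _stack_of_radii(np.full(11, 2.0), spacing=0.5)
        mesh = loft_branch(stack)
        assert is_watertight(mesh)
        assert mesh.volume == pytest.approx(np.pi * 4 * 5.0, rel=0.01)

    def test_identical_contours_make_an_extrusion(self):
        stack = _stack_of_radii(np.full(5, 1.5), spacing=1.0)
        mesh = loft_branch(stack)
        for z in (0.5, 1.5, 2.5):
            polys = slice_mesh(mesh, z_frame(), z)
            assert len(polys) == 1
            assert polygon_area(polys[0]) == pytest.approx(np.pi * 1.5**2, rel=0.01)

    def test_union_of_overlapping_tubes_is_watertight(self):
        f1 = z_frame()
        f2 = BranchFrame(origin=[0, 0, 4], axis=[0.35, 0, 0.94])
        t1 = PolarTube(f1, np.linspace(0, 8, 9), np.full((9, 48), 2.0))
        t2 = PolarTube(f2, np.linspace(0, 6, 7), np.full((7, 48), 1.6))
        stack = ContourStack(frames={"CCA": f1, "ICA": f2}, spacing=1.0)
        for s, p in zip(t1.stations, t1.radii):
            stack.add("CCA", s, circle(p[0], 48))
        for s, p in zip(t2.stations, t2.radii):
            stack.add("ICA", s, circle(p[0], 48))
        mesh = loft_branch(stack)
        assert is_watertight(mesh)


class TestWallSolid:
    def test_concentric_cylinder_annulus_volume(self):
        inner = cylinder_mesh(2.0, 10.0)
        outer = cylinder_mesh(2.6, 10.0)
        wall = build_wall_solid(inner, outer, tube_centerlines())
        assert is_watertight(wall)
        analytic = np.pi * (2.6**2 - 2.0**2) * 10.0
        # sections span [0.15, L-0.15]: compare over the meshed span
        meshed = analytic * (10.0 - 0.3) / 10.0
        assert wall.volume == pytest.approx(meshed, rel=0.01)

    def test_volume_additivity(self, tube_anatomy, tube_wall):
        wm = tube_wall
        assert wm.wall_solid.volume + wm.inner.volume == pytest.approx(
            wm.outer.volume, rel=0.01
        )

    def test_intersecting_surfaces_rejected(self):
        inner = cylinder_mesh(2.0, 10.0)
        with pytest.raises(ValueError, match="not strictly inside"):
            build_wall_solid(inner, inner, tube_centerlines())


class TestHealthyLumenAndFibrous:
    def test_inverse_shrink_rule(self):
        stack = _stack_of_radii(np.full(6, 2.6), spacing=1.0)
        healthy = build_healthy_lumen(stack)
        polys = slice_mesh(healthy, z_frame(), 2.5)
        assert equivalent_radius(polys[0]) == pytest.approx(2.0, rel=0.005)

    def test_healthy_matches_lumen_without_stenosis(self, healthy_tube_anatomy):
        from carotidfem.reconstruction import reconstruct_wall

        wm = reconstruct_wall(
            healthy_tube_anatomy.lumen, [], healthy_tube_anatomy.centerlines
        )
        assert len(wm.fibrous.faces) == 0
        diff = abs(wm.healthy_lumen.volume - healthy_tube_anatomy.lumen.volume)
        assert diff / healthy_tube_anatomy.lumen.volume < 0.02

    def test_healthy_contains_stenotic(self, tube_anatomy, tube_wall):
        rng = np.random.default_rng(5)
        lo, hi = tube_anatomy.lumen.bounds
        cand = rng.uniform(lo, hi, (4000, 3))
        pts = cand[points_in_mesh(tube_anatomy.lumen, cand)][:400]
        inside = points_in_mesh(tube_wall.healthy_lumen, pts)
        from carotidfem.spatial import nearest_on_surface

        if not inside.all():
            d, _, _ = nearest_on_surface(tube_wall.healthy_lumen, pts[~inside])
            assert d.max() < 0.25  # within one extraction cell

    def test_annular_stenosis_closed_form(self):
        # concentric cylinders: fibrous = pi (rh^2 - rs^2) * extent
        rh, rs, L = 2.0, 1.5, 10.0
        healthy = cylinder_mesh(rh, L)
        sten = cylinder_mesh(rs, L)
        fib = build_fibrous_component(healthy, sten, [], tube_centerlines(L, rh))
        analytic = np.pi * (rh**2 - rs**2) * L
        meshed = analytic * (L - 0.35) / L  # section margin at the caps
        assert is_watertight(fib)
        assert fib.volume == pytest.approx(meshed, rel=0.02)

    def test_fibrous_set_algebra(self, tube_anatomy, tube_wall):
        wm = tube_wall
        gap = wm.healthy_lumen.volume - wm.inner.volume
        comp = sum(c.volume for c in tube_anatomy.components)
        assert wm.fibrous.volume <= gap + 0.02 * wm.healthy_lumen.volume
        assert wm.fibrous.volume + comp <= gap + 0.05 * wm.healthy_lumen.volume

    def test_no_stenosis_empty_fibrous(self):
        healthy = cylinder_mesh(2.0, 8.0)
        fib = build_fibrous_component(healthy, healthy, [], tube_centerlines(8.0))
        assert len(fib.faces) == 0
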