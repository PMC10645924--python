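import numpy as np
import pytest
import trimesh
from hypothesis import given, settings
from hypothesis import strategies as st

from carotidfem.discretization import SUBSETS
from carotidfem.fem import StressField
from carotidfem.postprocess import (
    DistanceReport,
    PressureRecord,
    composition_percentages,
    differential_pressure,
    fc_thickness,
    percentage_difference,
    sensitivity_sweep,
    signed_distance_report,
    vm99,
    volume_stress_curve,
)


def field_of(vm_kpa, volumes, label="fibrous"):
    vm = np.asarray(vm_kpa, dtype=float) * 1e-3  # kPa -> MPa storage
    volumes = np.asarray(volumes, dtype=float)
    n = len(vm)
    cent = np.column_stack([np.zeros(n), np.zeros(n), np.arange(n, dtype=float)])
    labels = np.full(n, SUBSETS.index(label), dtype=np.int8)
    return StressField(vm=vm, volume=volumes, centroid=cent, labels=labels)


class TestDifferentialPressure:
    @pytest.mark.parametrize(
        "ps,pd,expected",
        [(161.5, 73.0, 88.5), (148.5, 80.0, 68.5), (124.4, 93.0, 31.4)],
    )
    def test_clinical_worked_examples(self, ps, pd, expected):
        assert differential_pressure(ps, pd) == pytest.approx(expected, abs=1e-12)

    def test_equal_pressures_give_zero(self):
        assert differential_pressure(120.0, 120.0) == 0.0

    def test_reversed_pressures_rejected(self):
        with pytest.raises(ValueError):
            differential_pressure(70.0, 80.0)

    def test_record_invariants(self):
        r = PressureRecord(1, 161.5, 73.0)
        assert r.differential == pytest.approx(88.5)
        with pytest.raises(ValueError):
            PressureRecord(1, 73.0, 161.5)


class TestVolumeStressCurve:
    def test_hand_enumerated_two_elements(self):
        curve = volume_stress_curve(field_of([2.0, 1.0], [1.0, 3.0]))
        assert curve.stresses == pytest.approx([1.0, 2.0])
        assert curve.cumulative_volume == pytest.approx([0.75, 1.0])

    def test_uniform_stress_is_a_step(self):
        curve = volume_stress_curve(field_of([5.0] * 4, [1.0] * 4))
        assert np.all(curve.stresses == 5.0)
        assert curve.cumulative_volume[-1] == 1.0

    def test_final_volume_is_exactly_one(self):
        rng = np.random.default_rng(0)
        curve = volume_stress_curve(
            field_of(rng.uniform(1, 50, 200), rng.uniform(0.1, 2, 200))
        )
        assert curve.cumulative_volume[-1] == 1.0
        assert np.all(np.diff(curve.stresses) >= 0)
        assert np.all(np.diff(curve.cumulative_volume) > 0)

    def test_empty_subset_rejected(self):
        with pytest.raises(ValueError):
            volume_stress_curve(field_of([1.0], [1.0], label="wall"), subset="fibrous")


class TestVM99:
    def test_single_element(self):
        assert vm99(field_of([7.0], [2.0])).vm99_kpa == pytest.approx(7.0)

    def test_hundred_equal_volumes(self):
        r = vm99(field_of(np.arange(1.0, 101.0), np.ones(100)))
        assert r.vm99_kpa == pytest.approx(99.0)

    def test_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            n = rng.integers(1, 60)
            vm = rng.uniform(0, 100, n)
            vol = rng.uniform(0.01, 5, n)
            r = vm99(field_of(vm, vol))
            order = np.argsort(vm, kind="stable")
            cum = np.cumsum(vol[order])
            expect = next(
                vm[order[i]] for i in range(n) if cum[i] >= 0.99 * cum[-1] - 1e-12
            )
            assert r.vm99_kpa == pytest.approx(expect)

    def test_scaling_property(self):
        rng = np.random.default_rng(3)
        vm = rng.uniform(1, 30, 50)
        vol = rng.uniform(0.1, 2, 50)
        base = vm99(field_of(vm, vol)).vm99_kpa
        scaled = vm99(field_of(3.5 * vm, vol)).vm99_kpa
        assert scaled == pytest.approx(3.5 * base, rel=1e-12)

    def test_curve_and_field_paths_agree(self):
        rng = np.random.default_rng(9)
        f = field_of(rng.uniform(0, 40, 300), rng.uniform(0.05, 1, 300))
        r = vm99(f)
        curve = volume_stress_curve(f)
        i = int(np.searchsorted(curve.cumulative_volume, 0.99 - 1e-12))
        assert curve.stresses[i] == pytest.approx(r.vm99_kpa)

    def test_reports_element_centroid_station(self):
        r = vm99(field_of([1.0, 2.0, 50.0], [1.0, 1.0, 1.0]))
        assert r.z_station == pytest.approx(r.centroid[2])

    @given(
        st.lists(st.floats(0.1, 100.0), min_size=1, max_size=40),
        st.floats(0.05, 20.0),
    )
    @settings(deadline=None, max_examples=60, derandomize=True)
    def test_scale_equivariance_property(self, vms, c):
        """Order-preserving positive scaling commutes with VM_99 even in
        the presence of ties (stable ordering keeps the same element)."""
        vol = np.ones(len(vms))
        base = vm99(field_of(vms, vol)).vm99_kpa
        scaled = vm99(field_of(np.asarray(vms) * c, vol)).vm99_kpa
        assert scaled == pytest.approx(c * base, rel=1e-9)

    @given(
        st.lists(
            st.tuples(st.floats(0.0, 50.0), st.floats(0.01, 3.0)),
            min_size=1,
            max_size=40,
        )
    )
    @settings(deadline=None, max_examples=60, derandomize=True)
    def test_vm99_bounds_property(self, pairs):
        """VM_99 lies within the stress range and at least 99% of the
        subset volume is at or below it."""
        vm = np.array([p[0] for p in pairs])
        vol = np.array([p[1] for p in pairs])
        r = vm99(field_of(vm, vol))
        assert vm.min() - 1e-9 <= r.vm99_kpa <= vm.max() + 1e-9
        covered = vol[vm <= r.vm99_kpa / 1.0 + 1e-12].sum()
        assert covered >= 0.99 * vol.sum() - 1e-9


class TestComposition:
    def test_simple_fractions(self):
        out = composition_percentages({"calcific": 1.0, "lipid": 1.0, "fibrous": 2.0})
        assert (out["calcific"], out["lipid"], out["fibrous"]) == (25.0, 25.0, 50.0)

    def test_single_component(self):
        out = composition_percentages({"calcific": 3.0, "lipid": 0.0, "fibrous": 0.0})
        assert out == {"calcific": 100.0, "lipid": 0.0, "fibrous": 0.0}

    def test_normalization(self):
        rng = np.random.default_rng(1)
        v = dict(zip(("calcific", "lipid", "fibrous"), rng.uniform(0.1, 9, 3)))
        assert sum(composition_percentages(v).values()) == pytest.approx(100.0, abs=0.01)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            composition_percentages({"calcific": 0.0})


class TestPercentageDifference:
    def test_reported_volume_comparison(self):
        assert percentage_difference(174.54, 92.65) == pytest.approx(88.39, abs=0.005)

    def test_reported_vm99_comparison(self):
        assert percentage_difference(41.14, 37.85) == pytest.approx(8.69, abs=0.005)

    def test_identity(self):
        assert percentage_difference(3.7, 3.7) == 0.0

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            percentage_difference(1.0, 0.0)


def brute_force_signed(reference, proposed):
    """Independent oracle: all-pairs vertex/edge/face distances plus a
    z-ray parity sign, formulated differently from the implementation."""
    tri = np.asarray(proposed.vertices)[np.asarray(proposed.faces)]
    out = np.empty(len(reference.vertices))
    for i, p in enumerate(np.asarray(reference.vertices)):
        cands = [np.linalg.norm(tri.reshape(-1, 3) - p, axis=1).min()]
        for e0, e1 in ((0, 1), (1, 2), (2, 0)):
            a, b = tri[:, e0], tri[:, e1]
            ab = b - a
            t = np.clip(
                np.einsum("ij,ij->i", p - a, ab) / np.einsum("ij,ij->i", ab, ab),
                0, 1,
            )
            cands.append(np.linalg.norm(a + t[:, None] * ab - p, axis=1).min())
        n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        nn = np.linalg.norm(n, axis=1)
        ok = nn > 1e-14
        nh = n[ok] / nn[ok][:, None]
        dplane = np.einsum("ij,ij->i", p - tri[ok, 0], nh)
        foot = p - dplane[:, None] * nh
        # barycentric inside test
        v0 = tri[ok, 1] - tri[ok, 0]
        v1 = tri[ok, 2] - tri[ok, 0]
        v2 = foot - tri[ok, 0]
        d00 = np.einsum("ij,ij->i", v0, v0)
        d01 = np.einsum("ij,ij->i", v0, v1)
        d11 = np.einsum("ij,ij->i", v1, v1)
        d20 = np.einsum("ij,ij->i", v2, v0)
        d21 = np.einsum("ij,ij->i", v2, v1)
        den = d00 * d11 - d01 * d01
        v = (d11 * d20 - d01 * d21) / den
        w = (d00 * d21 - d01 * d20) / den
        inside = (v >= -1e-12) & (w >= -1e-12) & (v + w <= 1 + 1e-12)
        if inside.any():
            cands.append(np.abs(dplane[inside]).min())
        d = min(cands)
        # z-ray crossings for the sign
        crossings = 0
        for t3 in tri:
            n3 = np.cross(t3[1] - t3[0], t3[2] - t3[0])
            if abs(n3[2]) < 1e-14:
                continue
            tz = np.dot(t3[0] - p, n3) / n3[2]
            if tz <= 1e-12:
                continue
            q = p + np.array([0, 0, tz])
            s0 = np.cross(t3[1] - t3[0], q - t3[0])[2] * np.sign(n3[2])
            s1 = np.cross(t3[2] - t3[1], q - t3[1])[2] * np.sign(n3[2])
            s2 = np.cross(t3[0] - t3[2], q - t3[2])[2] * np.sign(n3[2])
            if s0 >= 0 and s1 >= 0 and s2 >= 0:
                crossings += 1
        out[i] = -d if crossings % 2 == 1 else d
    return out


class TestSignedDistanceReport:
    def test_identical_meshes_report_zero(self):
        m = trimesh.creation.icosphere(2, radius=1.5)
        rep = signed_distance_report(m, m)
        assert rep.mean == pytest.approx(0.0, abs=1e-9)
        assert rep.sd == pytest.approx(0.0, abs=1e-9)

    def test_concentric_spheres_offset(self):
        ref = trimesh.creation.icosphere(3, radius=2.0)
        prop = trimesh.creation.icosphere(3, radius=1.0)
        rep = signed_distance_report(ref, prop)
        assert rep.mean == pytest.approx(1.0, abs=0.02)  # reference outside
        swapped = signed_distance_report(prop, ref)
        assert swapped.mean == pytest.approx(-1.0, abs=0.02)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        prop = trimesh.creation.icosphere(1, radius=1.2)
        prop.apply_translation(rng.uniform(-0.3, 0.3, 3))
        ref = trimesh.creation.icosphere(1, radius=1.5)
        rep = signed_distance_report(ref, prop)
        oracle = brute_force_signed(ref, prop)
        assert np.allclose(rep.distances, oracle, atol=1e-9)
        assert rep.p5 == pytest.approx(np.percentile(oracle, 5))
        assert rep.p95 == pytest.approx(np.percentile(oracle, 95))

    def test_open_proposed_rejected(self):
        ref = trimesh.creation.icosphere(1)
        open_mesh = trimesh.Trimesh(
            vertices=[[0, 0, 0], [1, 0, 0], [0, 1, 0]], faces=[[0, 1, 2]]
        )
        with pytest.raises(ValueError, match="watertight"):
            signed_distance_report(ref, open_mesh)


class TestFCThickness:
    def _annular_meshes(self, r_lumen, r_lipid_in, r_lipid_out=None):
        from carotidfem.contours import BranchFrame
        from carotidfem.meshops import PolarTube, annular_loft

        frame = BranchFrame(origin=[0, 0, 0], axis=[0, 0, 1])
        st = np.linspace(0, 10, 21)
        lumen = PolarTube(frame, st, np.full((21, 96), r_lumen)).loft()
        r_out = r_lipid_out or r_lipid_in + 0.3
        inner = PolarTube(frame, st, np.full((21, 96), r_lipid_in)).rings()
        outer = PolarTube(frame, st, np.full((21, 96), r_out)).rings()
        lipid = annular_loft(inner, outer)
        return lumen, lipid

    def _result_at(self, z):
        from carotidfem.postprocess import VM99Result

        return VM99Result(10.0, 0, np.array([3.2, 0.0, z]), z)

    def test_concentric_annulus_gap(self):
        lumen, lipid = self._annular_meshes(3.0, 3.5)
        t = fc_thickness(self._result_at(5.0), lumen, lipid)
        assert t == pytest.approx(0.5, abs=0.02)

    def test_no_lipid_marks_not_applicable(self):
        lumen, _ = self._annular_meshes(3.0, 3.5)
        assert fc_thickness(self._result_at(5.0), lumen, None) is None

    def test_no_lipid_on_plane_marks_not_applicable(self):
        lumen, lipid = self._annular_meshes(3.0, 3.5)
        assert fc_thickness(self._result_at(20.0), lumen, lipid) is None

    def test_touching_contours_give_zero(self):
        lumen, lipid = self._annular_meshes(3.0, 3.0)
        t = fc_thickness(self._result_at(5.0), lumen, lipid)
        assert t == pytest.approx(0.0, abs=0.02)


@pytest.fixture(scope="module")
def small_model():
    from carotidfem.discretization import tube_wall_mesh

    mesh = tube_wall_mesh(2.0, 2.6, 3.0, size=0.55)
    # label the mid-span band as fibrous
    z = mesh.centroids[:, 2]
    mesh.labels = np.where(
        (z > 1.0) & (z < 2.0), SUBSETS.index("fibrous"), SUBSETS.index("wall")
    ).astype(np.int8)
    from carotidfem.fem import LoadCase, MaterialTable

    mat = MaterialTable(
        young_kpa={"calcific": 20000.0, "lipid": 4.0, "fibrous": 400.0, "wall": 550.0},
        poisson=0.49,
    )
    return mesh, mat, LoadCase(88.5, ("cca_end", "ica_end"))


class TestSensitivitySweep:
    def test_unit_multiplier_reproduces_baseline(self, small_model):
        mesh, mat, load = small_model
        out = sensitivity_sweep(mesh, mat, load, multipliers=(1.0, 1.0))
        vals = [v["vm99"].vm99_kpa for v in out.values()]
        assert vals[0] == vals[-1]

    def test_modulus_changes_stress_continuously(self, small_model):
        mesh, mat, load = small_model
        mults = (1.1, 1.3, 1.375, 1.45, 1.5)
        out = sensitivity_sweep(mesh, mat, load, multipliers=mults)
        vals = np.array([out[m]["vm99"].vm99_kpa for m in mults])
        # no discontinuity where E_fibrous crosses E_wall (linear systems
        # depend continuously on their coefficients)
        rel_steps = np.abs(np.diff(vals)) / vals[:-1]
        assert rel_steps.max() < 0.15

    def test_empty_fibrous_subset_is_inert(self, small_model):
        mesh, mat, load = small_model
        import copy

        m2 = copy.deepcopy(mesh)
        m2.labels = np.zeros(len(m2.tets), dtype=np.int8)  # all wall
        out = sensitivity_sweep(m2, mat, load, multipliers=(0.5, 1.0, 1.5))
        vals = [v["vm99"].vm99_kpa for v in out.values()]
        assert vals[0] == vals[1] == vals[2]
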