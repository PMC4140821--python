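import numpy as np
import pytest

from mpn_integrator import errors
from mpn_integrator._geometry import fibonacci_sphere, random_rotation
from mpn_integrator.interface_metrics import (
    PROBE_RADIUS,
    VDW_RADII,
    buried_area,
    contact_pairs,
    interface_residues,
    sasa,
    sc_from_dots,
    shape_complementarity,
    surface_dots,
)
from mpn_integrator.structure_io import Atom, Residue, Structure


def single_atom(element="C", xyz=(0, 0, 0), chain="A", seq=1):
    s = Structure(f"atom_{chain}{seq}")
    s.add_residue(Residue(chain, seq, "GLY", [Atom("X1", element, list(xyz))]))
    return s


class TestSasa:
    def test_isolated_sphere_closed_form(self):
        r = sasa(single_atom("C"))
        expected = 4 * np.pi * (VDW_RADII["C"] + PROBE_RADIUS) ** 2
        assert r.total == pytest.approx(expected, rel=1e-12)

    def test_two_distant_atoms_additive(self):
        s = single_atom("C")
        s.add_residue(Residue("A", 2, "GLY", [Atom("X1", "C", [100.0, 0, 0])]))
        one = sasa(single_atom("C")).total
        assert sasa(s).total == pytest.approx(2 * one, rel=1e-12)

    def test_total_is_sum_of_per_atom(self, single_helix):
        r = sasa(single_helix, n_points=240)
        assert r.total == pytest.approx(r.per_atom.sum(), abs=1e-6)
        assert r.total == pytest.approx(sum(r.per_residue.values()), abs=1e-6)
        assert np.all(r.per_atom >= 0)

    def test_rotation_translation_invariance(self, single_helix):
        rng = np.random.default_rng(11)
        moved = single_helix.transformed(random_rotation(rng), rng.normal(size=3) * 15)
        a = sasa(single_helix, n_points=240)
        b = sasa(moved, n_points=240)
        assert b.total == pytest.approx(a.total, rel=1e-6)

    def test_unknown_element_with_no_default_radius(self):
        s = single_atom("J")  # not in the radius table
        with pytest.raises(errors.RadiusError, match="J"):
            sasa(s, default_radius=None)
        assert sasa(s).total > 0  # default radius applies otherwise


def test_sasa_matches_dense_sampling_oracle(single_helix):
    """Per-atom areas at matched density agree with an independent
    brute-force Shrake–Rupley using a rotated 10,000-point set."""
    from mpn_integrator.structure_io import select

    helix = select(single_helix, "A", (1, 5))
    r = sasa(helix, n_points=10000)
    coords = helix.coords(heavy_only=True)
    radii = np.array([VDW_RADII["C"]] * len(coords)) + PROBE_RADIUS
    pts0 = fibonacci_sphere(10000) @ random_rotation(np.random.default_rng(42)).T
    oracle = []
    for i in range(len(coords)):
        pts = coords[i] + radii[i] * pts0
        acc = 0
        for p in pts:
            if all(
                np.dot(p - coords[j], p - coords[j]) >= radii[j] ** 2
                for j in range(len(coords))
                if j != i
            ):
                acc += 1
        oracle.append(acc / 10000 * 4 * np.pi * radii[i] ** 2)
    np.testing.assert_allclose(r.per_atom, oracle, rtol=0.01)


class TestBuriedArea:
    def test_distant_partners_bury_nothing(self):
        a = single_atom("C", (0, 0, 0), "A")
        b = single_atom("C", (100, 0, 0), "B")
        assert buried_area(a, b) == pytest.approx(0.0, abs=0.1)

    def test_two_sphere_closed_form(self):
        """Touching single-atom partners: buried area equals the analytic
        spherical-cap occlusion of the two probe-extended spheres."""
        d = 3.0
        a = single_atom("C", (0, 0, 0), "A")
        b = single_atom("C", (d, 0, 0), "B")
        R = VDW_RADII["C"] + PROBE_RADIUS
        h = R - (d**2) / (2 * d)  # equal radii
        cap_both = 2 * (2 * np.pi * R * h)
        assert buried_area(a, b, n_points=4000) == pytest.approx(cap_both, rel=0.02)

    def test_symmetry(self, docking_pair):
        from mpn_integrator.structure_io import apply_pose

        rec, lig, native = docking_pair
        posed = apply_pose(lig, native)
        ab = buried_area(rec, posed, n_points=240)
        ba = buried_area(posed, rec, n_points=240)
        assert ab == pytest.approx(ba, abs=1e-6)
        assert ab > 0


class TestContacts:
    def test_brute_force_pair_loop_oracle(self):
        a = Structure("a")
        a.add_residue(Residue("A", 1, "GLY", [Atom("CA", "C", [0, 0, 0]), Atom("CB", "C", [1.5, 0, 0])]))
        b = Structure("b")
        b.add_residue(Residue("B", 1, "GLY", [Atom("CA", "C", [3.0, 0, 0]), Atom("CB", "C", [9.0, 0, 0])]))
        mat, total = contact_pairs(a, b, cutoff=5.0)
        # exhaustive loop
        ca = [np.array([0, 0, 0]), np.array([1.5, 0, 0])]
        cb = [np.array([3.0, 0, 0]), np.array([9.0, 0, 0])]
        expected = sum(1 for x in ca for y in cb if np.linalg.norm(x - y) <= 5.0)
        assert total == expected == mat.to_numpy().sum()

    def test_distant_and_zero_cutoff_give_empty_matrix(self, docking_pair):
        from mpn_integrator.structure_io import apply_pose

        rec, lig, native = docking_pair
        far = apply_pose(lig, native).transformed(np.eye(3), [100.0, 0, 0])
        assert contact_pairs(rec, far, 5.0)[1] == 0
        assert contact_pairs(rec, apply_pose(lig, native), 0.0)[1] == 0


class TestInterfaceResidues:
    def test_separated_partners_empty(self):
        a = single_atom("C", (0, 0, 0), "A")
        b = single_atom("C", (100, 0, 0), "B")
        sa, sb = interface_residues(a, b)
        assert sa == set() and sb == set()

    def test_union_rule_matches_component_sets(self, docking_pair):
        from mpn_integrator.interface_metrics import per_residue_dsasa
        from mpn_integrator.structure_io import apply_pose

        rec, lig, native = docking_pair
        posed = apply_pose(lig, native)
        sa, sb = interface_residues(rec, posed, dsasa_min=1.0, contact_cutoff=5.0, n_points=240)
        da, db = per_residue_dsasa(rec, posed, n_points=240)
        mat, _ = contact_pairs(rec, posed, 5.0)
        arr = mat.to_numpy()
        dsasa_a = {k for k, v in da.items() if v > 1.0}
        touch_a = {k for i, k in enumerate(mat.index) if arr[i].any()}
        assert sa == dsasa_a | touch_a
        dsasa_b = {k for k, v in db.items() if v > 1.0}
        touch_b = {k for j, k in enumerate(mat.columns) if arr[:, j].any()}
        assert sb == dsasa_b | touch_b
        assert sa and sb


class TestShapeComplementarity:
    def test_coincident_antiparallel_dots_score_one(self):
        rng = np.random.default_rng(0)
        dots = rng.normal(size=(50, 3))
        normals = rng.normal(size=(50, 3))
        normals /= np.linalg.norm(normals, axis=1, keepdims=True)
        assert sc_from_dots(dots, normals, dots, -normals) == pytest.approx(1.0)

    def test_tangent_point_spheres(self):
        # single coincident dot with antiparallel normals, as at a tangent point
        d = np.array([[0.0, 0.0, 0.0]])
        n = np.array([[0.0, 0.0, 1.0]])
        assert sc_from_dots(d, n, d, -n) == pytest.approx(1.0)

    def test_formula_oracle_on_random_rough_interface(self):
        rng = np.random.default_rng(1)
        da = rng.normal(size=(40, 3))
        db = da + rng.normal(size=(40, 3)) * 0.3
        na = rng.normal(size=(40, 3))
        na /= np.linalg.norm(na, axis=1, keepdims=True)
        nb = rng.normal(size=(40, 3))
        nb /= np.linalg.norm(nb, axis=1, keepdims=True)
        got = sc_from_dots(da, na, db, nb, w=0.5)
        # direct re-implementation of the statistic
        from scipy.spatial import cKDTree

        def side(d1, n1, d2, n2):
            dist, idx = cKDTree(d2).query(d1)
            return np.median(
                [np.dot(n1[i], -n2[idx[i]]) * np.exp(-0.5 * dist[i] ** 2) for i in range(len(d1))]
            )

        expected = 0.5 * (side(da, na, db, nb) + side(db, nb, da, na))
        assert got == pytest.approx(expected, abs=1e-9)
        assert -1.0 <= got <= 1.0

    def test_sc_invariant_under_rigid_transform_of_complex(self, docking_pair):
        from mpn_integrator.structure_io import apply_pose

        rec, lig, native = docking_pair
        posed = apply_pose(lig, native)
        base = shape_complementarity(rec, posed, n_points=240)
        rng = np.random.default_rng(4)
        R, t = random_rotation(rng), rng.normal(size=3) * 10
        assert shape_complementarity(
            rec.transformed(R, t), posed.transformed(R, t), n_points=240
        ) == pytest.approx(base, abs=1e-9)

    def test_untouching_partners_undefined(self):
        a = single_atom("C", (0, 0, 0), "A")
        b = single_atom("C", (50, 0, 0), "B")
        with pytest.raises(errors.UndefinedInterfaceError):
            shape_complementarity(a, b)


def test_surface_dots_outward_normals(single_helix):
    dots, normals = surface_dots(single_helix, n_points=120)
    assert len(dots) == len(normals) > 0
    np.testing.assert_allclose(np.linalg.norm(normals, axis=1), 1.0, atol=1e-12)
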