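import numpy as np
import pytest

from mpn_integrator import errors
from mpn_integrator._geometry import random_rotation
from mpn_integrator.crosslinks import CrossLink
from mpn_integrator.density import simulate_map
from mpn_integrator.refine import (
    assess_model,
    enm_modes,
    flexible_fit,
    mode_displacement,
)
from mpn_integrator.structure_io import Atom, Residue, Structure
from mpn_integrator.synthetic_data import make_synthetic_links


def bead_chain(positions):
    s = Structure("beads")
    for i, p in enumerate(positions, start=1):
        s.add_residue(Residue("A", i, "ALA", [Atom("CA", "C", p)]))
    return s


class TestEnm:
    def test_connected_network_has_exactly_six_zero_modes(self, single_helix):
        e = enm_modes(single_helix)
        assert e.n_rigid_modes() == 6
        assert e.eigenvalues[6] > 1e-6 * e.eigenvalues.max()

    def test_modes_orthonormal(self, single_helix):
        e = enm_modes(single_helix, n_modes=10)
        gram = e.modes.T @ e.modes
        np.testing.assert_allclose(gram, np.eye(gram.shape[0]), atol=1e-8)

    def test_eigenvalues_nonnegative_ascending(self, single_helix):
        e = enm_modes(single_helix)
        assert np.all(e.eigenvalues >= 0)
        assert np.all(np.diff(e.eigenvalues) >= -1e-10)

    def test_mode7_orthogonal_to_rigid_modes(self, single_helix):
        e = enm_modes(single_helix)
        for k in range(6):
            assert abs(e.modes[:, 6] @ e.modes[:, k]) < 1e-8

    def test_four_bead_chain_matches_dense_hand_hessian(self):
        pos = np.array([[0.0, 0, 0], [4.0, 0.3, 0], [8.0, 0, 0.4], [12.0, 0.2, 0.1]])
        s = bead_chain(pos)
        e = enm_modes(s, cutoff=5.0)
        # independent dense Hessian build + eigensolve
        n = 4
        H = np.zeros((3 * n, 3 * n))
        for i in range(n):
            for j in range(i + 1, n):
                d = pos[j] - pos[i]
                if np.linalg.norm(d) <= 5.0:
                    blk = -np.outer(d, d) / (d @ d)
                    H[3 * i:3 * i + 3, 3 * j:3 * j + 3] += blk
                    H[3 * j:3 * j + 3, 3 * i:3 * i + 3] += blk
                    H[3 * i:3 * i + 3, 3 * i:3 * i + 3] -= blk
                    H[3 * j:3 * j + 3, 3 * j:3 * j + 3] -= blk
        expected = np.sort(np.linalg.eigvalsh(H))
        np.testing.assert_allclose(e.eigenvalues, np.maximum(expected, 0.0), atol=1e-9)

    def test_disconnected_network_reports_components(self):
        pos = [[0.0, 0, 0], [4.0, 0, 0], [100.0, 0, 0], [104.0, 0, 0]]
        with pytest.raises(errors.ConnectivityError, match="2 components"):
            enm_modes(bead_chain(np.array(pos)), cutoff=8.0)


class TestModeDisplacement:
    def test_sums_to_one(self, single_helix):
        e = enm_modes(single_helix)
        d = mode_displacement(e, 7)
        assert d.sum() == pytest.approx(1.0, abs=1e-12)

    def test_rigid_mode_warns(self, single_helix):
        e = enm_modes(single_helix)
        with pytest.warns(UserWarning, match="rigid-body"):
            mode_displacement(e, 1)

    def test_profile_invariant_to_global_rotation(self, single_helix):
        rng = np.random.default_rng(8)
        rotated = single_helix.transformed(random_rotation(rng), np.zeros(3))
        d1 = mode_displacement(enm_modes(single_helix), 7)
        d2 = mode_displacement(enm_modes(rotated), 7)
        np.testing.assert_allclose(d1, d2, atol=1e-6)

    def test_out_of_range_rejected(self, single_helix):
        e = enm_modes(single_helix, n_modes=5)
        with pytest.raises(errors.ParameterError):
            mode_displacement(e, 0)


class TestFlexibleFit:
    def test_fixed_point_at_own_map_with_satisfied_links(self, toy_assembly):
        m = simulate_map(toy_assembly, 10.0, 3.0, pad=12.0)
        links = make_synthetic_links(toy_assembly, n=8, d_max=35.0, seed=0)
        trace = flexible_fit(toy_assembly, m, links, cycles=50)
        motion = np.linalg.norm(
            trace.final_model.coords() - toy_assembly.coords(), axis=1
        ).max()
        assert motion < 0.01
        assert trace.ccc[0] > 0.999

    def test_energy_trace_non_increasing(self, toy_assembly, tiny_displaced):
        pert, m, links = tiny_displaced
        trace = flexible_fit(pert, m, links, cycles=100)
        assert np.all(np.diff(np.array(trace.energies)) <= 1e-9)
        assert len(trace.energies) <= 102

    def test_zero_weights_rejected(self, toy_assembly):
        m = simulate_map(toy_assembly, 10.0, 3.0)
        with pytest.raises(errors.ParameterError):
            flexible_fit(toy_assembly, m, [], weights={"w_e": 0, "w_x": 0, "w_m": 0})

    def test_unmappable_links_rejected(self, toy_assembly):
        m = simulate_map(toy_assembly, 10.0, 3.0)
        with pytest.raises(errors.ParameterError):
            flexible_fit(toy_assembly, m, [CrossLink("Z", 1, "Z", 5)], cycles=5)


@pytest.fixture(scope="module")
def tiny_displaced(toy_assembly):
    m = simulate_map(toy_assembly, 10.0, 3.0, pad=12.0)
    links = make_synthetic_links(toy_assembly, n=10, d_max=40.0, seed=0)
    pert = toy_assembly.copy()
    cen_b = pert.ca_coords("B").mean(axis=0)
    u = cen_b - toy_assembly.coords(True).mean(axis=0)
    u[2] = 0.0
    u /= np.linalg.norm(u)
    for res in pert.chains["B"]:
        for a in res.atoms:
            a.coord = a.coord + 8.0 * u
    return pert, m, links


class TestAssessModel:
    def test_perfect_model(self, toy_assembly):
        m = simulate_map(toy_assembly, 10.0, 3.0, pad=12.0)
        links = make_synthetic_links(toy_assembly, n=10, d_max=35.0, seed=1)
        rep = assess_model(toy_assembly, m, links)
        assert rep["local_ccc"] > 0.99
        assert rep["link_audit"].n_satisfied == rep["link_audit"].n_mapped

    def test_outlier_link_reported(self):
        from mpn_integrator import synthetic_data as syn
        from mpn_integrator.synthetic_data import lysine_residues

        tall = syn.make_toy_assembly(syn.ToyAssemblySpec(n_subunits=2, residues_per_subunit=60))
        m = simulate_map(tall, 10.0, 3.0, pad=12.0)
        # pick a lysine pair > 60 Å apart in the assembly
        lys = lysine_residues(tall)
        pair = None
        for i in range(len(lys)):
            for j in range(i + 1, len(lys)):
                if np.linalg.norm(lys[i].ca.coord - lys[j].ca.coord) > 70.0:
                    pair = (lys[i], lys[j])
                    break
            if pair:
                break
        assert pair is not None
        link = CrossLink(pair[0].chain_id, pair[0].seq_id, pair[1].chain_id, pair[1].seq_id)
        rep = assess_model(tall, m, [link])
        assert rep["link_audit"].n_outliers == 1

    def test_composition_equals_underlying_calls(self, toy_assembly):
        from mpn_integrator.crosslinks import audit_links
        from mpn_integrator.density import ccc

        m = simulate_map(toy_assembly, 10.0, 3.0, pad=12.0)
        links = make_synthetic_links(toy_assembly, n=6, d_max=35.0, seed=2)
        rep = assess_model(toy_assembly, m, links)
        sim = simulate_map(toy_assembly, 10.0, 3.0, on_grid=m)
        assert rep["local_ccc"] == pytest.approx(
            ccc(m, sim, structure=toy_assembly, radius=5.0), abs=1e-12
        )
        direct = audit_links(toy_assembly, links)
        assert rep["link_audit"].mean_all == pytest.approx(direct.mean_all)
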