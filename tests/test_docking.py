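import numpy as np
import pandas as pd
import pytest

from mpn_integrator import errors
from mpn_integrator._geometry import dedup_rotations, euler_zyz_to_matrix, matrix_to_quaternion
from mpn_integrator.docking import (
    ConstraintSet,
    PoseScorer,
    PoseSet,
    cluster_poses,
    constraints_from_pose,
    filter_poses,
    generate_poses,
    rank_poses,
    read_zdock_table,
    touch_along_axis,
    write_zdock_table,
)
from mpn_integrator.structure_io import Pose, apply_pose
from scipy.spatial import cKDTree


@pytest.fixture(scope="module")
def scored_native(docking_pair):
    rec, lig, native = docking_pair
    scorer = PoseScorer(rec, lig, n_points=240)
    ps = PoseSet(rec, lig, [native])
    constraints = constraints_from_pose(ps, native, scorer=scorer)
    return rec, lig, native, scorer, constraints


class TestGeneratePoses:
    def test_grid_count_matches_quaternion_dedup_oracle(self, docking_pair):
        rec, lig, _ = docking_pair
        ps = generate_poses(rec, lig, euler_step_deg=90.0)
        step = np.deg2rad(90.0)
        mats = [
            euler_zyz_to_matrix(p, t, q)
            for p in np.arange(0, 2 * np.pi - 1e-9, step)
            for t in np.arange(0, np.pi + 1e-9, step)
            for q in np.arange(0, 2 * np.pi - 1e-9, step)
        ]
        # independent exhaustive dedup on quaternions (q ~ −q)
        quats = []
        for R in mats:
            q = matrix_to_quaternion(R)
            if not any(np.allclose(q, p, atol=1e-6) for p in quats):
                quats.append(q)
        assert len(ps.poses) == len(quats)
        assert len(quats) < 4 * 3 * 4  # duplicates were actually removed

    def test_orientations_unique_as_rotations(self, docking_pair):
        rec, lig, _ = docking_pair
        ps = generate_poses(rec, lig, euler_step_deg=90.0)
        mats = [p.rotation for p in ps.poses]
        assert len(dedup_rotations(mats)) == len(mats)

    def test_every_pose_touches(self, docking_pair):
        rec, lig, _ = docking_pair
        ps = generate_poses(rec, lig, euler_step_deg=120.0)
        tree = cKDTree(rec.coords(True))
        for pose in ps.poses:
            d = tree.query(apply_pose(lig, pose).coords(True))[0].min()
            assert 3.0 <= d <= 4.5

    def test_deterministic(self, docking_pair):
        rec, lig, _ = docking_pair
        a = generate_poses(rec, lig, euler_step_deg=120.0, seed=3)
        b = generate_poses(rec, lig, euler_step_deg=120.0, seed=3)
        for pa, pb in zip(a.poses, b.poses):
            np.testing.assert_array_equal(pa.rotation, pb.rotation)
            np.testing.assert_array_equal(pa.translation, pb.translation)

    def test_bad_step_rejected(self, docking_pair):
        rec, lig, _ = docking_pair
        with pytest.raises(errors.ParameterError):
            generate_poses(rec, lig, euler_step_deg=0.0)


class TestZdockTable:
    def test_handcrafted_rows(self, docking_pair, tmp_path):
        rec, lig, _ = docking_pair
        p = tmp_path / "poses.txt"
        p.write_text("128 1.2\n0.0 0.0 0.0\n0 0 0 0 0 0 10.5\n0 1.5707963268 0 2 0 127 3.0\n")
        ps = read_zdock_table(p, rec, lig)
        assert len(ps.poses) == 2
        np.testing.assert_allclose(ps.poses[0].rotation, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(ps.poses[0].translation, 0.0, atol=1e-12)
        assert ps.poses[0].source_score == 10.5
        # index 127 > 64 wraps to −1 grid unit = −1.2 Å
        np.testing.assert_allclose(ps.poses[1].translation, [2.4, 0.0, -1.2], atol=1e-9)

    def test_round_trip_transforms(self, docking_pair, tmp_path):
        rec, lig, native = docking_pair
        ps = PoseSet(rec, lig, [native, Pose.identity(pose_id=1)])
        p = tmp_path / "rt.txt"
        write_zdock_table(ps, p)
        back = read_zdock_table(p, rec, lig)
        for a, b in zip(ps.poses, back.poses):
            np.testing.assert_allclose(a.rotation, b.rotation, atol=1e-6)
            np.testing.assert_allclose(a.translation, b.translation, atol=1e-6)

    def test_malformed_row_names_line(self, docking_pair, tmp_path):
        rec, lig, _ = docking_pair
        p = tmp_path / "bad.txt"
        p.write_text("128 1.2\n0 0 0\n0 0 0 nope 0 0 1\n")
        with pytest.raises(errors.FormatError, match="line 3"):
            read_zdock_table(p, rec, lig)


class TestFilterPoses:
    def test_native_passes_self_derived_constraints(self, scored_native):
        rec, lig, native, scorer, constraints = scored_native
        table = filter_poses(PoseSet(rec, lig, [native]), constraints, scorer=scorer)
        assert bool(table["passes"].iloc[0])
        assert table["passive_violations"].iloc[0] == 0

    def test_far_pose_fails_with_empty_interface(self, scored_native):
        rec, lig, native, scorer, constraints = scored_native
        far = Pose(native.rotation, native.translation + np.array([50.0, 0, 0]), pose_id=1)
        table = filter_poses(PoseSet(rec, lig, [far]), constraints, scorer=scorer)
        assert not bool(table["passes"].iloc[0])
        assert "empty-interface" in table["reasons"].iloc[0]

    def test_pose_burying_passive_residue_fails(self, scored_native):
        rec, lig, native, scorer, constraints = scored_native
        # rotate the ligand to the opposite receptor face: previously passive
        # (exposed, non-interface) receptor residues become interfacial
        flipped = touch_along_axis(
            rec, lig, native.rotation, axis=[-1.0, 0.5, 0.0], pose_id=2
        )
        table = filter_poses(PoseSet(rec, lig, [flipped]), constraints, scorer=scorer)
        row = table.iloc[0]
        assert row["passive_violations"] >= 1
        assert not bool(row["passes"])
        assert "passive-violation" in row["reasons"]

    def test_missing_constraint_residue_rejected(self, scored_native):
        rec, lig, native, scorer, _ = scored_native
        bad = ConstraintSet(passive_residues={("Z", 999, None)})
        with pytest.raises(errors.ConstraintError):
            filter_poses(PoseSet(rec, lig, [native]), bad, scorer=scorer)

    def test_enlarging_passive_set_is_monotone(self, scored_native):
        rec, lig, native, scorer, constraints = scored_native
        from mpn_integrator.synthetic_data import make_decoys

        ps = make_decoys(rec, lig, native, n=20, seed=0)
        rec_keys = sorted({r.key for r in rec.residues()})
        rng = np.random.default_rng(1)
        for _ in range(10):
            small = {rec_keys[i] for i in rng.choice(len(rec_keys), 5, replace=False)}
            big = small | {rec_keys[i] for i in rng.choice(len(rec_keys), 5, replace=False)}
            base = dict(
                buried_area_window=(0.0, 1e9), sc_min=-1.0
            )
            t_small = filter_poses(ps, ConstraintSet(passive_residues=small, **base), scorer=scorer)
            t_big = filter_poses(ps, ConstraintSet(passive_residues=big, **base), scorer=scorer)
            assert t_big["passes"].sum() <= t_small["passes"].sum()


class TestRankPoses:
    def _table(self, rows):
        return pd.DataFrame(rows)

    def test_single_metric_orders_by_value(self):
        t = self._table(
            [
                {"pose_id": 0, "buried_area": 1500.0, "sc": 0.4, "contact_total": 10,
                 "iface_conservation_enrichment": np.nan, "passes": True},
                {"pose_id": 1, "buried_area": 1500.0, "sc": 0.8, "contact_total": 10,
                 "iface_conservation_enrichment": np.nan, "passes": True},
            ]
        )
        out = rank_poses(t, weights={"sc": 1.0, "buried": 0, "conservation": 0, "contacts": 0})
        assert int(out.loc[out["rank"] == 1, "pose_id"].iloc[0]) == 1

    def test_tie_breaks_to_lower_pose_id(self):
        rows = [
            {"pose_id": pid, "buried_area": 1500.0, "sc": 0.5, "contact_total": 10,
             "iface_conservation_enrichment": np.nan, "passes": True}
            for pid in (7, 3)
        ]
        out = rank_poses(self._table(rows))
        assert int(out.loc[out["rank"] == 1, "pose_id"].iloc[0]) == 3

    def test_rank_invariant_to_input_order(self):
        rng = np.random.default_rng(2)
        rows = [
            {"pose_id": i, "buried_area": float(rng.uniform(1000, 2000)),
             "sc": float(rng.uniform(0, 1)), "contact_total": int(rng.integers(5, 50)),
             "iface_conservation_enrichment": float(rng.normal()), "passes": True}
            for i in range(12)
        ]
        a = rank_poses(self._table(rows)).sort_values("pose_id")["rank"].tolist()
        b = rank_poses(self._table(rows[::-1])).sort_values("pose_id")["rank"].tolist()
        assert a == b

    def test_ranks_are_a_permutation(self):
        rng = np.random.default_rng(3)
        rows = [
            {"pose_id": i, "buried_area": float(rng.uniform(500, 2500)),
             "sc": float(rng.uniform(0, 1)), "contact_total": int(rng.integers(0, 60)),
             "iface_conservation_enrichment": np.nan, "passes": bool(rng.random() < 0.5)}
            for i in range(15)
        ]
        out = rank_poses(self._table(rows))
        assert sorted(out["rank"]) == list(range(1, 16))


class TestClusterPoses:
    def _ranked(self, ps):
        t = pd.DataFrame(
            {"pose_id": [p.pose_id for p in ps.poses], "passes": True,
             "buried_area": 0.0, "sc": 0.0, "contact_total": 0,
             "iface_conservation_enrichment": np.nan}
        )
        return rank_poses(t)

    def test_duplicate_poses_form_single_cluster(self, docking_pair):
        rec, lig, native = docking_pair
        ps = PoseSet(rec, lig, [Pose(native.rotation, native.translation, pose_id=i) for i in range(4)])
        out, leaders = cluster_poses(ps, self._ranked(ps), rmsd_cutoff=5.0)
        assert out["cluster"].nunique() == 1 and len(leaders) == 1

    def test_two_distant_groups_form_two_clusters(self, docking_pair):
        rec, lig, native = docking_pair
        shifted = Pose(native.rotation, native.translation + np.array([30.0, 0, 0]), pose_id=2)
        ps = PoseSet(
            rec, lig,
            [native, Pose(native.rotation, native.translation, pose_id=1), shifted],
        )
        out, leaders = cluster_poses(ps, self._ranked(ps), rmsd_cutoff=5.0)
        assert out["cluster"].nunique() == 2

    def test_infinite_cutoff_single_cluster(self, docking_pair):
        rec, lig, native = docking_pair
        shifted = Pose(native.rotation, native.translation + np.array([30.0, 0, 0]), pose_id=1)
        ps = PoseSet(rec, lig, [native, shifted])
        out, _ = cluster_poses(ps, self._ranked(ps), rmsd_cutoff=np.inf)
        assert out["cluster"].nunique() == 1
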