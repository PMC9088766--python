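"""Pose triage: anchor distances, dual-threshold filter, stability, RMSD,
clustering."""

import math

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from ketopose.errors import IntegrityError, ValidationError
from ketopose.synthetic import TrajectorySpec, gen_competence_trajectory
from ketopose.model_io import Trajectory
from ketopose.triage import (PoseRecord, TriageThresholds, ca_rmsd,
                             cluster_poses, ser42_arg_com_distance,
                             ser42_patch_distance, stability_flag,
                             triage_filter)
from conftest import make_structure


class TestSer42PatchDistance:
    def test_axis_aligned_distance(self):
        s = make_structure({("A", 42, "CB"): (0, 0, 0),
                            ("K", 38, "CZ"): (0, 0, 9.0)})
        assert ser42_patch_distance(s) == pytest.approx(9.0)

    def test_hand_euclidean_norm(self):
        s = make_structure({("A", 42, "CB"): (1, 2, 2),
                            ("K", 38, "CZ"): (4, 6, 14)})
        assert ser42_patch_distance(s) == pytest.approx(13.0)

    def test_translation_invariance(self):
        rng = np.random.default_rng(0)
        s = make_structure({("A", 42, "CB"): rng.normal(size=3),
                            ("K", 38, "CZ"): rng.normal(size=3)})
        shifted = s.with_coords(s.coords + np.array([3.0, -7.0, 11.0]))
        assert ser42_patch_distance(shifted) == pytest.approx(
            ser42_patch_distance(s))

    def test_missing_atom_named_in_error(self):
        s = make_structure({("A", 42, "CB"): (0, 0, 0)})
        with pytest.raises(KeyError, match="CZ"):
            ser42_patch_distance(s)


GUA = ("CZ", "NH1", "NH2", "NE")


class TestArgComDistance:
    def test_coincident_guanidinium_atoms(self):
        atoms = {("A", 42, "OG"): (0.0, 0.0, 0.0)}
        atoms.update({("K", 38, n): (5.0, 0.0, 0.0) for n in GUA})
        s = make_structure(atoms)
        assert ser42_arg_com_distance(s, [38]) == pytest.approx(5.0)

    def test_symmetric_pair_reduces_to_midpoint(self):
        # two arginines mirror-symmetric about P: pooled COM is P
        p = np.array([2.0, 1.0, -3.0])
        offset = np.array([1.5, 0.7, 0.2])
        atoms = {("A", 42, "OG"): p + np.array([0.0, 0.0, 4.0])}
        atoms.update({("K", 65, n): p + offset for n in GUA})
        atoms.update({("K", 93, n): p - offset for n in GUA})
        s = make_structure(atoms)
        assert ser42_arg_com_distance(s, [65, 93]) == pytest.approx(4.0)

    def test_per_residue_option(self):
        atoms = {("A", 42, "OG"): (0.0, 0.0, 0.0)}
        atoms.update({("K", 38, n): (3.0, 0.0, 0.0) for n in GUA})
        atoms.update({("K", 65, n): (0.0, 7.0, 0.0) for n in GUA})
        s = make_structure(atoms)
        assert ser42_arg_com_distance(s, [38, 65], per_residue=True) == \
            pytest.approx([3.0, 7.0])


class TestTriageFilter:
    def _pose(self, pid, e, d):
        return PoseRecord(pid, "M1", "docking", e, d)

    def test_hand_enumerated_table(self):
        poses = [
            self._pose("keep1", -120.0, 5.0),   # both pass
            self._pose("x_energy", -80.0, 5.0),  # energy too high
            self._pose("x_dist", -120.0, 10.0),  # distance too large
            self._pose("x_bound_e", -90.0, 5.0),  # boundary energy: excluded
            self._pose("x_bound_d", -120.0, 9.0),  # boundary distance: excluded
            self._pose("keep2", -95.0, 8.9),    # both pass
        ]
        kept = triage_filter(poses, TriageThresholds())
        assert [p.pose_id for p in kept] == ["keep1", "keep2"]

    def test_subset_and_idempotent(self):
        poses = [self._pose(f"p{i}", -130.0 + 10 * i, 4.0 + i) for i in range(8)]
        t = TriageThresholds()
        kept = triage_filter(poses, t)
        assert all(p in poses for p in kept)
        assert triage_filter(kept, t) == kept

    def test_undetermined_fields_rejected(self):
        with pytest.raises(ValidationError):
            triage_filter([PoseRecord("p", "M1")], TriageThresholds())


class TestStabilityFlag:
    DT = 500.0  # ps; 17 samples -> 8 ns, final window = 9 samples

    def test_constant_series_is_stable(self):
        assert stability_flag([8.0] * 17, self.DT, TriageThresholds())

    def test_large_final_excursion_unstable(self):
        series = [8.0] * 16 + [8.0 * 1.3]
        assert not stability_flag(series, self.DT, TriageThresholds())

    @pytest.mark.parametrize("excursion,expected", [(1.1, True), (1.3, False)])
    def test_15pc_boundary_around_window_mean(self, excursion, expected):
        # symmetric +-x tail keeps the window mean at exactly 8.0;
        # tolerance is 0.15 * 8.0 = 1.2
        series = [8.0] * 15 + [8.0 - excursion, 8.0 + excursion]
        assert stability_flag(series, self.DT, TriageThresholds()) is expected

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        series = 8.0 + rng.normal(0, 0.5, size=17)
        t = TriageThresholds()
        flag = stability_flag(series, self.DT, t)
        assert stability_flag(series * 3.7, self.DT, t) == flag

    def test_short_series_rejected(self):
        with pytest.raises(ValidationError):
            stability_flag([8.0] * 5, self.DT, TriageThresholds())

    def test_first_value_reference_mode(self):
        t = TriageThresholds(stability_reference="first_value")
        series = [8.0] * 8 + [8.0] + [9.1] * 8  # first window sample = 8.0
        assert stability_flag(series, self.DT, t)  # 9.1 is 13.75% above 8.0
        series = [8.0] * 8 + [8.0] + [9.3] * 8
        assert not stability_flag(series, self.DT, t)  # 16.25% above


def _ca_structure(points, chain="A"):
    return make_structure({(chain, i + 1, "CA"): p for i, p in enumerate(points)})


def brute_force_rmsd(p, q, n_starts=40, seed=0):
    """Oracle: direct minimization over rotation vectors, many restarts."""
    p = p - p.mean(axis=0)
    q = q - q.mean(axis=0)

    def objective(rv):
        diff = p - Rotation.from_rotvec(rv).apply(q)
        return math.sqrt((diff ** 2).sum() / len(p))

    rng = np.random.default_rng(seed)
    best = np.inf
    for _ in range(n_starts):
        rv0 = rng.uniform(-math.pi, math.pi, size=3)
        res = minimize(objective, rv0, method="Nelder-Mead",
                       options={"xatol": 1e-12, "fatol": 1e-14,
                                "maxiter": 5000})
        best = min(best, res.fun)
    return best


class TestCaRmsd:
    def test_self_rmsd_zero(self):
        s = _ca_structure(np.random.default_rng(0).normal(size=(6, 3)))
        assert ca_rmsd(s, s) == pytest.approx(0.0, abs=1e-12)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(8, 3))
        s = _ca_structure(pts)
        rot = Rotation.random(random_state=np.random.RandomState(7))
        moved = s.with_coords(rot.apply(pts) + np.array([5.0, -2.0, 9.0]))
        assert ca_rmsd(s, moved) == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_on_4_point_toys(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.normal(size=(4, 3))
        q = rng.normal(size=(4, 3))
        ours = ca_rmsd(_ca_structure(p), _ca_structure(q))
        assert ours == pytest.approx(brute_force_rmsd(p, q), abs=1e-6)

    def test_symmetry(self):
        rng = np.random.default_rng(5)
        a = _ca_structure(rng.normal(size=(5, 3)))
        b = _ca_structure(rng.normal(size=(5, 3)))
        assert ca_rmsd(a, b) == pytest.approx(ca_rmsd(b, a), abs=1e-12)

    def test_chain_selection_and_roster_mismatch(self):
        a = _ca_structure(np.zeros((3, 3)))
        b = _ca_structure(np.zeros((4, 3)))
        with pytest.raises(IntegrityError):
            ca_rmsd(a, b)


class TestClusterPoses:
    def _traj_from_frames(self, frames):
        return Trajectory(frames, timestep=1.0)

    def test_identical_frames_single_cluster(self):
        pts = np.random.default_rng(0).normal(size=(5, 3))
        frames = [_ca_structure(pts) for _ in range(6)]
        reps = cluster_poses(self._traj_from_frames(frames), 1)
        assert len(reps) == 1
        assert reps[0].member_count == 6
        assert reps[0].frame_index == 0  # tie-break: lowest index

    def test_planted_two_conformations_recovered(self):
        rng = np.random.default_rng(3)
        conf_a = rng.normal(size=(6, 3))
        conf_b = conf_a + np.array([0.0, 0.0, 20.0]) * rng.normal(1, 0.1, size=(6, 1))
        frames, truth = [], []
        for i in range(10):
            base = conf_a if i % 2 == 0 else conf_b
            frames.append(_ca_structure(base + rng.normal(0, 0.05, size=(6, 3))))
            truth.append(i % 2)
        reps = cluster_poses(self._traj_from_frames(frames), 2)
        rep_groups = {truth[r.frame_index] for r in reps}
        assert rep_groups == {0, 1}
        counts = sorted(r.member_count for r in reps)
        assert counts == [5, 5]

    def test_n_equals_frames_is_singletons(self):
        rng = np.random.default_rng(4)
        frames = [_ca_structure(rng.normal(size=(4, 3))) for _ in range(4)]
        reps = cluster_poses(self._traj_from_frames(frames), 4)
        assert [r.frame_index for r in reps] == [0, 1, 2, 3]
        assert all(r.member_count == 1 for r in reps)

    def test_invalid_counts_rejected(self):
        frames = [_ca_structure(np.zeros((3, 3)))]
        traj = self._traj_from_frames(frames)
        with pytest.raises(ValidationError):
            cluster_poses(traj, 0)
        with pytest.raises(ValidationError):
            cluster_poses(traj, 2)
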