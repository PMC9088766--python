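"""Chirality, prochiral faces, ring puckering and the competence statistic."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ketopose.constants import R_KCAL
from ketopose.errors import DegenerateGeometryError, ValidationError
from ketopose.model_io import Trajectory
from ketopose.stereo import (AtomMap, CompetenceCriteria, assign_chirality,
                             classify_face, competence_summary,
                             enumerate_isomer_conformers,
                             free_energy_from_fraction, is_reaction_competent,
                             ring_conformer)
from ketopose.synthetic import TrajectorySpec, gen_competence_trajectory
from conftest import apply_rigid, make_structure, mirror, random_rigid_motion

CENTER = ("S", 1, "C")
SUBS = [("S", 1, "S1"), ("S", 1, "S2"), ("S", 1, "S3"), ("S", 1, "S4")]


def tetrahedron(p1, p2, p3, p4):
    return make_structure({CENTER: (0.0, 0.0, 0.0), SUBS[0]: p1,
                           SUBS[1]: p2, SUBS[2]: p3, SUBS[3]: p4})


class TestAssignChirality:
    # priorities 1-3 clockwise viewed from +z, priority 4 pointing -z -> R
    R_FIXTURE = ((1.0, 0.0, 0.33), (-0.5, -0.87, 0.33), (-0.5, 0.87, 0.33),
                 (0.0, 0.0, -1.0))

    def test_canonical_right_handed_fixture_is_R(self):
        assert assign_chirality(tetrahedron(*self.R_FIXTURE), CENTER, SUBS) == "R"

    def test_mirror_flips_to_S(self):
        s = mirror(tetrahedron(*self.R_FIXTURE), axis=0)
        assert assign_chirality(s, CENTER, SUBS) == "S"

    def test_coplanar_substituents_degenerate(self):
        flat = tetrahedron((1, 0, 0), (0, 1, 0), (-1, -1, 0), (1, 1, 0))
        with pytest.raises(DegenerateGeometryError):
            assign_chirality(flat, CENTER, SUBS)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_rigid_invariance_and_mirror_parity(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(4, 3))
        s = tetrahedron(*pts)
        try:
            label = assign_chirality(s, CENTER, SUBS)
        except DegenerateGeometryError:
            return
        rot, trans = random_rigid_motion(rng)
        assert assign_chirality(apply_rigid(s, rot, trans), CENTER, SUBS) == label
        flipped = assign_chirality(mirror(s), CENTER, SUBS)
        assert flipped != label


class TestClassifyFace:
    def test_re_side_hydride_is_pro_s(self, carbonyl_frame):
        # hydride at -z; the O9>C8>C10 normal points +z, so -z is the Re face
        assert classify_face(carbonyl_frame) == "pro-S"

    def test_reflection_through_carbonyl_plane_flips_label(self, carbonyl_frame):
        assert classify_face(mirror(carbonyl_frame, axis=2)) == "pro-R"

    def test_rigid_motion_invariance(self, carbonyl_frame):
        rng = np.random.default_rng(9)
        for _ in range(10):
            rot, trans = random_rigid_motion(rng)
            assert classify_face(apply_rigid(carbonyl_frame, rot, trans)) == "pro-S"

    def test_in_plane_hydride_degenerate(self, carbonyl_frame):
        coords = carbonyl_frame.coords.copy()
        idx = carbonyl_frame.roster().index(("N", 1, "H4N"))
        coords[idx] = [3.0, 3.0, 0.0]  # in the carbonyl plane
        with pytest.raises(DegenerateGeometryError):
            classify_face(carbonyl_frame.with_coords(coords))

    def test_consistent_with_product_chirality(self):
        """Re-face attack must yield the S-alcohol.

        Build the tetrahedral product (carbonyl substituents pyramidalized
        away from the incoming hydride) and check the R/S label obtained
        independently from the determinant rule with priorities
        O9 > C8 > C10 > H.
        """
        for h_z, expected_face, expected_chir in [(-1.1, "pro-S", "S"),
                                                  (1.1, "pro-R", "R")]:
            pyr = 0.3 if h_z < 0 else -0.3
            frame = make_structure({
                ("S", 2, "C9"): (0.0, 0.0, 0.0),
                ("S", 2, "O9"): (1.23, 0.0, pyr),
                ("S", 2, "C8"): (-0.755, 1.308, pyr),
                ("S", 2, "C10"): (-0.755, -1.308, pyr),
                ("N", 1, "H4N"): (0.0, 0.0, h_z),
            })
            assert classify_face(frame) == expected_face
            chir = assign_chirality(
                frame, ("S", 2, "C9"),
                [("S", 2, "O9"), ("S", 2, "C8"), ("S", 2, "C10"),
                 ("N", 1, "H4N")])
            assert chir == expected_chir

    def test_generator_competent_frames_all_pro_s(self):
        traj = gen_competence_trajectory(TrajectorySpec(30, 1.0, 0.0, seed=2))
        assert all(classify_face(f) == "pro-S" for f in traj)


def ideal_chair(z0=0.25, r=1.46):
    """Chair-puckered six-ring with alternating +-z displacement."""
    pts = {}
    for j in range(6):
        ang = math.pi / 3 * j
        pts[("R", 1, f"C{j + 1}")] = (r * math.cos(ang), r * math.sin(ang),
                                      z0 * (-1) ** j)
    return pts


RING = [("R", 1, f"C{j}") for j in range(1, 7)]
SUB = ("R", 1, "O7")


class TestRingConformer:
    def test_ideal_chair_with_axial_substituent(self):
        pts = ideal_chair()
        c1 = np.array(pts[RING[0]])
        pts[SUB] = tuple(c1 + np.array([0.0, 0.0, 1.4]))  # along ring axis
        ring, orient = ring_conformer(make_structure(pts), RING, SUB)
        assert ring.startswith("chair")
        assert orient == "axial"

    def test_ideal_chair_with_equatorial_substituent(self):
        pts = ideal_chair()
        c1 = np.array(pts[RING[0]])
        out = c1 / np.linalg.norm(c1)
        pts[SUB] = tuple(c1 + 1.4 * out)  # radially outward: equatorial
        _, orient = ring_conformer(make_structure(pts), RING, SUB)
        assert orient == "equatorial"

    def test_planar_hexagon_is_non_chair(self):
        pts = ideal_chair(z0=0.0)
        pts[SUB] = (3.0, 0.0, 0.0)
        ring, _ = ring_conformer(make_structure(pts), RING, SUB)
        assert ring == "non_chair"

    @staticmethod
    def _exo_directions(ring_pts):
        """Tetrahedral exocyclic bond directions at C1 (the +/- pair)."""
        c1, c2, c6 = (np.asarray(ring_pts[RING[i]]) for i in (0, 1, 5))
        b1 = (c2 - c1) / np.linalg.norm(c2 - c1)
        b2 = (c6 - c1) / np.linalg.norm(c6 - c1)
        u = -(b1 + b2) / np.linalg.norm(b1 + b2)
        v = np.cross(b1, b2)
        v /= np.linalg.norm(v)
        plus = (u + v) / np.linalg.norm(u + v)
        minus = (u - v) / np.linalg.norm(u - v)
        return c1, plus, minus

    def test_ring_inversion_swaps_axial_equatorial(self):
        # at one carbon the two tetrahedral exocyclic directions are one
        # axial and one equatorial; inverting the ring pucker exchanges them
        def classify(z0, sign):
            pts = ideal_chair(z0=z0)
            c1, plus, minus = self._exo_directions(pts)
            d = plus if sign > 0 else minus
            pts[SUB] = tuple(c1 + 1.4 * d)
            return ring_conformer(make_structure(pts), RING, SUB)[1]

        assert {classify(0.25, +1), classify(0.25, -1)} == \
            {"axial", "equatorial"}
        assert classify(0.25, +1) != classify(-0.25, +1)
        assert classify(0.25, -1) != classify(-0.25, -1)

    def test_chair_up_down_distinguished(self):
        pts_up = ideal_chair(z0=0.25)
        pts_up[SUB] = (3.0, 0.0, 0.0)
        pts_down = ideal_chair(z0=-0.25)
        pts_down[SUB] = (3.0, 0.0, 0.0)
        up, _ = ring_conformer(make_structure(pts_up), RING, SUB)
        down, _ = ring_conformer(make_structure(pts_down), RING, SUB)
        assert {up, down} == {"chair_up", "chair_down"}


class TestEnumerateIsomerConformers:
    def test_exactly_eight_distinct(self):
        all_ic = enumerate_isomer_conformers()
        assert len(all_ic) == 8
        assert len(set(all_ic)) == 8

    def test_contains_rr_axial(self):
        labels = [ic.label for ic in enumerate_isomer_conformers()]
        assert "RR-OHax" in labels


class TestIsReactionCompetent:
    def test_frame_just_inside_cutoffs(self):
        traj = gen_competence_trajectory(TrajectorySpec(1, 1.0, 0.0, seed=0))
        assert is_reaction_competent(traj[0], CompetenceCriteria())

    def test_distant_tyrosine_disqualifies(self):
        traj = gen_competence_trajectory(TrajectorySpec(1, 1.0, 0.0, seed=0))
        frame = traj[0]
        coords = frame.coords.copy()
        idx = frame.roster().index(("K", 157, "OH"))
        o9 = frame.position("S", 2, "O9")
        coords[idx] = o9 + np.array([5.0, 0.0, 0.0])
        assert not is_reaction_competent(frame.with_coords(coords),
                                         CompetenceCriteria())

    def test_si_face_hydride_fails_pro_s_requirement(self):
        traj = gen_competence_trajectory(TrajectorySpec(1, 1.0, 0.0, seed=0))
        frame = traj[0]
        criteria = CompetenceCriteria()
        flipped = mirror(frame, axis=2)  # moves hydride to the Si face
        # mirroring flips the face while preserving every distance
        assert classify_face(flipped) == "pro-R"
        assert not is_reaction_competent(flipped, criteria)
        assert is_reaction_competent(
            flipped, CompetenceCriteria(required_face="either"))


class TestCompetenceSummary:
    def _trajs(self, fractions, n=200, noise=0.0, seed0=10):
        return [gen_competence_trajectory(
            TrajectorySpec(n, f, noise, seed=seed0 + i))
            for i, f in enumerate(fractions)]

    def test_all_competent_gives_zero_delta_g(self):
        s = competence_summary(self._trajs([1.0, 1.0]), CompetenceCriteria())
        assert s.fraction == 1.0
        assert s.delta_g == pytest.approx(0.0, abs=1e-12)

    def test_none_competent_flags_delta_g_undefined(self):
        s = competence_summary(self._trajs([0.0, 0.0]), CompetenceCriteria())
        assert s.fraction == 0.0
        assert s.delta_g is None

    def test_pooled_fraction_is_brute_force_count(self):
        trajs = self._trajs([0.1, 0.4, 0.7], n=100)
        criteria = CompetenceCriteria()
        s = competence_summary(trajs, criteria)
        brute = sum(is_reaction_competent(f, criteria)
                    for t in trajs for f in t)
        assert s.fraction == brute / 300
        assert s.n_competent == brute

    def test_identical_replicas_have_zero_jackknife_error(self):
        one = gen_competence_trajectory(TrajectorySpec(100, 0.3, 0.0, seed=5))
        s = competence_summary([one, one, one], CompetenceCriteria())
        assert s.loo_stderr == pytest.approx(0.0, abs=1e-15)

    def test_nine_percent_fraction_maps_to_1p4_kcal(self):
        # 9.1% competent at 303 K costs 1.4 kcal/mol (1 d.p.)
        n = 1000
        traj = gen_competence_trajectory(TrajectorySpec(n, 0.091, 0.0, seed=6))
        s = competence_summary([traj], CompetenceCriteria(), temperature=303.0)
        assert s.fraction == pytest.approx(0.091)
        assert round(s.delta_g, 1) == 1.4

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            competence_summary([], CompetenceCriteria())


class TestFreeEnergyFromFraction:
    def test_limiting_and_hand_values(self):
        assert free_energy_from_fraction(1.0, 303.0) == 0.0
        assert free_energy_from_fraction(0.5, 300.0) == pytest.approx(0.413, abs=5e-4)

    @pytest.mark.parametrize("f,printed", [(0.091, 1.4), (0.029, 2.1),
                                           (0.022, 2.3)])
    def test_printed_free_energy_costs(self, f, printed):
        assert round(free_energy_from_fraction(f, 303.0), 1) == printed

    def test_strictly_decreasing_and_additive(self):
        t = 303.0
        fs = np.linspace(0.05, 1.0, 30)
        gs = [free_energy_from_fraction(f, t) for f in fs]
        assert all(a > b for a, b in zip(gs, gs[1:]))
        assert free_energy_from_fraction(0.2 * 0.3, t) == pytest.approx(
            free_energy_from_fraction(0.2, t) + free_energy_from_fraction(0.3, t))

    def test_domain_errors(self):
        with pytest.raises(ValidationError):
            free_energy_from_fraction(0.0, 303.0)
        with pytest.raises(ValidationError):
            free_energy_from_fraction(1.2, 303.0)
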