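"""Geometric CV correctness: superposition, ΔRMSD, angles, switches, contacts."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

import confdyn as cd
from confdyn.geometry import FUNCTION_GROUPS, _helix_template

from oracles import (
    brute_delta_rmsd,
    brute_salpha,
    brute_switching,
    quaternion_superpose,
)


# ---------------------------------------------------------------------------
# Superposition
# ---------------------------------------------------------------------------

class TestKabsch:
    def test_identical_coordinates_give_zero_rmsd_identity_rotation(self):
        pts = np.random.default_rng(0).normal(size=(8, 3))
        rot, trans, rmsd = cd.kabsch_superpose(pts, pts)
        assert rmsd < 1e-6
        assert np.allclose(rot, np.eye(3), atol=1e-8)

    def test_rigid_transform_recovered_exactly(self):
        pts = np.random.default_rng(1).normal(size=(10, 3))
        rot90 = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        moved = pts @ rot90.T + np.array([1.0, -2.0, 0.5])
        _, _, rmsd = cd.kabsch_superpose(moved, pts)
        assert rmsd < 1e-6

    def test_matches_quaternion_oracle_with_jitter(self):
        rng = np.random.default_rng(2)
        ref = rng.normal(size=(10, 3))
        mob = ref @ Rotation.random(rng=rng).as_matrix().T
        mob = mob + rng.normal(scale=0.05, size=mob.shape) + 3.0
        _, _, rmsd = cd.kabsch_superpose(mob, ref)
        _, _, oracle = quaternion_superpose(mob, ref)
        assert abs(rmsd - oracle) < 1e-10

    def test_proper_rotation_even_for_reflected_input(self):
        rng = np.random.default_rng(3)
        ref = rng.normal(size=(12, 3))
        mirrored = ref * np.array([1.0, 1.0, -1.0])
        rot, _, _ = cd.kabsch_superpose(mirrored, ref)
        assert np.linalg.det(rot) > 0

    def test_degenerate_collinear_input_rejected(self):
        line = np.outer(np.arange(5.0), np.array([1.0, 0.0, 0.0]))
        with pytest.raises(ValueError, match="degenerate|collinear"):
            cd.kabsch_superpose(line, line)

    def test_mismatched_sizes_rejected(self):
        with pytest.raises(ValueError):
            cd.kabsch_superpose(np.zeros((4, 3)), np.zeros((5, 3)))


# ---------------------------------------------------------------------------
# Fitted RMSD and ΔRMSD
# ---------------------------------------------------------------------------

class TestDeltaRmsd:
    def test_frame_equal_reference_gives_zero(self, toy_pair, delta_rmsd_spec):
        state_a, _ = toy_pair
        r = cd.rmsd_after_fit(state_a, state_a, delta_rmsd_spec.fit_selection,
                              delta_rmsd_spec.calc_selection)
        assert r < 1e-12

    def test_calc_equal_fit_matches_plain_kabsch(self, toy_pair, delta_rmsd_spec):
        state_a, state_b = toy_pair
        fit = delta_rmsd_spec.fit_selection
        r = cd.rmsd_after_fit(state_a, state_b, fit, fit)
        _, _, direct = cd.kabsch_superpose(
            cd.select_coords(state_a, fit), cd.select_coords(state_b, fit)
        )
        assert abs(r - direct) < 1e-12

    def test_reference_frames_score_minus_and_plus_d(self, toy_pair, delta_rmsd_spec):
        state_a, state_b = toy_pair
        d = cd.rmsd_after_fit(state_a, state_b, delta_rmsd_spec.fit_selection,
                              delta_rmsd_spec.calc_selection)
        assert d > 0
        assert cd.delta_rmsd(state_a, delta_rmsd_spec) == pytest.approx(-d, abs=1e-9)
        assert cd.delta_rmsd(state_b, delta_rmsd_spec) == pytest.approx(+d, abs=1e-9)

    def test_antisymmetric_under_reference_swap(self, toy_pair, delta_rmsd_spec):
        midpoint = cd.interpolate_path(*toy_pair, 7)[2]
        forward = cd.delta_rmsd(midpoint, delta_rmsd_spec)
        backward = cd.delta_rmsd(midpoint, delta_rmsd_spec.swapped())
        assert forward == pytest.approx(-backward, abs=1e-9)

    def test_matches_brute_force_oracle_at_midpoint(self, toy_pair, delta_rmsd_spec):
        state_a, state_b = toy_pair
        mid = cd.interpolate_path(state_a, state_b, 3)[1]
        fit, calc = delta_rmsd_spec.fit_selection, delta_rmsd_spec.calc_selection
        oracle = brute_delta_rmsd(
            cd.select_coords(mid, fit), cd.select_coords(mid, calc),
            cd.select_coords(state_a, fit), cd.select_coords(state_a, calc),
            cd.select_coords(state_b, fit), cd.select_coords(state_b, calc),
        )
        assert cd.delta_rmsd(mid, delta_rmsd_spec) == pytest.approx(oracle, abs=1e-10)


# ---------------------------------------------------------------------------
# Helix crossing angle
# ---------------------------------------------------------------------------

class TestCrossAngle:
    def test_same_helix_same_direction_is_zero(self, helix30):
        axis = cd.HelixAxisSpec((2, 5), (25, 28))
        assert cd.helix_cross_angle(helix30, axis, axis) < 1e-6

    def test_constructed_perpendicular_vectors_give_90(self):
        # four CA atoms forming vectors along x and along y
        atoms = []
        positions = {1: [0, 0, 0], 2: [1, 0, 0], 11: [5, 0, 0], 12: [5, 1, 0]}
        for resnum, pos in positions.items():
            atoms.append(cd.AtomRecord(resnum, "CA", "ALA", "A", resnum,
                                       np.array(pos, dtype=float), "C"))
        frame = cd.Structure(atoms)
        a = cd.HelixAxisSpec((1, 1), (2, 2))
        b = cd.HelixAxisSpec((11, 11), (12, 12))
        assert cd.helix_cross_angle(frame, a, b) == pytest.approx(90.0, abs=1e-9)

    def test_invariant_under_global_rotation_translation(self, toy_pair):
        state_a, _ = toy_pair
        axis_a = cd.HelixAxisSpec((2, 5), (14, 17))
        axis_b = cd.HelixAxisSpec((45, 48), (55, 58))
        before = cd.helix_cross_angle(state_a, axis_a, axis_b)
        rot = Rotation.from_euler("xyz", [31, -47, 100], degrees=True).as_matrix()
        moved = state_a.with_coords(state_a.coords @ rot.T + np.array([3.0, -1.0, 2.0]))
        after = cd.helix_cross_angle(moved, axis_a, axis_b)
        assert after == pytest.approx(before, abs=1e-8)

    def test_antiparallel_reported_near_180_not_folded(self, helix30):
        axis = cd.HelixAxisSpec((2, 5), (25, 28))
        reverse = cd.HelixAxisSpec((25, 28), (2, 5))
        assert cd.helix_cross_angle(helix30, axis, reverse) > 175.0


# ---------------------------------------------------------------------------
# Switching function and contact numbers
# ---------------------------------------------------------------------------

class TestSwitching:
    def test_limit_at_r0_is_n_over_m(self):
        sw = cd.SwitchingParams(r0=0.85)
        assert cd.switching_function(0.85, sw) == pytest.approx(2.0 / 3.0, abs=1e-12)

    def test_continuous_through_r0(self):
        sw = cd.SwitchingParams(r0=0.85)
        eps = 1e-9
        below = cd.switching_function(0.85 - eps, sw)
        above = cd.switching_function(0.85 + eps, sw)
        assert abs(below - 2 / 3) < 1e-7 and abs(above - 2 / 3) < 1e-7

    def test_far_pair_contributes_nothing(self):
        sw = cd.SwitchingParams(r0=0.85)
        single = cd.contact_number(np.zeros((1, 3)), np.array([[5.0, 0, 0]]), sw)
        assert single < 1e-3

    @settings(deadline=None, derandomize=True)
    @given(st.floats(min_value=0.01, max_value=5.0),
           st.floats(min_value=0.05, max_value=2.0))
    def test_switch_in_unit_interval_and_matches_rational_form(self, r, r0):
        sw = cd.SwitchingParams(r0=r0)
        value = cd.switching_function(r, sw)
        assert 0.0 < value <= 1.0
        assert value == pytest.approx(brute_switching(r, r0), rel=1e-9)

    @settings(deadline=None, derandomize=True)
    @given(st.floats(min_value=0.05, max_value=4.0))
    def test_switch_strictly_decreasing(self, r):
        sw = cd.SwitchingParams(r0=0.85)
        assert cd.switching_function(r, sw) > cd.switching_function(r + 1e-3, sw)

    def test_contact_number_bounded_by_pair_count(self, helix30):
        sw = cd.SwitchingParams(r0=0.85)
        ca = cd.select_coords(helix30, cd.AtomSelection.ca(1, 10))
        cb = cd.select_coords(helix30, cd.AtomSelection.ca(20, 30))
        nc = cd.contact_number(ca, cb, sw)
        assert 0.0 < nc <= ca.shape[0] * cb.shape[0]


# ---------------------------------------------------------------------------
# α-helix RMSD CV
# ---------------------------------------------------------------------------

class TestAlphaHelixCv:
    def test_template_window_contributes_one(self):
        helix6 = cd.build_ideal_helix(6)
        assert cd.alpha_helix_rmsd_cv(helix6, (1, 6)) == pytest.approx(1.0, abs=1e-9)

    def test_ideal_helix_scores_windows_count(self, helix12):
        value = cd.alpha_helix_rmsd_cv(helix12, (1, 12))
        assert value == pytest.approx(7.0, rel=0.05)

    def test_extended_chain_scores_near_zero(self):
        # a straight strand: backbone atoms spread along x
        atoms = []
        serial = 1
        for res in range(1, 13):
            for k, name in enumerate(("N", "CA", "C", "O")):
                pos = np.array([0.35 * res + 0.09 * k, 0.02 * (k % 2), 0.0])
                atoms.append(cd.AtomRecord(serial, name, "ALA", "A", res, pos, name[0]))
                serial += 1
        strand = cd.Structure(atoms)
        assert cd.alpha_helix_rmsd_cv(strand, (1, 12)) < 0.05

    def test_matches_per_window_oracle(self, toy_pair):
        state_a, _ = toy_pair
        first, last = 20, 35
        windows = [
            cd.select_coords(state_a, cd.AtomSelection.backbone(s, s + 5))
            for s in range(first, last - 4)
        ]
        oracle = brute_salpha(windows, _helix_template(6))
        value = cd.alpha_helix_rmsd_cv(state_a, (first, last))
        assert value == pytest.approx(oracle, abs=1e-9)

    def test_too_short_range_rejected(self, helix12):
        with pytest.raises(ValueError):
            cd.alpha_helix_rmsd_cv(helix12, (1, 5))


# ---------------------------------------------------------------------------
# Side-chain groups, close contacts, π-cation
# ---------------------------------------------------------------------------

def _residue(resnum, resname, atom_positions, chain="A"):
    return [
        cd.AtomRecord(i + resnum * 100, name, resname, chain, resnum,
                      np.asarray(pos, dtype=float), name[0])
        for i, (name, pos) in enumerate(atom_positions.items())
    ]


class TestSidechainGeometry:
    def test_arg_glu_centroid_distance(self):
        arg = _residue(1, "ARG", {
            "NE": [0.05, 0, 0], "NH1": [-0.025, 0.05, 0], "NH2": [-0.025, -0.05, 0]})
        glu = _residue(2, "GLU", {"OE1": [0.3, 0.05, 0], "OE2": [0.3, -0.05, 0]})
        frame = cd.Structure(arg + glu)
        d = cd.sidechain_group_distance(frame, ("A", 1), ("A", 2))
        assert d == pytest.approx(0.3, abs=1e-12)

    def test_coincident_centroids_give_zero(self):
        lys = _residue(1, "LYS", {"NZ": [0.1, 0.2, 0.3]})
        ser = _residue(2, "SER", {"OG": [0.1, 0.2, 0.3]})
        frame = cd.Structure(lys + ser)
        assert cd.sidechain_group_distance(frame, ("A", 1), ("A", 2)) == 0.0

    def test_lys_asp_matches_hand_computed_value(self):
        lys = _residue(1, "LYS", {"NZ": [0.1, 0.1, 0.1]})
        asp = _residue(2, "ASP", {"OD1": [0.4, 0.1, 0.3], "OD2": [0.4, 0.3, 0.1]})
        frame = cd.Structure(lys + asp)
        centroid = np.array([0.4, 0.2, 0.2])
        expected = np.linalg.norm(centroid - np.array([0.1, 0.1, 0.1]))
        d = cd.sidechain_group_distance(frame, ("A", 1), ("A", 2))
        assert d == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("distance,expected", [
        (0.49, True), (0.51, False), (0.3, True), (0.5, False)])
    def test_close_contact_threshold(self, distance, expected):
        assert cd.is_close_contact(distance) is expected

    def _ring_plus_cation(self, cation_pos):
        # hexagonal ring of radius 0.14 nm in the xy-plane, centred at origin
        ring = {}
        for name, angle in zip(("CG", "CD1", "CE1", "CZ", "CE2", "CD2"),
                               np.linspace(0, 300, 6)):
            ring[name] = [0.14 * np.cos(np.radians(angle)),
                          0.14 * np.sin(np.radians(angle)), 0.0]
        phe = _residue(1, "PHE", ring)
        lys = _residue(2, "LYS", {"NZ": cation_pos})
        return cd.Structure(phe + lys)

    def test_pi_cation_true_inside_both_bounds(self):
        frame = self._ring_plus_cation([0.5, 0.0, 0.0])  # 90° to ring normal
        assert cd.is_pi_cation(frame, ("A", 1), ("A", 2)) is True

    def test_pi_cation_false_beyond_distance(self):
        frame = self._ring_plus_cation([0.7, 0.0, 0.0])
        assert cd.is_pi_cation(frame, ("A", 1), ("A", 2)) is False

    def test_pi_cation_false_for_stacked_geometry_under_printed_window(self):
        # 30° to the normal: stacked above the ring — outside [60°, 120°]
        frame = self._ring_plus_cation([0.25, 0.0, 0.25 * np.sqrt(3)])
        assert cd.is_pi_cation(frame, ("A", 1), ("A", 2)) is False

    def test_function_group_table_covers_referenced_types(self):
        for res in ("ARG", "LYS", "GLU", "ASP", "ASN", "GLN", "SER", "THR",
                    "HIS", "PHE", "TYR", "TRP"):
            assert len(FUNCTION_GROUPS[res]) >= 1
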