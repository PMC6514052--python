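"""Hydrogen bonds, charge centers, Coulomb energies and salt bridges."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import trajectory_from_coords
from lbdkit.errors import ConfigurationError, SelectionError
from lbdkit.interactions import (
    COULOMB_KC, ChargeCenter, CoulombSpec, HBondSpec, charge_center_position,
    coulomb_energy, h3ct_center, h12nt_center, hbond_occupancy, hbond_present,
    salt_bridge_series,
)
from lbdkit.structio import AtomRecord, Frame, SelectionMask, Topology, Trajectory
from lbdkit.synthetic import make_hbond_trajectory
from oracles import coulomb_energy_from_constants


def dha_frame(angle_deg: float, d_da: float | None = None) -> Frame:
    """Donor at origin, H at 0.1 nm along x, acceptor placed 0.2 nm from H so
    that the D-H-A angle is exactly ``angle_deg`` (D-A stays under 0.3 nm)."""
    phi = np.radians(180.0 - angle_deg)
    a = np.array([0.1 + 0.2 * np.cos(phi), 0.2 * np.sin(phi), 0.0])
    if d_da is not None:
        a = a / np.linalg.norm(a) * d_da
    return Frame(np.array([[0.0, 0.0, 0.0], [0.1, 0.0, 0.0], a]))


@pytest.fixture()
def hbond_spec():
    return HBondSpec(donor=SelectionMask((0,)), hydrogen=SelectionMask((1,)),
                     acceptor=SelectionMask((2,)))


class TestHBond:
    def test_textbook_geometry_is_bonded(self, hbond_spec):
        assert hbond_present(dha_frame(175.0), hbond_spec)

    def test_distance_cutoff_dominates_angle(self, hbond_spec):
        frame = dha_frame(175.0, d_da=0.36)
        assert not hbond_present(frame, hbond_spec)

    @pytest.mark.parametrize("angle,expected", [
        (110.0, False), (119.9, False), (120.001, True), (140.0, True),
    ])
    def test_angle_criterion_flips_at_120_degrees(self, hbond_spec, angle, expected):
        assert hbond_present(dha_frame(angle), hbond_spec) is expected

    def test_missing_hydrogen_uses_distance_only(self):
        spec = HBondSpec(donor=SelectionMask((0,)), acceptor=SelectionMask((2,)))
        assert hbond_present(dha_frame(90.0), spec)  # angle ignored

    def test_occupancy_planted_half(self):
        traj, planted = make_hbond_trajectory(0.5, 100)
        spec = HBondSpec(donor=SelectionMask((0,)), hydrogen=SelectionMask((1,)),
                         acceptor=SelectionMask((2,)))
        occ = hbond_occupancy(traj, spec)
        assert occ == planted == 0.5

    @pytest.mark.parametrize("fraction,expected", [(0.0, 0.0), (1.0, 1.0)])
    def test_occupancy_extremes(self, fraction, expected):
        traj, _ = make_hbond_trajectory(fraction, 40)
        spec = HBondSpec(donor=SelectionMask((0,)), hydrogen=SelectionMask((1,)),
                         acceptor=SelectionMask((2,)))
        assert hbond_occupancy(traj, spec) == expected

    def test_occupancy_invariant_under_frame_reordering(self, rng):
        traj, _ = make_hbond_trajectory(0.3, 20)
        spec = HBondSpec(donor=SelectionMask((0,)), hydrogen=SelectionMask((1,)),
                         acceptor=SelectionMask((2,)))
        order = rng.permutation(20)
        shuffled = Trajectory(traj.topology, [
            Frame(traj.frames[i].coordinates, time=float(k))
            for k, i in enumerate(order)
        ])
        assert hbond_occupancy(shuffled, spec) == hbond_occupancy(traj, spec)


def charged_topology():
    """GLU 10 and ARG 20 and LYS 30 with their charged side-chain atoms."""
    atoms = [
        AtomRecord(1, "CA", "GLU", 10, "A", "C", 12.011),
        AtomRecord(2, "OE1", "GLU", 10, "A", "O", 15.999),
        AtomRecord(3, "OE2", "GLU", 10, "A", "O", 15.999),
        AtomRecord(4, "CA", "ARG", 20, "A", "C", 12.011),
        AtomRecord(5, "CZ", "ARG", 20, "A", "C", 12.011),
        AtomRecord(6, "NE", "ARG", 20, "A", "N", 14.007),
        AtomRecord(7, "NH1", "ARG", 20, "A", "N", 14.007),
        AtomRecord(8, "NH2", "ARG", 20, "A", "N", 14.007),
        AtomRecord(9, "CA", "LYS", 30, "A", "C", 12.011),
        AtomRecord(10, "NZ", "LYS", 30, "A", "N", 14.007),
    ]
    return Topology(atoms)


class TestChargeCenters:
    def test_single_atom_center_is_that_atom(self):
        top = charged_topology()
        coords = np.arange(30.0).reshape(10, 3) / 10.0
        center = ChargeCenter([("A", 30)], charge=1.0)
        pos = charge_center_position(Frame(coords), top, center)
        assert np.allclose(pos, coords[9])

    def test_carboxylate_midpoint_symmetry(self):
        top = charged_topology()
        coords = np.zeros((10, 3))
        coords[1] = [1.0, 0.0, 0.0]   # OE1
        coords[2] = [-1.0, 0.0, 0.0]  # OE2
        center = ChargeCenter([("A", 10)], charge=-1.0)
        pos = charge_center_position(Frame(coords), top, center)
        assert np.allclose(pos, 0.0)

    def test_three_residue_centroid_hand_computed(self):
        top = charged_topology()
        coords = np.zeros((10, 3))
        coords[1] = coords[2] = [0.0, 0.0, 3.0]   # GLU point (midpoint) -> (0,0,3)
        coords[4] = [3.0, 0.0, 0.0]               # ARG CZ
        coords[9] = [0.0, 3.0, 0.0]               # LYS NZ
        center = ChargeCenter([("A", 10), ("A", 20), ("A", 30)], charge=-1.0)
        pos = charge_center_position(Frame(coords), top, center)
        assert np.allclose(pos, [1.0, 1.0, 1.0])

    def test_missing_atoms_listed_in_error(self):
        top = Topology([AtomRecord(1, "CA", "GLU", 10, "A", "C", 12.011)])
        center = ChargeCenter([("A", 10)], charge=-1.0)
        with pytest.raises(SelectionError, match="OE1"):
            charge_center_position(Frame(np.zeros((1, 3))), top, center)

    def test_literature_presets(self):
        neg = h12nt_center()
        pos = h3ct_center()
        assert [r for _, r in neg.members] == [904, 907, 911]
        assert [r for _, r in pos.members] == [733, 740]
        assert neg.charge == -3.0 and pos.charge == 2.0


class TestCoulomb:
    def test_zero_charge_zero_energy(self):
        assert coulomb_energy(0.0, 5.0, 0.7) == 0.0

    def test_reference_value_from_constants(self):
        ours = coulomb_energy(1.0, -1.0, 0.3, CoulombSpec(epsilon=80.0))
        oracle = coulomb_energy_from_constants(1.0, -1.0, 0.3, 80.0)
        assert ours == pytest.approx(oracle, rel=1e-10)
        assert ours == pytest.approx(-5.789, abs=5e-3)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.floats(1e-3, 1e3), st.floats(-3, 3), st.floats(-3, 3))
    def test_inverse_distance_scaling(self, d, q1, q2):
        e1 = coulomb_energy(q1, q2, d)
        e10 = coulomb_energy(q1, q2, 10.0 * d)
        assert e10 == pytest.approx(e1 / 10.0, rel=1e-12, abs=1e-30)

    def test_charge_symmetry(self):
        assert coulomb_energy(2.0, -1.0, 0.5) == coulomb_energy(-1.0, 2.0, 0.5)

    def test_as_printed_mode_uses_d_squared_and_is_flagged(self):
        spec = CoulombSpec(form="as_printed_1_over_d2")
        assert coulomb_energy(1.0, 1.0, 2.0, spec) == pytest.approx(
            COULOMB_KC / (80.0 * 4.0))
        assert spec.metadata["standard"] is False

    def test_nonpositive_distance_rejected(self):
        with pytest.raises(ConfigurationError):
            coulomb_energy(1.0, 1.0, 0.0)


class TestSaltBridge:
    def make_traj(self, arg_offset):
        top = charged_topology()
        coords = np.zeros((10, 3))
        coords[1] = [0.0, 0.1, 0.0]
        coords[2] = [0.0, -0.1, 0.0]
        coords[5] = arg_offset
        coords[6] = arg_offset + [0.1, 0.0, 0.0]
        coords[7] = arg_offset + [0.0, 0.1, 0.0]
        coords[8] = arg_offset + [0.0, 0.0, 0.1]
        return trajectory_from_coords(coords[None], top=top)

    def test_planted_contact_distance_and_flag(self):
        # nearest N-O pair: NH1 at (0.3, 0.1, 0) vs OE1 at (0, 0.1, 0) -> 0.30 nm
        traj = self.make_traj(np.array([0.3, 0.0, 0.0]))
        series = salt_bridge_series(traj, ("A", 10), ("A", 20))
        assert series.values[0] == pytest.approx(0.30, abs=1e-12)
        assert series.meta["contact"][0] is True

    def test_distant_groups_not_in_contact(self):
        traj = self.make_traj(np.array([2.0, 0.0, 0.0]))
        series = salt_bridge_series(traj, ("A", 10), ("A", 20))
        assert series.values[0] > 1.0
        assert series.meta["contact"][0] is False

    def test_matches_exhaustive_pair_minimum(self, rng):
        top = charged_topology()
        coords = rng.uniform(0, 1, size=(10, 3))
        traj = trajectory_from_coords(coords[None], top=top)
        series = salt_bridge_series(traj, ("A", 10), ("A", 20))
        oxygens = coords[[1, 2]]
        nitrogens = coords[[6, 7, 8]]
        brute = min(np.linalg.norm(o - n) for o in oxygens for n in nitrogens)
        assert series.values[0] == pytest.approx(brute, abs=1e-12)

    def test_two_acidic_residues_rejected(self):
        top = charged_topology()
        traj = trajectory_from_coords(np.zeros((1, 10, 3)), top=top)
        with pytest.raises(SelectionError):
            salt_bridge_series(traj, ("A", 10), ("A", 10))
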