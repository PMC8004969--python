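"""H-bond anchors, helix content/turn counting, contact series."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from loxmd.metrics import (
    assign_helix,
    contact_distance_series,
    count_turns,
    detect_anchor_hbonds,
    longest_run,
)
from loxmd.synth import gen_contact_drift, gen_ideal_helix
from loxmd.trajectory import Address, AtomRecord, Frame, TopologySpec, Trajectory


def _hbond_traj(h_pos, a_pos, d_pos=(-1.0, 0.0, 0.0)):
    atoms = [
        AtomRecord(1, "N", "N", "ARG", 405, "B"),
        AtomRecord(2, "HN", "H", "ARG", 405, "B"),
        AtomRecord(3, "O1", "O", "LIG", 800, "B"),
    ]
    top = TopologySpec(
        atoms=atoms,
        anchor_donors=[(Address("B", 405, "N"), Address("B", 405, "HN"))],
        anchor_acceptors=[Address("B", 800, "O1")],
    )
    coords = np.array([d_pos, h_pos, a_pos])
    return Trajectory(top, [Frame(0, 0.0, coords)])


class TestHBonds:
    def test_linear_short_contact_detected(self):
        # D-H...A collinear, d(H...A) = 1.872 Å: a textbook anchor bond
        traj = _hbond_traj((0, 0, 0), (1.872, 0, 0))
        events, occ = detect_anchor_hbonds(traj)
        assert len(events) == 1
        assert events[0].d_H_A == pytest.approx(1.872)
        assert events[0].angle_DHA == pytest.approx(180.0)
        assert occ[(Address("B", 405, "N"), Address("B", 800, "O1"))] == 1.0

    def test_long_permissive_contact_detected(self):
        traj = _hbond_traj((0, 0, 0), (3.346, 0, 0))
        events, _ = detect_anchor_hbonds(traj)
        assert len(events) == 1

    def test_beyond_distance_cutoff_rejected(self):
        traj = _hbond_traj((0, 0, 0), (3.6, 0, 0))
        events, occ = detect_anchor_hbonds(traj)
        assert events == []
        assert occ[(Address("B", 405, "N"), Address("B", 800, "O1"))] == 0.0

    def test_bent_geometry_rejected(self):
        # 90 degree D-H...A angle at 2.0 Å
        traj = _hbond_traj((0, 0, 0), (0, 2.0, 0))
        events, _ = detect_anchor_hbonds(traj)
        assert events == []

    def test_occupancy_counts_frames(self):
        base = _hbond_traj((0, 0, 0), (1.9, 0, 0))
        far = np.array([[-1.0, 0, 0], [0, 0, 0], [10.0, 0, 0]])
        frames = [base.frames[0], Frame(1, 0.1, far)]
        traj = Trajectory(base.topology, frames)
        _, occ = detect_anchor_hbonds(traj)
        assert occ[(Address("B", 405, "N"), Address("B", 800, "O1"))] == pytest.approx(0.5)

    def test_detection_invariant_under_rigid_motion(self, rng):
        from scipy.spatial.transform import Rotation

        traj = _hbond_traj((0, 0, 0), (2.5, 0.5, 0))
        R = Rotation.random(rng=rng).as_matrix()
        moved = Trajectory(
            traj.topology,
            [Frame(0, 0.0, traj.frames[0].coords @ R.T + rng.normal(size=3))],
        )
        e1, _ = detect_anchor_hbonds(traj)
        e2, _ = detect_anchor_hbonds(moved)
        assert len(e1) == len(e2) == 1
        assert e1[0].d_H_A == pytest.approx(e2[0].d_H_A, abs=1e-9)
        assert e1[0].angle_DHA == pytest.approx(e2[0].angle_DHA, abs=1e-6)


class TestHelix:
    @pytest.mark.parametrize("n_res,expected_turns", [(18, 5), (25, 7), (7, 2)])
    def test_ideal_helix_turn_counts(self, n_res, expected_turns):
        traj, spec = gen_ideal_helix(n_res)
        m = assign_helix(traj, traj.topology.helix_segments["helix"])[0]
        assert all(m.helical_flags)
        assert m.longest_run == n_res
        assert m.n_turns == expected_turns
        assert m.n_turns == spec.ground_truth["n_turns"]

    def test_partial_unwinding_mirrors_turn_loss(self):
        # a five-turn helix reduced to two turns by unwinding its first part
        traj, spec = gen_ideal_helix(18, unwound=(1, 11))
        m = assign_helix(traj, traj.topology.helix_segments["helix"])[0]
        assert m.longest_run == 7
        assert m.n_turns == 2
        assert list(m.helical_flags) == list(spec.ground_truth["helical_flags"])

    def test_displaced_residues_lose_helicity(self):
        # each residue of the 8-12 block moves >= 5 Å, with per-residue
        # directions so the block does not ride along as a rigid unit
        traj, _ = gen_ideal_helix(18)
        coords = traj.frames[0].coords.copy()
        atoms = traj.topology.atoms
        for i, a in enumerate(atoms):
            if 8 <= a.residue_number <= 12:
                coords[i] += np.array([5.0 * (a.residue_number - 7), 5.0, 0.0])
        moved = Trajectory(traj.topology, [Frame(0, 0.0, coords)])
        m = assign_helix(moved, traj.topology.helix_segments["helix"])[0]
        flags = dict(zip(range(1, 19), m.helical_flags))
        assert not any(flags[r] for r in range(8, 13))
        assert flags[1] and flags[18]

    def test_extended_chain_has_no_helicity(self):
        traj, _ = gen_ideal_helix(10, unwound=(1, 10))
        m = assign_helix(traj, traj.topology.helix_segments["helix"])[0]
        assert not any(m.helical_flags)
        assert m.n_turns == 0

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(n_res=st.integers(5, 40))
    def test_ideal_helix_fully_helical_any_length(self, n_res):
        traj, _ = gen_ideal_helix(n_res)
        m = assign_helix(traj, traj.topology.helix_segments["helix"])[0]
        assert all(m.helical_flags)


class TestTurnCounting:
    @pytest.mark.parametrize("run,expected", [(18, 5), (25, 7), (7, 2), (0, 0), (3, 1)])
    def test_turns_from_run_length(self, run, expected):
        flags = [True] * run + [False]
        assert count_turns(flags) == expected

    def test_longest_run_finds_interior_runs(self):
        flags = [True, False, True, True, True, False, True]
        assert longest_run(flags) == 3

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(a=st.integers(0, 50), b=st.integers(0, 10))
    def test_monotone_in_run_length(self, a, b):
        assert count_turns([True] * (a + b)) >= count_turns([True] * a)


class TestContacts:
    def test_static_pair(self):
        traj, _ = gen_contact_drift(5, 12.0, 12.0)
        pair = traj.topology.interface_pairs[0]
        s = contact_distance_series(traj, pair)
        assert s.mean == pytest.approx(12.0)
        assert s.sd == pytest.approx(0.0)

    def test_two_frame_mean(self):
        traj, _ = gen_contact_drift(2, 10.0, 14.0)
        s = contact_distance_series(traj, traj.topology.interface_pairs[0])
        assert s.mean == pytest.approx(12.0)

    def test_matches_generator_series(self):
        traj, spec = gen_contact_drift(50, 12.0, 17.0, noise_sd=0.3, seed=4)
        s = contact_distance_series(traj, traj.topology.interface_pairs[0])
        np.testing.assert_allclose(s.distances, spec.ground_truth["distances"], atol=1e-9)

    def test_unresolved_pair_rejected(self):
        traj, _ = gen_contact_drift(2, 10.0, 14.0)
        from loxmd.errors import UnresolvedAddressError

        with pytest.raises(UnresolvedAddressError):
            contact_distance_series(traj, (Address("A", 1, "XX"), traj.topology.interface_pairs[0][1]))
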