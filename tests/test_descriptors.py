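"""Descriptors: pair distances, aromatic contacts, hydration, RMSD."""

import numpy as np
import pytest

from bcct import descriptors as desc
from bcct.constants import TABLE1_PAIRS, TABLE2_CONTACTS
from bcct.structure import (AtomSelector, SelectionError, Trajectory,
                            read_structure, read_trajectory, select_atoms)
from bcct.synthetic import write_toy_structure


class TestCaDistances:
    def test_crystal_values_recovered(self, reference_traj):
        traj, truth = reference_traj
        for label, *_ in TABLE1_PAIRS:
            s = desc.ca_distance_series(traj, label)
            assert s.values[0] == pytest.approx(truth["table1"][label],
                                                abs=2e-3)

    def test_explicit_selectors(self, reference_traj):
        traj, _ = reference_traj
        s = desc.ca_distance_series(traj, AtomSelector("B", 26, "CA"),
                                    AtomSelector("B", 12, "CA"))
        assert s.values[0] == pytest.approx(7.2, abs=2e-3)

    def test_ambiguous_selector_rejected(self, toy_traj):
        with pytest.raises(SelectionError, match="exactly one"):
            desc.ca_distance_series(toy_traj,
                                    AtomSelector("B", None, "CA"),
                                    AtomSelector("B", 12, "CA"))

    def test_unknown_pair_label(self, toy_traj):
        with pytest.raises(KeyError, match="tracked pairs"):
            desc.ca_distance_series(toy_traj, "X99-Y99")

    def test_brute_force_oracle(self, toy_traj):
        st = toy_traj.structure
        ia = select_atoms(st, AtomSelector("B", 24, "CA"))[0]
        ib = select_atoms(st, AtomSelector("B", 15, "CA"))[0]
        s = desc.ca_distance_series(toy_traj, "F24-L15")
        for f in range(toy_traj.n_frames):
            d = np.sqrt(((toy_traj.frames[f, ia]
                          - toy_traj.frames[f, ib]) ** 2).sum())
            assert s.values[f] == pytest.approx(d, abs=1e-9)


class TestAromaticContacts:
    def test_crystal_values_recovered(self, reference_traj):
        traj, truth = reference_traj
        for label, ac, ar, pc, pr, crystal, *_ in TABLE2_CONTACTS:
            s = desc.aromatic_contact_series(traj, (ac, ar), (pc, pr),
                                             label=label)
            assert s.values[0] == pytest.approx(crystal, abs=2e-3)

    def test_ring_center_is_centroid(self, reference_traj):
        traj, _ = reference_traj
        st = traj.structure
        idx = select_atoms(st, AtomSelector("B", 24, "ring_carbons"))
        c = desc.ring_center(st, traj.frames[0], "B", 24)
        np.testing.assert_allclose(c, traj.frames[0, idx].mean(axis=0),
                                   atol=1e-12)

    def test_nearest_carbon_brute_force(self, toy_traj):
        st = toy_traj.structure
        ring = select_atoms(st, AtomSelector("B", 26, "ring_carbons"))
        part = select_atoms(st, AtomSelector("B", 12, "sidechain_carbons"))
        s = desc.aromatic_contact_series(toy_traj, ("B", 26), ("B", 12))
        for f in range(toy_traj.n_frames):
            centre = toy_traj.frames[f, ring].mean(axis=0)
            d = min(np.sqrt(((toy_traj.frames[f, j] - centre) ** 2).sum())
                    for j in part)
            assert s.values[f] == pytest.approx(d, abs=1e-9)

    def test_non_aromatic_rejected(self, toy_traj):
        with pytest.raises(SelectionError):
            desc.aromatic_contact_series(toy_traj, ("B", 15), ("B", 12))


class TestWaterCounts:
    def test_known_count_and_baseline(self):
        text, _ = write_toy_structure(
            core_water_distances=[3.0 + 0.5 * k for k in range(12)],
            n_far_waters=20)
        traj = read_trajectory(read_structure(text))
        ws = desc.water_count_series(traj)
        assert ws.raw[0] == 12
        assert ws.corrected[0] == 3

    def test_boundary_inclusive(self):
        text, _ = write_toy_structure(core_water_distances=[9.0, 9.1],
                                      n_far_waters=5)
        traj = read_trajectory(read_structure(text))
        ws = desc.water_count_series(traj)
        assert ws.raw[0] == 1  # the 9.000 A water counts, 9.1 does not

    def test_corrected_clamped_at_zero(self):
        text, _ = write_toy_structure(core_water_distances=[4.0, 5.0],
                                      n_far_waters=5)
        traj = read_trajectory(read_structure(text))
        ws = desc.water_count_series(traj)
        assert ws.raw[0] == 2
        assert ws.corrected[0] == 0

    def test_no_waters_warns_and_zero(self):
        text, _ = write_toy_structure(core_water_distances=[],
                                      n_far_waters=0)
        traj = read_trajectory(read_structure(text))
        with pytest.warns(UserWarning, match="no water"):
            ws = desc.water_count_series(traj)
        assert (ws.raw == 0).all()

    def test_brute_force_oracle(self, toy_traj):
        st = toy_traj.structure
        ws = desc.water_count_series(toy_traj)
        ic = select_atoms(st, AtomSelector("B", 15, "CG"))[0]
        wat = select_atoms(st, AtomSelector(atom_names="water_oxygen"))
        for f in range(toy_traj.n_frames):
            n = sum(np.sqrt(((toy_traj.frames[f, j]
                              - toy_traj.frames[f, ic]) ** 2).sum()) <= 9.0
                    for j in wat)
            assert ws.raw[f] == n

    def test_invalid_radius(self, toy_traj):
        with pytest.raises(ValueError):
            desc.water_count_series(toy_traj, radius=0.0)


class TestRmsd:
    def test_reference_frame_zero(self, toy_traj):
        s = desc.rmsd_series(toy_traj)
        assert s.values[0] == pytest.approx(0.0, abs=1e-5)
        assert (s.values[1:] > 1e-3).all()

    def test_rigid_motion_invariance(self, toy_structure):
        coords = toy_structure.coordinates
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta), 0],
                        [np.sin(theta), np.cos(theta), 0],
                        [0, 0, 1.0]])
        moved = coords @ rot.T + np.array([5.0, -3.0, 2.0])
        traj = read_trajectory(toy_structure,
                               np.stack([coords, moved]))
        s = desc.rmsd_series(traj)
        assert s.values[1] == pytest.approx(0.0, abs=1e-5)

    def test_too_few_atoms(self, toy_traj):
        with pytest.raises(SelectionError, match="at least 3"):
            desc.rmsd_series(toy_traj, AtomSelector("B", 26, "CA"))


class TestSummaries:
    def test_table1_closed_state_bands(self, wt_traj):
        """Generator closed-frame means fall inside the published
        closed-state mean +/- SD bands (the generator is calibrated to
        them)."""
        closed = wt_traj.true_states == "closed"
        for label, _, _, _, mean, sd in TABLE1_PAIRS:
            mu = wt_traj.series[label][closed].mean()
            assert mean - sd <= mu <= mean + sd, (label, mu)

    def test_table2_summary_layout(self, reference_traj):
        traj, _ = reference_traj
        df = desc.table2_summary(traj)
        assert list(df["contact"]) == [row[0] for row in TABLE2_CONTACTS]
        assert df["frame0_A"].round(1).tolist() == [5.2, 5.2, 5.2, 3.8]
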