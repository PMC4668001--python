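"""Generator: landscape validation, dynamics, water process, toy PDB."""

import math

import numpy as np
import pytest

import bcct.synthetic as S
from bcct.constants import STATE_NAMES, TABLE1_PAIRS
from bcct.synthetic import (CoordinateLandscape, LandscapeModel, Well,
                            WaterProcessParams, build_landscape,
                            simulate_langevin, simulate_trajectory,
                            simulate_water_process, stationary_marginals,
                            threshold_occupancies, write_toy_structure)


def single_well_model(width=1.0, center=8.0, n=2):
    coords = tuple(
        CoordinateLandscape(f"c{i}", (Well(center, 0.0, width),),
                            center + 1.0, center + 3.0)
        for i in range(n))
    return LandscapeModel(coords, coupling_strength=0.0, primary="c0")


class TestLandscapeValidation:
    def test_presets_build_and_validate(self):
        for preset in ("WT", "Y26G", "F24E", "wt", "Y26G-LIKE"):
            model = build_landscape(preset)
            S._validate_model(model)

    def test_unknown_preset(self):
        with pytest.raises(ValueError, match="unknown preset"):
            build_landscape("Y99Z")

    def test_nonpositive_width_rejected(self):
        c = CoordinateLandscape("x", (Well(8.0, 1.0, 0.0),), 9.0, 10.0)
        with pytest.raises(ValueError):
            S._validate_model(LandscapeModel((c,)))

    def test_threshold_order_rejected(self):
        c = CoordinateLandscape("x", (Well(8.0, 1.0, 0.5),), 10.0, 9.0)
        with pytest.raises(ValueError):
            S._validate_model(LandscapeModel((c,)))

    def test_zipper_violation_names_coordinate(self, wt_model):
        # deepen the outermost coordinate's well so its escape barrier
        # exceeds its inner neighbour's
        coords = []
        for c in wt_model.coordinates:
            if c.label == "T30-G8":
                wells = (Well(c.wells[0].center, 9.0, c.wells[0].width),
                         ) + c.wells[1:]
                c = CoordinateLandscape(c.label, wells, c.theta_open,
                                        c.theta_wide, c.exempt_from_zipper)
            coords.append(c)
        with pytest.raises(ValueError, match="T30-G8"):
            S._validate_model(LandscapeModel(
                tuple(coords), coupling_strength=wt_model.coupling_strength))

    def test_barriers_monotone_toward_hinge(self, wt_model):
        bars = S.barrier_heights(wt_model)
        assert all(bars[i] >= bars[i + 1] for i in range(len(bars) - 1))


class TestLangevin:
    def test_determinism(self, wt_model):
        a = simulate_langevin(wt_model, 200, seed=5)
        b = simulate_langevin(wt_model, 200, seed=5)
        for lab in a.series:
            np.testing.assert_array_equal(a.series[lab], b.series[lab])

    def test_seed_changes_trajectory(self, wt_model):
        a = simulate_langevin(wt_model, 200, seed=5)
        b = simulate_langevin(wt_model, 200, seed=6)
        assert not np.allclose(a.series["Y26-V12"], b.series["Y26-V12"])

    def test_unstable_dt_rejected(self, wt_model):
        with pytest.raises(ValueError, match="unstable time step"):
            simulate_langevin(wt_model, 10, dt=5.0)

    def test_invalid_args(self, wt_model):
        with pytest.raises(ValueError):
            simulate_langevin(wt_model, 0)
        with pytest.raises(ValueError):
            simulate_langevin(wt_model, 10, dt=-0.1)

    def test_distances_positive_and_equal_length(self, wt_traj):
        n = wt_traj.n_frames
        for lab, v in wt_traj.series.items():
            assert len(v) == n
            assert (v > 0).all()
        assert len(wt_traj.true_states) == n
        assert len(wt_traj.water_counts) == n

    def test_true_states_match_thresholds(self, wt_traj, wt_model):
        gate = wt_model.coordinate("Y26-V12")
        d = wt_traj.series["Y26-V12"]
        expect = np.where(d < gate.theta_open, "closed",
                          np.where(d >= gate.theta_wide, "wide_open",
                                   "open"))
        assert (wt_traj.true_states == expect).all()

    def test_near_zero_temperature_stays_at_minimum(self):
        model = LandscapeModel(single_well_model().coordinates,
                               coupling_strength=0.0, temperature=1e-6,
                               primary="c0")
        tr = simulate_langevin(model, 20, seed=1)
        for v in tr.series.values():
            assert np.allclose(v, 8.0, atol=1e-3)


class TestStationaryOracle:
    def test_marginals_normalised(self, wt_model):
        marg = stationary_marginals(wt_model)
        for lab, (x, p) in marg.items():
            dx = x[1] - x[0]
            assert p.sum() * dx == pytest.approx(1.0, abs=1e-9)
            assert (p >= 0).all()

    def test_uncoupled_marginal_matches_boltzmann(self):
        model = single_well_model(width=0.8, n=2)
        marg = stationary_marginals(model)
        x, p = marg["c0"]
        kT = model.kT
        u = model.potential(0, x)
        ref = np.exp(-(u - u.min()) / kT)
        ref /= ref.sum() * (x[1] - x[0])
        assert np.abs(p - ref).max() < 1e-9

    def test_sampled_occupancy_matches_oracle(self, wt_model, wt_traj):
        exact = threshold_occupancies(wt_model)
        gate = wt_model.coordinate("Y26-V12")
        d = wt_traj.series["Y26-V12"]
        sampled = ((d < gate.theta_open).mean(),
                   ((d >= gate.theta_open) & (d < gate.theta_wide)).mean(),
                   (d >= gate.theta_wide).mean())
        for s, e in zip(sampled, exact):
            assert s == pytest.approx(e, abs=0.03)

    def test_y26g_wide_open_dominant(self):
        occ = threshold_occupancies(build_landscape("Y26G"))
        assert occ[2] > 0.8 and occ[0] < 0.15


class TestWaterProcess:
    def test_params_validation(self):
        with pytest.raises(ValueError):
            WaterProcessParams(on_rate=-1)
        with pytest.raises(ValueError):
            WaterProcessParams(residual_mean=20, capacity=10)

    def test_counts_bounded_and_deterministic(self):
        gate = np.full(2000, 12.0)
        p = WaterProcessParams()
        a = simulate_water_process(gate, p, 10.0, seed=3)
        b = simulate_water_process(gate, p, 10.0, seed=3)
        np.testing.assert_array_equal(a, b)
        assert a.min() >= 0 and a.max() <= p.capacity

    def test_closed_gate_residual_only(self):
        gate = np.full(5000, 5.0)  # always below the 8.7 threshold
        p = WaterProcessParams()
        counts = simulate_water_process(gate, p, 10.0, seed=4)
        assert counts.max() <= p.residual_cap
        assert counts.mean() == pytest.approx(p.residual_mean, abs=0.3)

    def test_open_gate_mean_half_dozen(self):
        gate = np.full(5000, 12.0)
        p = WaterProcessParams()
        counts = simulate_water_process(gate, p, 10.0, seed=5)
        assert 5.0 < counts.mean() < 10.0

    def test_entry_confined_to_open_frames(self, wt_traj):
        """Counts above the residual cap occur (essentially) only while
        the gate is open; brief carry-over across a closing transition is
        the only exception."""
        p = WaterProcessParams()
        closed = wt_traj.series["Y26-V12"] < 8.7
        over = wt_traj.water_counts > p.residual_cap
        assert over[~closed].mean() > 0.5
        assert (over & closed).sum() / max(closed.sum(), 1) < 0.02

    def test_zero_off_rate_rejected(self):
        with pytest.raises(ValueError):
            simulate_water_process(np.ones(5), WaterProcessParams(off_rate=0),
                                   10.0)


class TestToyStructure:
    def test_crystal_distances_exact(self):
        _, truth = write_toy_structure()
        for label, _, _, crystal, *_ in TABLE1_PAIRS:
            assert truth["table1"][label] == pytest.approx(crystal, abs=5e-4)
        assert truth["table2"] == {"F24/L15": 5.2, "Y26/I2A": 5.2,
                                   "Y26/L11": 5.2, "Y26/V12": 3.8}

    def test_pdb_syntax(self):
        text, _ = write_toy_structure(n_frames=2)
        lines = text.splitlines()
        assert sum(ln.startswith("MODEL") for ln in lines) == 2
        assert sum(ln.startswith("ENDMDL") for ln in lines) == 2
        atom_lines = [ln for ln in lines
                      if ln.startswith(("ATOM", "HETATM"))]
        for ln in atom_lines:
            float(ln[30:38]); float(ln[38:46]); float(ln[46:54])
        waters = [ln for ln in atom_lines if ln[17:20] == "HOH"]
        assert len(waters) >= 30 * 2

    def test_known_in_sphere_water_count(self):
        # distances chosen clear of the 9 A boundary: PDB coordinates are
        # written to 3 decimals, which perturbs distances by up to ~2e-3
        text, truth = write_toy_structure(
            core_water_distances=[3.0, 8.9, 8.99], n_far_waters=30)
        center = truth["core_center"]
        lines = [ln for ln in text.splitlines() if ln.startswith("HETATM")]
        coords = np.array([[float(ln[30:38]), float(ln[38:46]),
                            float(ln[46:54])] for ln in lines])
        d = np.linalg.norm(coords - center, axis=1)
        assert (d <= 9.0).sum() == 3

    def test_invalid_n_frames(self):
        with pytest.raises(ValueError):
            write_toy_structure(n_frames=0)


def test_trajectory_roundtrip_csv(tmp_path, wt_model):
    tr = simulate_trajectory(wt_model, 50, seed=9)
    path = tmp_path / "series.csv"
    tr.write_csv(path)
    import pandas as pd

    df = pd.read_csv(path)
    assert list(df["frame"]) == list(range(50))
    np.testing.assert_allclose(df["Y26-V12"], tr.series["Y26-V12"],
                               rtol=0, atol=1e-6)
    assert set(df["true_state"]) <= set(STATE_NAMES)
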