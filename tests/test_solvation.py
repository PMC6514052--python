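"""Hydration shells, block averaging, bridging waters and residence times."""

import numpy as np
import pytest

import lbdkit as lk
from conftest import trajectory_from_coords
from lbdkit.errors import ConfigurationError
from lbdkit.geometry import TimeSeries
from lbdkit.solvation import (
    ResidenceInterval, SolvationConfig, block_average, bridging_water_events,
    hydration_count_series, residence_summary, waters_in_shell,
)
from lbdkit.structio import AtomRecord, Frame, SelectionMask, Topology, Trajectory
from lbdkit.synthetic import SyntheticSpec, WaterEvent, make_transition_trajectory, plant_solvent


def solvated(n_frames=20, n_waters=4, schedule=None, noise=0.0):
    spec = SyntheticSpec(n_frames=n_frames, noise_sigma=noise,
                         n_waters=n_waters, water_schedule=schedule)
    traj, refs, _ = make_transition_trajectory(spec)
    traj, truth = plant_solvent(traj, spec)
    return traj, truth


def masks(traj):
    return lk.select(traj.topology, "protein"), lk.select(traj.topology, "water")


class TestHydrationCounts:
    def test_no_waters_gives_zero(self):
        spec = SyntheticSpec(n_frames=5, noise_sigma=0.0)
        traj, refs, _ = make_transition_trajectory(spec)
        solute = lk.select(traj.topology, "protein")
        empty = SelectionMask(())
        series = hydration_count_series(traj, solute, empty)
        assert np.all(series.values == 0)

    def test_counts_equal_planted_truth(self):
        traj, truth = solvated(n_frames=30, n_waters=6, noise=0.01)
        solute, water = masks(traj)
        series = hydration_count_series(traj, solute, water)
        assert np.array_equal(series.values, truth.shell_counts)

    def test_boundary_water_counted_inclusively(self):
        schedule = [WaterEvent(0, 2, 4, "shell_boundary")]
        traj, truth = solvated(n_frames=6, n_waters=1, schedule=schedule)
        solute, water = masks(traj)
        series = hydration_count_series(traj, solute, water)
        assert series.values.tolist() == [0, 0, 1, 1, 1, 0]

    def test_distance_exactly_at_cutoff_counted(self):
        """Inclusive boundary rule with exactly representable coordinates."""
        solute = np.array([[0.0, 0.0, 0.0]])
        waters = np.array([[0.5, 0.0, 0.0], [0.5000001, 0.0, 0.0]])
        for method in ("cell", "brute"):
            inside = waters_in_shell(solute, waters, 0.5, method=method)
            assert inside.tolist() == [True, False]

    def test_cell_list_equals_brute_force(self, rng):
        solute = rng.uniform(0, 3, size=(40, 3))
        waters = rng.uniform(-1, 4, size=(500, 3))
        for box in (None, np.eye(3) * 5.0):
            cell = waters_in_shell(solute, waters, 0.5, box=box, method="cell")
            brute = waters_in_shell(solute, waters, 0.5, box=box, method="brute")
            assert np.array_equal(cell, brute)

    def test_count_monotone_in_cutoff(self, rng):
        traj, _ = solvated(n_frames=10, n_waters=5, noise=0.01)
        solute, water = masks(traj)
        previous = None
        for cutoff in (0.2, 0.35, 0.5, 1.0, 3.0):
            counts = hydration_count_series(
                traj, solute, water, SolvationConfig(shell_cutoff=cutoff)).values
            if previous is not None:
                assert np.all(counts >= previous)
            previous = counts

    def test_overlapping_masks_rejected(self):
        traj, _ = solvated(n_frames=3, n_waters=1)
        solute, water = masks(traj)
        with pytest.raises(ConfigurationError):
            hydration_count_series(traj, solute, solute)


class TestBlockAverage:
    def test_block_one_is_identity(self):
        ts = TimeSeries(np.arange(5.0), np.array([1.0, 4.0, 2.0, 8.0, 5.0]))
        out = block_average(ts, 1)
        assert np.array_equal(out.values, ts.values)

    def test_constant_series_stays_constant(self):
        ts = TimeSeries(np.arange(10.0), np.full(10, 3.3))
        assert np.allclose(block_average(ts, 4).values, 3.3)

    def test_arithmetic_example(self):
        ts = TimeSeries(np.arange(10.0), np.arange(1.0, 11.0))
        out = block_average(ts, 5)
        assert out.values.tolist() == [3.0, 8.0]
        assert out.meta["partial_final_block"] is False

    def test_partial_trailing_block_flagged(self):
        ts = TimeSeries(np.arange(7.0), np.arange(7.0))
        out = block_average(ts, 5)
        assert len(out) == 2
        assert out.meta["partial_final_block"] is True

    def test_strict_mode_rejects_oversized_block(self):
        ts = TimeSeries(np.arange(3.0), np.arange(3.0))
        with pytest.raises(ConfigurationError):
            block_average(ts, 10, strict=True)


class TestBridgingWaters:
    def site_masks(self, traj):
        return (lk.select(traj.topology, "name NE1"),
                lk.select(traj.topology, "resid 756 and name N"))

    def test_full_span_single_interval(self):
        schedule = [WaterEvent(0, 0, 19, "bridge")]
        traj, truth = solvated(n_frames=20, n_waters=1, schedule=schedule)
        sa, sb = self.site_masks(traj)
        _, water = masks(traj)
        events = bridging_water_events(traj, sa, sb, water)
        assert len(events) == 1
        ev = events[0]
        assert (ev.start_time, ev.end_time) == (0.0, 19 * 100.0)
        assert ev.duration == pytest.approx(20 * 100.0)

    def test_scripted_gap_pattern(self):
        # occupancy pattern 1-1-1-0-1-1 over six frames
        schedule = [WaterEvent(0, 0, 2, "bridge"), WaterEvent(0, 4, 5, "bridge")]
        traj, truth = solvated(n_frames=6, n_waters=1, schedule=schedule)
        sa, sb = self.site_masks(traj)
        _, water = masks(traj)
        strict = bridging_water_events(traj, sa, sb, water,
                                       SolvationConfig(gap_tolerance=0))
        assert [(e.start_time, e.end_time) for e in strict] == [
            (0.0, 200.0), (400.0, 500.0)]
        merged = bridging_water_events(traj, sa, sb, water,
                                       SolvationConfig(gap_tolerance=1))
        assert [(e.start_time, e.end_time) for e in merged] == [(0.0, 500.0)]

    def test_recovered_intervals_equal_planted_truth(self):
        schedule = [WaterEvent(0, 3, 9, "bridge"), WaterEvent(1, 5, 6, "bridge"),
                    WaterEvent(2, 0, 14, "shell")]
        traj, truth = solvated(n_frames=15, n_waters=3, schedule=schedule)
        sa, sb = self.site_masks(traj)
        _, water = masks(traj)
        events = bridging_water_events(traj, sa, sb, water)
        got = [(e.water_id, e.start_time, e.end_time) for e in events]
        expected = [(e.water_id, e.start_time, e.end_time)
                    for e in truth.bridge_intervals]
        assert got == expected

    def test_water_near_one_site_only_gives_nothing(self):
        schedule = [WaterEvent(0, 0, 9, "shell")]
        traj, _ = solvated(n_frames=10, n_waters=1, schedule=schedule)
        sa, sb = self.site_masks(traj)
        _, water = masks(traj)
        assert bridging_water_events(traj, sa, sb, water) == []

    def test_multi_atom_site_mask_rejected(self):
        traj, _ = solvated(n_frames=3, n_waters=1)
        solute, water = masks(traj)
        sa, _ = self.site_masks(traj)
        with pytest.raises(ConfigurationError):
            bridging_water_events(traj, solute, sa, water)

    def test_frame_conservation_on_scripted_data(self):
        """Total frames inside recovered intervals = scripted bridge frames."""
        schedule = [WaterEvent(0, 2, 6, "bridge"), WaterEvent(0, 10, 11, "bridge")]
        traj, _ = solvated(n_frames=14, n_waters=1, schedule=schedule)
        sa, sb = self.site_masks(traj)
        _, water = masks(traj)
        events = bridging_water_events(traj, sa, sb, water)
        total_frames = sum(
            int((e.end_time - e.start_time) / 100.0) + 1 for e in events)
        assert total_frames == 5 + 2


class TestResidenceSummary:
    def test_empty_list(self):
        assert residence_summary([]) == {"count": 0, "mean_ps": None, "max_ps": None}

    def test_arithmetic(self):
        ivs = [
            ResidenceInterval(("W", 1), 0.0, 8.0, "s", 10.0),
            ResidenceInterval(("W", 2), 5.0, 33.0, "s", 30.0),
        ]
        out = residence_summary(ivs)
        assert out == {"count": 2, "mean_ps": 20.0, "max_ps": 30.0}
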