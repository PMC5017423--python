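import numpy as np
import pytest
from scipy.spatial import cKDTree

from pillarbeat.detect import (InsufficientDataError, detect_pillars,
                               select_reference_frame)
from pillarbeat.mechanics import SpringConstant
from pillarbeat.track import (Trajectory, build_tracks_table,
                              estimate_reference, to_displacement, to_force,
                              track_pillars)


def truth_order(pillars, truth):
    _, idx = cKDTree(truth.centers_px).query(pillars.centers_px)
    return idx


class TestTrackPillars:
    def test_noise_free_rmse_below_0p1_px(self, tracked_small, small_noisefree):
        _, truth, pillars, trajectories, _ = tracked_small
        idx = truth_order(pillars, truth)
        errs = np.concatenate([
            np.linalg.norm(t.positions_px - truth.positions_px[:, i, :], axis=1)
            for t, i in zip(trajectories, idx)
        ])
        assert np.sqrt((errs**2).mean()) < 0.1

    def test_snr10_rmse_below_0p3_px(self, small_snr10):
        stack, truth = small_snr10
        ref = select_reference_frame(stack.data)
        pillars = detect_pillars(stack.data[ref], 16.0, 36.8)
        trajectories = track_pillars(stack, pillars, 10.0, reference_frame=ref)
        idx = truth_order(pillars, truth)
        errs = np.concatenate([
            np.linalg.norm(t.positions_px - truth.positions_px[:, i, :], axis=1)
            for t, i in zip(trajectories, idx)
        ])
        assert np.sqrt((errs**2).mean()) < 0.3

    def test_static_scene_constant_trajectories(self, static_stack):
        stack, truth = static_stack
        pillars = detect_pillars(stack.data[0], 16.0, 36.8)
        trajectories = track_pillars(stack, pillars, 5.0, reference_frame=0)
        for t in trajectories:
            spread = np.abs(t.positions_px - t.positions_px[0]).max()
            assert spread < 0.05
            assert not t.lost.any()

    def test_integer_translation_invariance(self, small_noisefree):
        """Tracking error does not depend on where the scene sits in the frame."""
        stack, _ = small_noisefree
        ref = select_reference_frame(stack.data)
        pillars = detect_pillars(stack.data[ref], 16.0, 36.8)
        base = track_pillars(stack, pillars, 10.0, reference_frame=ref)

        rolled = type(stack)(np.roll(stack.data, (4, 6), axis=(1, 2)),
                             stack.pixel_size_um, stack.frame_rate_fps)
        pillars_r = detect_pillars(rolled.data[ref], 16.0, 36.8)
        moved = track_pillars(rolled, pillars_r, 10.0, reference_frame=ref)
        for a, b in zip(base, moved):
            np.testing.assert_allclose(
                b.positions_px - np.array([6, 4]), a.positions_px, atol=0.05)

    def test_empty_pillar_set_rejected(self, small_noisefree):
        from pillarbeat.detect import PillarSet
        stack, _ = small_noisefree
        empty = PillarSet(np.array([], int), np.empty((0, 2)), 16.0, np.array([]))
        with pytest.raises(ValueError, match="empty"):
            track_pillars(stack, empty)


class TestEstimateReference:
    def test_recovers_resting_center(self, tracked_small):
        _, truth, pillars, trajectories, _ = tracked_small
        idx = truth_order(pillars, truth)
        for t, i in zip(trajectories, idx):
            ref = estimate_reference(t)
            assert np.linalg.norm(ref - truth.centers_px[i]) < 0.1

    def test_constant_trajectory_reference_is_that_constant(self):
        pos = np.tile([12.0, 34.0], (50, 1))
        traj = Trajectory(0, pos, np.ones(50), np.zeros(50, bool))
        np.testing.assert_allclose(estimate_reference(traj), [12.0, 34.0],
                                   atol=1e-9)

    def test_fixed_frame_method(self):
        pos = np.cumsum(np.ones((20, 2)), axis=0)
        traj = Trajectory(0, pos, np.ones(20), np.zeros(20, bool))
        np.testing.assert_allclose(
            estimate_reference(traj, "fixed-frame", frame_index=3), pos[3])

    def test_rolling_baseline_tolerates_drift(self):
        """With slow linear drift the rolling baseline keeps deflections
        honest while a fixed frame reference does not."""
        from pillarbeat.simulate import TwitchWaveform, twitch_displacement
        fps, T = 25.0, 250
        t = np.arange(T) / fps
        pulse = twitch_displacement(TwitchWaveform(amplitude_um=3.0), t) / 0.5
        drift = 0.02 * np.arange(T)  # 5 px over the recording
        pos = np.column_stack([100 + drift + pulse, np.full(T, 50.0)])
        traj = Trajectory(0, pos, np.ones(T), np.zeros(T, bool))

        ref_roll = estimate_reference(traj, "rolling", window_frames=50)
        resting = pulse == 0
        roll_err = np.abs((pos[:, 0] - ref_roll[:, 0]))[resting]
        assert np.median(roll_err) < 0.2

        ref_fixed = estimate_reference(traj, "fixed-frame", frame_index=0)
        fixed_err = np.abs(pos[:, 0] - ref_fixed[0])[resting]
        assert fixed_err.max() > 2.0  # drift corrupts the fixed reference

    def test_all_lost_trajectory_rejected(self):
        traj = Trajectory(0, np.zeros((20, 2)), np.zeros(20), np.ones(20, bool))
        with pytest.raises(InsufficientDataError):
            estimate_reference(traj)

    def test_too_short_trajectory_rejected(self):
        traj = Trajectory(0, np.zeros((5, 2)), np.ones(5), np.zeros(5, bool))
        with pytest.raises(InsufficientDataError):
            estimate_reference(traj)


class TestToDisplacement:
    def _traj(self, deltas_px, ref=(10.0, 10.0)):
        pos = np.asarray(ref) + np.asarray(deltas_px, float)
        n = len(pos)
        return Trajectory(0, pos, np.ones(n), np.zeros(n, bool)), np.asarray(ref)

    def test_identity_case_all_zero(self):
        traj, ref = self._traj(np.zeros((30, 2)))
        ser = to_displacement(traj, ref, 0.5, 25.0)
        assert np.all(ser.d_um == 0)

    def test_hand_arithmetic_with_y_flip(self):
        """An image delta of (4, -3) px at 0.5 um/px is a physical deflection
        of (2, 1.5) um with magnitude 2.5 um (image y points down)."""
        traj, ref = self._traj([[0, 0], [4, -3]])
        ser = to_displacement(traj, ref, 0.5, 25.0)
        assert ser.dx_um[1] == pytest.approx(2.0)
        assert ser.dy_um[1] == pytest.approx(1.5)
        assert ser.d_um[1] == pytest.approx(2.5)

    def test_exactly_linear_in_pixel_size(self):
        traj, ref = self._traj([[1, 2], [3, -4], [0.5, 0.25]])
        a = to_displacement(traj, ref, 0.5, 25.0)
        b = to_displacement(traj, ref, 1.5, 25.0)
        np.testing.assert_allclose(b.d_um, 3.0 * a.d_um, rtol=1e-12)

    def test_peak_magnitude_matches_waveform(self, tracked_small):
        _, truth, _, _, series = tracked_small
        for ser in series:
            assert ser.d_um.max() == pytest.approx(
                truth.waveform.amplitude_um, abs=0.1)

    def test_nonpositive_pixel_size_rejected(self):
        traj, ref = self._traj(np.zeros((10, 2)))
        with pytest.raises(ValueError):
            to_displacement(traj, ref, 0.0, 25.0)


class TestToForce:
    def test_day7_peak_force(self, tracked_small):
        """A 3.0071 um peak at k = 0.04 N/m is a 0.1202 uN peak force."""
        import math
        _, _, _, _, series = tracked_small
        ser = series[0]
        scaled = ser.d_um * (3.0071 / ser.d_um.max())
        ser2 = type(ser)(ser.pillar_id, ser.reference_px, ser.pixel_size_um,
                         ser.frame_rate_fps, scaled, np.zeros_like(scaled),
                         ser.lost)
        f = to_force(ser2, SpringConstant(0.04))
        assert math.floor(f.max() * 1e4) / 1e4 == 0.1202

    def test_zero_series_zero_force(self):
        traj = Trajectory(0, np.full((30, 2), 5.0), np.ones(30),
                          np.zeros(30, bool))
        ser = to_displacement(traj, np.array([5.0, 5.0]), 0.5, 25.0)
        assert np.all(to_force(ser, 0.04) == 0)

    def test_doubling_k_doubles_force(self, tracked_small):
        _, _, _, _, series = tracked_small
        f1 = to_force(series[0], 0.04)
        f2 = to_force(series[0], 0.08)
        np.testing.assert_allclose(f2, 2 * f1, rtol=1e-12)


class TestTracksTable:
    def test_tidy_schema_and_length(self, tracked_small):
        _, _, _, trajectories, series = tracked_small
        table = build_tracks_table(trajectories, series, 0.04)
        assert list(table.columns) == [
            "pillar_id", "frame", "time_s", "x_px", "y_px", "dx_um", "dy_um",
            "d_um", "force_un", "quality", "lost"]
        assert len(table) == sum(t.n_frames for t in trajectories)
        np.testing.assert_allclose(table["force_un"], table["d_um"] * 0.04)
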