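"""Episode termination rules and gait metrics."""

import numpy as np
import pytest

from reflexgait.episode import (
    MAXIMIZE,
    MINIMIZE,
    classify_gait,
    completed_distance,
    gait_cycle_angles,
    moving_average_velocity,
    rms_vs_reference,
    run_episode,
    stride_events,
)
from reflexgait.controller import ParameterVector


class TestCompletedDistance:
    def test_rigid_translation_gives_same_distance_either_direction(self):
        traj = np.array([[0.0, 0.0], [10.0, 10.0]])
        assert completed_distance(traj, MINIMIZE) == 10.0
        assert completed_distance(traj, MAXIMIZE) == 10.0

    def test_stationary_model_travels_zero(self):
        traj = np.zeros((5, 3))
        assert completed_distance(traj, MAXIMIZE) == 0.0

    def test_selection_rule_on_two_segments(self):
        """Maximization selects the segment nearest the origin at the end
        (the trailing one), minimization the farthest."""
        traj = np.array([[0.0, 0.0], [3.0, 5.0]])
        assert completed_distance(traj, MAXIMIZE) == 3.0
        assert completed_distance(traj, MINIMIZE) == 5.0

    def test_empty_trajectory_rejected(self):
        with pytest.raises(ValueError):
            completed_distance(np.empty((0, 2)), MAXIMIZE)

    def test_unknown_direction_rejected(self):
        with pytest.raises(ValueError):
            completed_distance(np.zeros((2, 2)), "sideways")


class TestMovingAverage:
    def test_constant_series_unchanged(self):
        v = np.full(400, 1.2)
        out = moving_average_velocity(v, dt=0.01, window=1.0)
        assert np.allclose(out, 1.2)

    def test_unit_step_rises_linearly_over_one_window(self):
        dt = 0.01
        v = np.concatenate([np.zeros(200), np.ones(200)])
        out = moving_average_velocity(v, dt, window=1.0)
        w = 100
        # linear ramp completing exactly one window after the step
        assert out[199] == 0.0
        assert out[199 + w // 2] == pytest.approx(0.5, abs=0.011)
        assert np.allclose(out[199 + w :], 1.0)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="shorter than window"):
            moving_average_velocity(np.ones(40), dt=0.01, window=1.0)

    def test_matches_brute_force_windowed_mean_exactly(self):
        rng = np.random.default_rng(3)
        v = rng.normal(size=500)
        dt, window = 0.02, 1.0
        out = moving_average_velocity(v, dt, window)
        w = int(round(window / dt))
        for k in range(len(v)):
            lo = max(0, k - w + 1)
            assert out[k] == np.mean(v[lo : k + 1])


class TestGaitClassification:
    def _trace(self, pattern, reps):
        """Build an (n, 2) contact trace from a repeated support pattern."""
        return np.array(pattern * reps, dtype=bool)

    def test_alternating_single_double_support_is_walking(self):
        stride = [[1, 1]] * 3 + [[1, 0]] * 7 + [[1, 1]] * 3 + [[0, 1]] * 7
        trace = self._trace(stride, 6)
        assert classify_gait(trace) == "walk"

    def test_periodic_flight_phases_are_running(self):
        stride = [[1, 0]] * 5 + [[0, 0]] * 4 + [[0, 1]] * 5 + [[0, 0]] * 4
        trace = self._trace(stride, 6)
        assert classify_gait(trace) == "run"

    def test_single_stride_is_unclassified(self):
        stride = [[1, 0]] * 5 + [[0, 0]] * 5
        assert classify_gait(self._trace(stride, 1)) == "none"

    def test_hopper_trace_with_flight_is_running(self):
        hop = [[1]] * 6 + [[0]] * 6
        assert classify_gait(np.array(hop * 8, dtype=bool)) == "run"


class TestStrideEvents:
    def test_square_wave_toe_off_at_falling_edges(self):
        dt = 0.01
        f = np.tile(np.concatenate([np.full(30, 400.0), np.zeros(20)]), 5)
        ev = stride_events(f, dt, threshold_on=20.0)
        assert len(ev.heel_strikes) == 5
        assert len(ev.toe_offs) == 5
        # falling edges at samples 30, 80, 130, ...
        assert np.allclose(ev.toe_offs, (np.arange(5) * 50 + 30) * dt)
        assert ev.stance_fraction == pytest.approx(0.6, abs=0.02)

    def test_no_cycles_detected_raises(self):
        with pytest.raises(ValueError, match="no complete gait cycles"):
            stride_events(np.zeros(100), 0.01)


class TestCycleCurvesAndRms:
    def test_identical_curves_have_zero_rms(self):
        curves = np.random.default_rng(0).normal(size=(101, 3))
        assert np.allclose(rms_vs_reference(curves, curves), 0.0)

    def test_constant_offset_gives_that_rms(self):
        base = np.zeros((101, 3))
        assert np.allclose(rms_vs_reference(base + 5.0, base), 5.0)

    def test_cycle_resampling_shape_and_endpoint(self):
        t = np.arange(300)
        angles = np.stack([np.sin(0.1 * t), np.cos(0.1 * t)], axis=1)
        cycles = gait_cycle_angles(angles, [0, 100, 200], n_phase=101)
        assert cycles.shape == (2, 101, 2)
        assert cycles[0, 0, 0] == angles[0, 0]
        assert cycles[0, -1, 0] == angles[100, 0]


class TestRunEpisode:
    def test_baseline_toy_episode_is_stable_and_fully_timed(self, baseline_episode, toy_cfg):
        assert baseline_episode.stable
        assert baseline_episode.t_sim == toy_cfg.t_max
        assert baseline_episode.v_act is not None and baseline_episode.v_act > 0
        assert baseline_episode.gait == "run"

    def test_zero_parameters_fall_before_t_max(self, toy, toy_cfg):
        plant, _ = toy
        p = ParameterVector.zeros(plant.connection_matrix)
        result = run_episode(plant, p, toy_cfg)
        assert not result.stable
        assert result.t_sim < toy_cfg.t_max
        assert result.v_act is None

    def test_identical_inputs_give_identical_results(self, toy, toy_cfg):
        plant, p0 = toy
        a = run_episode(plant, p0, toy_cfg)
        b = run_episode(plant, p0, toy_cfg)
        assert a.t_sim == b.t_sim
        assert np.array_equal(a.trajectories["com_x"], b.trajectories["com_x"])
        assert np.array_equal(a.trajectories["torso_vx"], b.trajectories["torso_vx"])

    def test_stability_flag_iff_full_duration(self, baseline_episode):
        assert baseline_episode.stable == (
            baseline_episode.t_sim == baseline_episode.t_max
        )
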