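"""Target-speed schedules, online modulation and gait transitions."""

import numpy as np
import pytest

from reflexgait.controller import ParameterVector
from reflexgait.key_params import KeySelection
from reflexgait.online import (
    Schedule,
    TransitionPlan,
    run_online,
    run_transition,
    schedule_switches,
    schedule_value,
)
from reflexgait.smf import SMFModel
from reflexgait.episode import run_episode
from reflexgait.toybench import toy_episode_config


def constant_model(p0):
    """SMF whose assembly returns the baseline vector at every speed."""
    keys = KeySelection(n_key=1, indices=(4,), kinds=("kF",))
    beta = np.zeros((1, 4))
    beta[0, 0] = p0.encode()[4]
    return SMFModel(degree=1, keys=keys, beta=beta, p_init=p0)


class TestScheduleValues:
    def test_settle_period_holds_start_speed(self):
        for kind in ("constant", "step", "ramp"):
            s = Schedule(kind=kind, v_min=1.0, v_max=1.7, j=3)
            assert schedule_value(s, 5.0) == s.v_start

    def test_start_speed_is_midrange(self):
        s = Schedule(kind="ramp", v_min=1.0, v_max=1.7)
        assert s.v_start == pytest.approx(1.35)

    def test_step_jump_is_exactly_j_quanta(self):
        s = Schedule(kind="step", v_min=0.9, v_max=1.1, j=1, direction=1)
        assert schedule_value(s, 20.0) == pytest.approx(s.v_start + 0.025)
        down = Schedule(kind="step", v_min=0.9, v_max=1.1, j=4, direction=-1)
        assert schedule_value(down, 25.0) == pytest.approx(down.v_start - 0.1)

    def test_ramp_period_formula(self):
        s = Schedule(kind="ramp", v_min=1.0, v_max=1.7)  # span 0.7 m/s
        assert s.period == pytest.approx(28.0)

    def test_ramp_starts_at_midrange_and_rises_first(self):
        s = Schedule(kind="ramp", v_min=1.0, v_max=1.7)
        v0 = schedule_value(s, s.settle)
        assert v0 == pytest.approx(s.v_start)
        assert schedule_value(s, s.settle + 1.0) > v0

    def test_ramp_analytics_against_dense_evaluation(self):
        """Period, extrema and slope magnitude of the triangle wave."""
        s = Schedule(kind="ramp", v_min=0.8, v_max=1.5)
        tau = np.linspace(0, 2 * s.period, 40001)
        v = np.array([schedule_value(s, s.settle + t) for t in tau])
        assert v.min() == pytest.approx(s.v_min, abs=1e-6)
        assert v.max() == pytest.approx(s.v_max, abs=1e-6)
        # periodicity
        n_quarter = np.searchsorted(tau, s.period)
        assert np.allclose(v[: len(v) - n_quarter], v[n_quarter:], atol=1e-9)
        slopes = np.abs(np.diff(v) / np.diff(tau))
        interior = slopes[(slopes > 1e-9)]
        assert np.quantile(interior, 0.02) == pytest.approx(s.v_a, rel=1e-3)
        assert np.quantile(interior, 0.98) == pytest.approx(s.v_a, rel=1e-3)

    def test_invalid_schedules_rejected(self):
        with pytest.raises(ValueError):
            Schedule(kind="step", v_min=1.0, v_max=1.5, j=0)
        with pytest.raises(ValueError):
            Schedule(kind="warp", v_min=1.0, v_max=1.5)

    def test_step_switch_events_single_discontinuity(self, toy):
        _, p0 = toy
        s = Schedule(kind="step", v_min=1.0, v_max=1.5, j=2)
        events = schedule_switches(s, constant_model(p0), t_max=50.0)
        assert len(events) == 1
        assert events[0][0] == s.settle

    def test_constant_schedule_generates_no_events(self, toy):
        _, p0 = toy
        s = Schedule(kind="constant", v_min=1.0, v_max=1.5)
        assert schedule_switches(s, constant_model(p0), t_max=50.0) == []


class TestRunOnline:
    def test_constant_schedule_bit_identical_to_offline_episode(self, toy):
        plant, p0 = toy
        cfg = toy_episode_config(t_max=5.0, transient=1.0)
        model = constant_model(p0)
        s = Schedule(kind="constant", v_min=1.5, v_max=2.5)
        online = run_online(plant, model, s, cfg)
        offline = run_episode(plant, p0, cfg)
        for key in ("com_x", "com_y", "torso_vx"):
            assert np.array_equal(
                online.episode.trajectories[key], offline.trajectories[key]
            )
        assert np.all(online.v_tgt == s.v_start)

    def test_parameters_change_only_at_update_instants(self, toy):
        plant, p0 = toy
        cfg = toy_episode_config(t_max=22.0, transient=2.0)
        model = constant_model(p0)
        s = Schedule(kind="step", v_min=1.5, v_max=2.5, j=1)
        res = run_online(plant, model, s, cfg)
        assert res.episode.switch_times == (20.0,)


class TestTransitions:
    def test_identical_sets_match_plain_episode(self, toy):
        plant, p0 = toy
        cfg = toy_episode_config(t_max=12.0, transient=2.0)
        plan = TransitionPlan([p0.copy(), p0.copy()])
        res = run_transition(plant, plan, cfg)
        plain = run_episode(plant, p0, cfg)
        assert np.array_equal(
            res.episode.trajectories["com_x"], plain.trajectories["com_x"]
        )
        assert res.episode.switch_times == (10.0,)

    def test_four_set_plan_switches_at_10s_intervals(self, std_matrix):
        p = ParameterVector.zeros(std_matrix)
        plan = TransitionPlan([p, p, p, p])
        assert plan.switch_times == (10.0, 20.0, 30.0)
        assert plan.dimension == 4 * 71

    def test_two_set_plan_searches_142_dimensions(self, std_matrix):
        p = ParameterVector.zeros(std_matrix)
        plan = TransitionPlan([p, p])
        assert plan.dimension == 142
        x = plan.encode()
        assert x.shape == (142,)
        back = plan.with_encoded(x + 1.0)
        assert np.all(back.param_sets[0].encode() == 1.0)

    def test_single_set_plan_rejected(self, std_matrix):
        with pytest.raises(ValueError):
            TransitionPlan([ParameterVector.zeros(std_matrix)])


class TestLargestStableStep:
    def test_robust_model_exhausts_the_scan(self, toy):
        plant, p0 = toy
        cfg = toy_episode_config(t_max=22.0, transient=2.0)
        model = constant_model(p0)  # every target assembles the stable baseline
        from reflexgait.online import largest_stable_step

        j_star, dv = largest_stable_step(
            plant, model, direction=1, v_bounds=(1.8, 2.6), episode_cfg=cfg, j_max=2
        )
        assert j_star == 2
        assert dv == pytest.approx(0.05)

    def test_always_falling_model_reports_zero(self, toy):
        plant, p0 = toy
        cfg = toy_episode_config(t_max=22.0, transient=2.0)
        from reflexgait.online import largest_stable_step
        from reflexgait.smf import SMFModel
        from reflexgait.key_params import KeySelection

        zeros = ParameterVector.zeros(plant.connection_matrix)
        keys = KeySelection(1, (4,), ("kF",))
        model = SMFModel(degree=1, keys=keys, beta=np.zeros((1, 4)), p_init=zeros)
        j_star, dv = largest_stable_step(
            plant, model, direction=1, v_bounds=(1.8, 2.6), episode_cfg=cfg, j_max=3
        )
        assert (j_star, dv) == (0, 0.0)


class TestOptimizeTransition:
    def test_already_surviving_plan_terminates_at_zero_objective(self, toy):
        from reflexgait.online import optimize_transition
        from reflexgait.speed_opt import CmaConfig

        plant, p0 = toy
        cfg = toy_episode_config(t_max=6.0, transient=1.0)
        plan = TransitionPlan([p0.copy(), p0.copy()], interval=2.0)
        cma_cfg = CmaConfig(sigma0=0.02, n_seeds=1, max_generations=3, popsize=4,
                            improve_window=50)
        optimized, res = optimize_transition(plant, plan, cma_cfg, cfg, seed=0)
        assert res.f_best == 0.0
        assert res.stop_reason == "f_target"
        final = run_transition(plant, optimized, cfg)
        assert final.episode.stable
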