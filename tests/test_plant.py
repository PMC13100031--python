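"""Rigid-body engine, ground contact and the seven-segment humanoid."""

import math

import numpy as np
import pytest

from reflexgait.controller import ParameterVector
from reflexgait.episode import EpisodeConfig, run_episode
from reflexgait.plant import (
    BipedPlant,
    BodySpec,
    ContactParams,
    PlanarTree,
    PlantConfig,
    SegmentSpec,
    build_standard_human,
)
from reflexgait.plant.biped import ConfigurationError, default_segments
from reflexgait.plant.contact import friction_force, normal_force, point_contact_force


@pytest.fixture(scope="module")
def biped():
    return build_standard_human()


class TestRigidEngine:
    def test_free_body_without_gravity_stays_put(self):
        tree = PlanarTree(
            [
                BodySpec("bx", -1, "px", (0, 0), 0.0, (0, 0), 0.0),
                BodySpec("by", 0, "py", (0, 0), 0.0, (0, 0), 0.0),
                BodySpec("b", 1, "rz", (0, 0), 2.0, (0.1, 0.0), 0.05),
            ],
            gravity=0.0,
        )
        q, qd = np.array([0.1, 0.2, 0.3]), np.zeros(3)
        q2, qd2 = tree.step(q, qd, np.zeros(3), 1e-3)
        assert np.array_equal(q2, q)
        assert np.array_equal(qd2, np.zeros(3))

    def test_passive_pendulum_energy_drift_below_0p1_percent(self):
        """Semi-implicit integration of an unactuated single pendulum keeps
        the total mechanical energy within 0.1 % over 10 s at the default
        0.5 ms step."""
        rod = PlanarTree(
            [BodySpec("rod", -1, "rz", (0, 0), 1.0, (0, -0.5), 1.0 / 12)],
            gravity=9.81,
        )
        q, qd = np.array([0.6]), np.zeros(1)
        e0 = rod.total_energy(q, qd)
        dt = 5e-4
        worst = 0.0
        for k in range(int(10 / dt)):
            q, qd = rod.step(q, qd, np.zeros(1), dt)
            if k % 100 == 0:
                worst = max(worst, abs(rod.total_energy(q, qd) - e0))
        assert worst / abs(e0) < 1e-3

    def test_pendulum_small_oscillation_frequency(self):
        """Period matches the analytic rigid-pendulum value to 0.5 %."""
        rod = PlanarTree(
            [BodySpec("rod", -1, "rz", (0, 0), 1.0, (0, -0.5), 1.0 / 12)],
            gravity=9.81,
        )
        # I_pivot = 1/3, omega^2 = m g l_c / I_pivot = 9.81*0.5*3
        omega = math.sqrt(9.81 * 0.5 * 3)
        q, qd = np.array([0.02]), np.zeros(1)
        dt = 5e-4
        crossings = []
        prev = q[0]
        for k in range(int(6 / dt)):
            q, qd = rod.step(q, qd, np.zeros(1), dt)
            if prev > 0 >= q[0]:
                crossings.append(k * dt)
            prev = q[0]
        period = np.mean(np.diff(crossings))
        assert period == pytest.approx(2 * math.pi / omega, rel=5e-3)

    def test_mass_matrix_symmetric_positive_definite(self, biped):
        q = np.zeros(9)
        q[1] = biped.standing_hip_height()
        M = biped.tree.mass_matrix(q)
        assert np.allclose(M, M.T, atol=1e-10)
        assert np.all(np.linalg.eigvalsh(M) > 0)


class TestContact:
    def test_point_above_ground_has_zero_wrench(self):
        assert point_contact_force(ContactParams(), 0.05, 1.0, -1.0) == (0.0, 0.0)

    def test_static_penetration_matches_stiffness_law(self):
        p = ContactParams()
        d = 0.004
        assert normal_force(p, d, 0.0) == pytest.approx(p.stiffness * d**p.exponent)

    def test_sliding_contact_saturates_at_mu_times_normal(self):
        p = ContactParams()
        fn = 500.0
        ft = friction_force(p, fn, 1.0)  # fast sliding
        assert abs(ft) == pytest.approx(p.mu * fn, rel=1e-9)
        assert ft < 0  # opposes the motion

    def test_no_adhesion_during_fast_retraction(self):
        p = ContactParams()
        assert normal_force(p, 0.002, -10.0) == 0.0


class TestBipedConstruction:
    def test_default_model_matches_reference_anthropometry(self, biped):
        assert biped.tree.total_mass == pytest.approx(74.5)
        assert biped.config.height == pytest.approx(1.80)
        assert biped.n_muscles == 18
        assert len(biped.tree.bodies) == 9  # 7 segments + 2 base joints
        assert len(biped.contact_points) == 4  # heel and toe per foot

    def test_segment_masses_must_sum_to_total(self):
        segs = default_segments(74.5, 1.80)
        segs["torso"] = SegmentSpec(40.0, 0.8, 0.35, 2.5)
        with pytest.raises(ConfigurationError, match="segment masses"):
            PlantConfig(segments=segs).validate()

    def test_biarticular_muscles_span_two_joints(self, biped):
        for name in ("RF", "HAM", "GAS"):
            assert len(biped.moment_arms[name]) == 2
        for name in ("GLU", "ILI", "BF", "VAS", "TA", "SOL"):
            assert len(biped.moment_arms[name]) == 1

    def test_standing_signals_are_normalized(self, biped):
        obs = biped.observe(biped.initial_state())
        assert np.allclose(obs.L, 1.0, atol=1e-9)  # CE at optimal length
        assert np.all(obs.F >= 0)


class TestBipedDynamics:
    def test_step_is_deterministic(self, biped):
        u = np.linspace(0, 1, 18)

        def run():
            s = biped.initial_state()
            out = []
            for _ in range(200):
                s, obs = biped.step(s, u)
                out.append(obs.com_x)
            return np.array(out)

        assert np.array_equal(run(), run())

    def test_left_right_mirror_symmetry(self, biped):
        """Mirroring state and controls mirrors the trajectory (tolerance
        covers floating-point summation-order noise only)."""

        def rollout(state, mirror):
            rows = []
            for k in range(100):
                u = np.clip(0.3 + 0.3 * np.sin(0.01 * k + np.arange(18) * 0.5), 0, 1)
                if mirror:
                    u = biped.mirror_controls(u)
                state, obs = biped.step(state, u)
                rows.append((obs.com_x, obs.com_y) + obs.joint_angles)
            return np.array(rows)

        s0 = biped.initial_state({"hip_L": 0.2, "knee_R": 0.1})
        a = rollout(s0, mirror=False)
        b = rollout(biped.mirror_state(s0), mirror=True)
        mirrored = b.copy()
        mirrored[:, 2:5], mirrored[:, 5:8] = b[:, 5:8].copy(), b[:, 2:5].copy()
        assert np.abs(a - mirrored).max() < 1e-6

    def test_unactuated_model_falls(self, biped):
        cfg = EpisodeConfig(t_max=10.0, transient=1.0)
        p0 = ParameterVector.zeros(biped.connection_matrix)
        result = run_episode(biped, p0, cfg)
        assert not result.stable
        assert result.t_sim < 10.0

    def test_contact_wrench_zero_in_flight(self, biped):
        state = biped.initial_state({"torso_y": biped.standing_hip_height() + 0.3})
        assert np.all(biped.contact_wrench(state) == 0.0)
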