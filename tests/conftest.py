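import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from reflexgait.controller import standard_connection_matrix
from reflexgait.episode import EpisodeResult, run_episode
from reflexgait.toybench import make_toy_plant, toy_episode_config

settings.register_profile(
    "unit",
    deadline=None,
    max_examples=25,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("unit")


@pytest.fixture(scope="session")
def std_matrix():
    return standard_connection_matrix()


@pytest.fixture(scope="session")
def toy():
    """Toy hopper plant plus its committed baseline parameters."""
    return make_toy_plant()


@pytest.fixture(scope="session")
def toy_cfg():
    return toy_episode_config()


@pytest.fixture(scope="session")
def baseline_episode(toy, toy_cfg):
    """One cached stable baseline hop episode (10 s)."""
    plant, p0 = toy
    return run_episode(plant, p0, toy_cfg)


def make_result(
    t_max: float,
    t_sim: float,
    seg_x_initial,
    seg_x_final,
    gait: str = "none",
) -> EpisodeResult:
    """Fabricate an episode outcome for metric-level tests."""
    stable = t_sim == t_max
    seg0 = np.atleast_1d(np.asarray(seg_x_initial, dtype=float))
    seg1 = np.atleast_1d(np.asarray(seg_x_final, dtype=float))
    d = float(seg1[0] - seg0[0])
    return EpisodeResult(
        t_max=t_max,
        t_sim=t_sim,
        stable=stable,
        d_sim=d,
        v_mean=d / t_sim if t_sim else 0.0,
        v_act=d / t_sim if stable and t_sim else None,
        gait=gait,
        seg_x_initial=seg0,
        seg_x_final=seg1,
        trajectories={
            "t": np.array([0.0, t_sim]),
            "com_x": np.array([seg0[0], seg1[0]]),
            "com_y": np.array([1.0, 1.0]),
            "torso_x": np.array([seg0[0], seg1[0]]),
            "torso_vx": np.zeros(2),
            "contact_fy": np.zeros((2, 1)),
            "joint_angles": np.zeros((2, 0)),
        },
    )
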