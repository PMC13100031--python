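"""Run one simulation episode and compute gait metrics.

An episode advances plant + reflex controller at a fixed step until either
``t_max`` is reached (a *stable* episode) or the model center of mass drops
below the fall threshold.  The same loop serves offline episodes, online
runs with scheduled parameter switches, and gait-transition experiments: the
active parameter vector can be replaced at prescribed wall-clock times while
all dynamic state (joint state, activations, sensor buffers) carries over.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .controller import ParameterVector, ReflexController
from .plant.rigid import IntegrationError

MINIMIZE = "minimize_v"
MAXIMIZE = "maximize_v"
_DIRECTIONS = (MINIMIZE, MAXIMIZE)


@dataclass(frozen=True)
class EpisodeConfig:
    """Episode termination rules and measurement settings."""

    t_max: float = 50.0  # s
    fall_height: float = 0.9  # m, on the model CoM
    transient: float = 10.0  # s discarded before measuring v_act
    record_dt: float = 0.005  # s, trajectory sampling interval
    contact_threshold: float = 20.0  # N, vertical force marking stance
    initial_overrides: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if self.t_max <= 0:
            raise ValueError("t_max must be positive")
        if self.fall_height <= 0:
            raise ValueError("fall_height must be positive")
        if not 0 <= self.transient < self.t_max:
            raise ValueError("transient must lie in [0, t_max)")


@dataclass
class EpisodeResult:
    """Outcome of one simulation episode."""

    t_max: float
    t_sim: float
    stable: bool
    d_sim: float  # horizontal CoM displacement (reporting convenience)
    v_mean: float
    v_act: float | None  # defined only for stable episodes
    gait: str  # "walk" | "run" | "none"
    seg_x_initial: np.ndarray
    seg_x_final: np.ndarray
    trajectories: dict[str, np.ndarray]
    switch_times: tuple[float, ...] = ()
    diagnostic: str | None = None

    def __post_init__(self) -> None:
        assert 0.0 <= self.t_sim <= self.t_max + 1e-12
        assert self.stable == (self.t_sim == self.t_max)


def run_episode(
    plant,
    params: ParameterVector,
    cfg: EpisodeConfig | None = None,
    switches: Sequence[tuple[float, ParameterVector]] = (),
) -> EpisodeResult:
    """Simulate until fall or ``t_max``; deterministic for fixed inputs.

    ``switches`` is a sorted list of (time, parameters): at each time the
    controller's parameter vector is replaced instantly, nothing else resets.
    """
    cfg = cfg or EpisodeConfig()
    dt = plant.dt
    n_steps = int(round(cfg.t_max / dt))
    rec = max(1, int(round(cfg.record_dt / dt)))

    ctrl = ReflexController(
        plant.connection_matrix, plant.legs, plant.sensor_delays, dt
    )
    ctrl.set_params(params)
    state = plant.initial_state(cfg.initial_overrides)
    obs = plant.observe(state)
    ctrl.reset(obs.L, obs.F)

    sw = sorted(switches, key=lambda it: it[0])
    for t_s, _ in sw:
        if t_s < 0:
            raise ValueError("switch times must be non-negative")
    sw_idx = 0
    applied: list[float] = []

    rec_t = [0.0]
    rec_com_x = [obs.com_x]
    rec_com_y = [obs.com_y]
    rec_vx = [obs.torso_vx]
    rec_torso_x = [obs.torso_x]
    rec_contact = [obs.contact_fy]
    rec_joints = [obs.joint_angles]
    seg_x0 = np.asarray(obs.seg_x, dtype=float)

    fall_t: float | None = None
    diagnostic: str | None = None
    last_k = 0
    for k in range(n_steps):
        t = k * dt
        while sw_idx < len(sw) and t >= sw[sw_idx][0] - 1e-12:
            ctrl.set_params(sw[sw_idx][1])
            applied.append(t)
            sw_idx += 1
        u = ctrl.step(obs.L, obs.F)
        try:
            state, obs = plant.step(state, u, dt)
        except IntegrationError as err:
            fall_t = t
            diagnostic = f"integration failure at t={t:.4f}s: {err}"
            break
        last_k = k + 1
        if last_k % rec == 0:
            rec_t.append(last_k * dt)
            rec_com_x.append(obs.com_x)
            rec_com_y.append(obs.com_y)
            rec_vx.append(obs.torso_vx)
            rec_torso_x.append(obs.torso_x)
            rec_contact.append(obs.contact_fy)
            rec_joints.append(obs.joint_angles)
        if obs.com_y < cfg.fall_height:
            fall_t = last_k * dt
            break

    stable = fall_t is None
    t_sim = cfg.t_max if stable else float(fall_t)
    if last_k % rec != 0:  # always keep the terminal sample
        rec_t.append(last_k * dt)
        rec_com_x.append(obs.com_x)
        rec_com_y.append(obs.com_y)
        rec_vx.append(obs.torso_vx)
        rec_torso_x.append(obs.torso_x)
        rec_contact.append(obs.contact_fy)
        rec_joints.append(obs.joint_angles)

    traj = {
        "t": np.asarray(rec_t),
        "com_x": np.asarray(rec_com_x),
        "com_y": np.asarray(rec_com_y),
        "torso_x": np.asarray(rec_torso_x),
        "torso_vx": np.asarray(rec_vx),
        "contact_fy": np.asarray(rec_contact, dtype=float),
        "joint_angles": np.asarray(rec_joints, dtype=float),
    }
    seg_xf = np.asarray(obs.seg_x, dtype=float)
    d_sim = float(traj["com_x"][-1] - traj["com_x"][0])
    v_mean = d_sim / t_sim if t_sim > 0 else 0.0

    v_act = None
    if stable:
        i0 = int(np.searchsorted(traj["t"], cfg.transient))
        span = traj["t"][-1] - traj["t"][i0]
        if span > 0:
            v_act = float((traj["com_x"][-1] - traj["com_x"][i0]) / span)

    contact_bool = traj["contact_fy"] > cfg.contact_threshold
    gait = classify_gait(contact_bool)

    return EpisodeResult(
        t_max=cfg.t_max,
        t_sim=t_sim,
        stable=stable,
        d_sim=d_sim,
        v_mean=v_mean,
        v_act=v_act,
        gait=gait,
        seg_x_initial=seg_x0,
        seg_x_final=seg_xf,
        trajectories=traj,
        switch_times=tuple(applied),
        diagnostic=diagnostic,
    )


# ----------------------------------------------------------------------
# gait metrics
# ----------------------------------------------------------------------
def completed_distance(segment_x, direction: str) -> float:
    """Completed distance d_sim from per-segment horizontal CoM trajectories.

    ``segment_x`` is an (n_t, n_segments) array (or a (initial, final) pair
    of vectors).  For speed maximization the segment with the *minimal*
    final distance to the origin is selected (the trailing segment, a
    conservative measure); for minimization the *maximal*.  Returns that
    segment's horizontal displacement.
    """
    if direction not in _DIRECTIONS:
        raise ValueError(f"direction must be one of {_DIRECTIONS}")
    if isinstance(segment_x, tuple) and len(segment_x) == 2:
        initial, final = (np.asarray(a, dtype=float) for a in segment_x)
    else:
        arr = np.asarray(segment_x, dtype=float)
        if arr.ndim != 2 or arr.shape[0] == 0:
            raise ValueError("segment trajectory must be a non-empty 2-D array")
        initial, final = arr[0], arr[-1]
    if initial.size == 0:
        raise ValueError("no segments")
    dist = np.abs(final)
    idx = int(np.argmin(dist) if direction == MAXIMIZE else np.argmax(dist))
    return float(final[idx] - initial[idx])


def episode_distance(result: EpisodeResult, direction: str) -> float:
    """d_sim of a finished episode under the given objective direction."""
    return completed_distance((result.seg_x_initial, result.seg_x_final), direction)


def moving_average_velocity(
    velocity: np.ndarray, dt: float, window: float = 1.0
) -> np.ndarray:
    """Causal trailing mean over ``window`` seconds (growing startup window)."""
    v = np.asarray(velocity, dtype=float)
    if v.ndim != 1:
        raise ValueError("velocity series must be 1-D")
    duration = (len(v) - 1) * dt
    if duration < window:
        raise ValueError(f"series duration {duration}s shorter than window {window}s")
    w = int(round(window / dt))
    out = np.empty_like(v)
    for k in range(min(w - 1, len(v))):
        out[k] = np.mean(v[: k + 1])
    if len(v) >= w:
        sw = np.lib.stride_tricks.sliding_window_view(v, w)
        out[w - 1 :] = sw.mean(axis=-1)
    return out


def _contact_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """[start, end) index runs where ``mask`` is True."""
    if mask.size == 0:
        return []
    d = np.diff(mask.astype(int))
    starts = list(np.nonzero(d == 1)[0] + 1)
    ends = list(np.nonzero(d == -1)[0] + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(len(mask))
    return list(zip(starts, ends))


def classify_gait(contact: np.ndarray, min_strides: int = 4) -> str:
    """Classify a per-foot boolean contact trace as walk, run or none.

    Running shows periodic flight phases (no foot in contact); walking keeps
    at least one foot down with alternating single and double support.
    Fewer than ``min_strides`` complete strides of the first foot yield
    ``"none"``.
    """
    contact = np.asarray(contact, dtype=bool)
    if contact.ndim == 1:
        contact = contact[:, None]
    if contact.shape[0] < 2:
        return "none"
    foot0 = contact[:, 0]
    onsets = np.nonzero(foot0[1:] & ~foot0[:-1])[0] + 1
    if len(onsets) - 1 < min_strides:
        return "none"
    interior = slice(onsets[0], onsets[-1])
    any_foot = contact[interior].any(axis=1)
    flights = _contact_runs(~any_foot)
    if len(flights) >= 2:
        return "run"
    if any_foot.all():
        support = contact[interior].sum(axis=1)
        if contact.shape[1] >= 2 and (support == 1).any() and (support == 2).any():
            return "walk"
    return "none"


@dataclass(frozen=True)
class StrideEvents:
    heel_strikes: np.ndarray  # s
    toe_offs: np.ndarray  # s
    stance_fraction: float


def stride_events(
    f_vertical: np.ndarray,
    dt: float,
    threshold_on: float = 20.0,
    threshold_off: float | None = None,
) -> StrideEvents:
    """Heel strikes / toe-offs from a thresholded vertical contact force.

    Hysteresis: contact begins above ``threshold_on`` and ends below
    ``threshold_off`` (default half of on), the standard gait-event setup.
    """
    f = np.asarray(f_vertical, dtype=float)
    off = threshold_on / 2 if threshold_off is None else threshold_off
    in_contact = False
    hs: list[int] = []
    to: list[int] = []
    mask = np.empty(len(f), dtype=bool)
    for k, val in enumerate(f):
        if not in_contact and val > threshold_on:
            in_contact = True
            hs.append(k)
        elif in_contact and val < off:
            in_contact = False
            to.append(k)
        mask[k] = in_contact
    if len(hs) < 2:
        raise ValueError("no complete gait cycles detected")
    stance = float(mask[hs[0] : hs[-1]].sum()) / max(hs[-1] - hs[0], 1)
    return StrideEvents(
        heel_strikes=np.asarray(hs, dtype=float) * dt,
        toe_offs=np.asarray(to, dtype=float) * dt,
        stance_fraction=stance,
    )


def gait_cycle_angles(
    angles: np.ndarray,
    heel_strike_indices: Sequence[int],
    n_phase: int = 101,
) -> np.ndarray:
    """Per-cycle joint-angle curves resampled to a 0-100 % phase grid.

    Returns an array of shape (n_cycles, n_phase, n_joints).
    """
    angles = np.atleast_2d(np.asarray(angles, dtype=float))
    if angles.shape[0] == 1:
        angles = angles.T
    idx = list(heel_strike_indices)
    if len(idx) < 2:
        raise ValueError("need at least two heel strikes for one cycle")
    phase = np.linspace(0.0, 1.0, n_phase)
    cycles = []
    for a, b in zip(idx[:-1], idx[1:]):
        if b - a < 2:
            raise ValueError("degenerate gait cycle")
        src = np.linspace(0.0, 1.0, b - a + 1)
        cyc = np.stack(
            [np.interp(phase, src, angles[a : b + 1, j]) for j in range(angles.shape[1])],
            axis=-1,
        )
        cycles.append(cyc)
    return np.stack(cycles)


def rms_vs_reference(sim_curves: np.ndarray, ref_curves: np.ndarray) -> np.ndarray:
    """Per-joint RMS deviation over the gait cycle (same units as input)."""
    sim = np.atleast_2d(np.asarray(sim_curves, dtype=float))
    ref = np.atleast_2d(np.asarray(ref_curves, dtype=float))
    if sim.shape != ref.shape:
        raise ValueError("curve shapes differ")
    return np.sqrt(np.mean((sim - ref) ** 2, axis=0))
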