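"""Online speed modulation and walk-run transition experiments.

A schedule prescribes the target speed over time: after a settle period at
the midpoint of the stable range, either an abrupt step of j * 0.025 m/s or
a triangle-wave ramp that cycles between the range bounds at 0.05 m/s per
second.  During the run, the speed-modulation function re-assembles the full
parameter vector at one-second update instants; the replacement is
instantaneous and preserves all dynamic state.  Transition experiments swap
whole hand-picked parameter sets at fixed 10 s intervals and re-optimize the
concatenated sets for survival.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import cma
from .controller import ParameterVector
from .episode import EpisodeConfig, EpisodeResult, classify_gait, run_episode
from .smf import SMFModel, assemble
from .speed_opt import CmaConfig

STEP_QUANTUM = 0.025  # m/s, target-speed step granularity
RAMP_RATE = 0.05  # m/s per second
SETTLE_TIME = 20.0  # s at the start speed before modulation begins


@dataclass(frozen=True)
class Schedule:
    """Time-varying target speed: constant, step, or triangle ramp.

    The start speed sits mid-range, v_start = v_min + (v_max - v_min) / 2.
    Steps jump to v_start + direction * j * 0.025 m/s at the settle time;
    ramps cycle between v_min and v_max with period
    T = 2 (v_max - v_min) / v_a, rising first.
    """

    kind: str  # "constant" | "step" | "ramp"
    v_min: float
    v_max: float
    j: int = 0  # step index in [1, 25]
    direction: int = 1  # +1 accelerate, -1 decelerate (step only)
    v_a: float = RAMP_RATE
    settle: float = SETTLE_TIME
    quantum: float = STEP_QUANTUM

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "step", "ramp"):
            raise ValueError(f"unknown schedule kind {self.kind!r}")
        if self.v_max < self.v_min:
            raise ValueError("v_max must be >= v_min")
        if self.kind == "step":
            if not 1 <= self.j <= 25:
                raise ValueError("step index j must be in [1, 25]")
            if self.direction not in (-1, 1):
                raise ValueError("direction must be +1 or -1")
        if self.v_a <= 0 or self.settle < 0:
            raise ValueError("invalid rate or settle time")

    @property
    def v_start(self) -> float:
        return self.v_min + (self.v_max - self.v_min) / 2.0

    @property
    def v_end(self) -> float:
        if self.kind != "step":
            return self.v_start
        return self.v_start + self.direction * self.j * self.quantum

    @property
    def period(self) -> float:
        """Triangle-wave period T = 2 (v_max - v_min) / v_a."""
        return 2.0 * (self.v_max - self.v_min) / self.v_a


def schedule_value(s: Schedule, t: float) -> float:
    """Analytic target speed at time ``t`` (settle period included)."""
    if t < s.settle or s.kind == "constant":
        return s.v_start
    if s.kind == "step":
        return s.v_end
    # triangle wave, time-shifted so it starts at v_start and rises first
    tau = t - s.settle
    T = s.period
    if T == 0.0:
        return s.v_start
    return s.v_min + s.v_a * abs(((tau - T / 4.0) % T) - T / 2.0)


def schedule_switches(
    s: Schedule, model: SMFModel, t_max: float, update_dt: float = 1.0
) -> list[tuple[float, ParameterVector]]:
    """Parameter switch events realizing the schedule via the SMF.

    The target is sampled-and-held on the update lattice starting at the
    settle time, so a ramp is realized as v_a * update_dt increments.  A
    constant schedule yields no events.
    """
    if s.kind == "constant":
        return []
    events: list[tuple[float, ParameterVector]] = []
    v_prev = s.v_start
    t = s.settle
    while t < t_max:
        v = schedule_value(s, t)
        if v != v_prev:
            events.append((t, assemble(model, v)))
            v_prev = v
        if s.kind == "step":
            break
        t += update_dt
    return events


@dataclass
class OnlineResult:
    """Episode outcome plus the commanded target-speed trace."""

    episode: EpisodeResult
    schedule: Schedule
    v_tgt: np.ndarray  # commanded target at the recorded sample times

    @property
    def stable(self) -> bool:
        return self.episode.stable


def run_online(
    plant,
    model: SMFModel,
    schedule: Schedule,
    episode_cfg: EpisodeConfig | None = None,
    update_dt: float = 1.0,
) -> OnlineResult:
    """Run an episode while the SMF tracks the schedule at run time.

    With a constant schedule this is the same computation as an offline
    episode at the start speed (no switch events are generated)."""
    episode_cfg = episode_cfg or EpisodeConfig()
    p_start = assemble(model, schedule.v_start)
    switches = schedule_switches(schedule, model, episode_cfg.t_max, update_dt)
    episode = run_episode(plant, p_start, episode_cfg, switches=switches)
    t = episode.trajectories["t"]
    held = np.empty_like(t)
    for i, ti in enumerate(t):  # sample-and-hold on the update lattice
        if ti < schedule.settle or schedule.kind == "constant":
            held[i] = schedule.v_start
        elif schedule.kind == "step":
            held[i] = schedule.v_end
        else:
            tk = schedule.settle + math.floor((ti - schedule.settle) / update_dt) * update_dt
            held[i] = schedule_value(schedule, tk)
    return OnlineResult(episode=episode, schedule=schedule, v_tgt=held)


def largest_stable_step(
    plant,
    model: SMFModel,
    direction: int,
    v_bounds: tuple[float, float],
    episode_cfg: EpisodeConfig | None = None,
    j_max: int = 25,
    early_stop: bool = True,
) -> tuple[int, float]:
    """Largest step index j whose online run survives to t_max.

    Scans j = 1..j_max in the given direction; returns (j*, dv) with
    dv = j* * 0.025, or (0, 0.0) when no step is stable.
    """
    v_min, v_max = v_bounds
    j_star = 0
    for j in range(1, j_max + 1):
        s = Schedule(kind="step", v_min=v_min, v_max=v_max, j=j, direction=direction)
        res = run_online(plant, model, s, episode_cfg)
        if res.stable:
            j_star = j
        elif early_stop:
            break
    return j_star, j_star * STEP_QUANTUM


# ----------------------------------------------------------------------
# gait transitions
# ----------------------------------------------------------------------
@dataclass
class TransitionPlan:
    """Ordered parameter sets switched abruptly at fixed times.

    With the default 10 s interval, a 2-set plan switches once at 10 s and a
    4-set plan at 10/20/30 s (walk-run-run-walk)."""

    param_sets: list[ParameterVector]
    interval: float = 10.0
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(self.param_sets) < 2:
            raise ValueError("a transition plan needs at least 2 parameter sets")
        if self.interval <= 0:
            raise ValueError("switch interval must be positive")
        if self.labels and len(self.labels) != len(self.param_sets):
            raise ValueError("one label per parameter set required")

    @property
    def switch_times(self) -> tuple[float, ...]:
        return tuple(self.interval * (k + 1) for k in range(len(self.param_sets) - 1))

    @property
    def dimension(self) -> int:
        """Search dimension of the joint re-optimization."""
        return sum(p.size for p in self.param_sets)

    def encode(self) -> np.ndarray:
        return np.concatenate([p.encode() for p in self.param_sets])

    def with_encoded(self, x: np.ndarray) -> "TransitionPlan":
        x = np.asarray(x, dtype=float)
        if x.shape != (self.dimension,):
            raise ValueError(f"expected a {self.dimension}-vector")
        sets = []
        at = 0
        for p in self.param_sets:
            sets.append(ParameterVector.decode(p.matrix, x[at : at + p.size]))
            at += p.size
        return TransitionPlan(sets, self.interval, self.labels)


@dataclass
class TransitionResult:
    episode: EpisodeResult
    plan: TransitionPlan
    segment_gaits: tuple[str, ...]
    failed_segment: int | None  # index of the segment in which the fall occurred


def run_transition(
    plant,
    plan: TransitionPlan,
    episode_cfg: EpisodeConfig | None = None,
) -> TransitionResult:
    """Episode with abrupt whole-vector switches at the plan's times."""
    episode_cfg = episode_cfg or EpisodeConfig()
    switches = [
        (t, p) for t, p in zip(plan.switch_times, plan.param_sets[1:])
    ]
    episode = run_episode(plant, plan.param_sets[0], episode_cfg, switches=switches)

    bounds = (0.0,) + plan.switch_times + (episode_cfg.t_max,)
    t = episode.trajectories["t"]
    contact = episode.trajectories["contact_fy"] > episode_cfg.contact_threshold
    gaits = []
    failed = None
    for k in range(len(plan.param_sets)):
        m = (t >= bounds[k]) & (t <= bounds[k + 1])
        gaits.append(classify_gait(contact[m]) if m.any() else "none")
        if not episode.stable and failed is None and episode.t_sim <= bounds[k + 1]:
            failed = k
    return TransitionResult(
        episode=episode,
        plan=plan,
        segment_gaits=tuple(gaits),
        failed_segment=failed,
    )


def optimize_transition(
    plant,
    plan: TransitionPlan,
    cfg: CmaConfig | None = None,
    episode_cfg: EpisodeConfig | None = None,
    seed: int = 0,
) -> tuple[TransitionPlan, cma.CmaResult]:
    """Re-optimize all sets jointly so the transition episode survives.

    The objective is the fall penalty alone, J = 100 * (1 - t_sim / t_max):
    zero exactly when the model completes the episode.  Terminates early
    once a surviving plan is found."""
    cfg = cfg or CmaConfig()
    episode_cfg = episode_cfg or EpisodeConfig()

    def objective(x: np.ndarray) -> float:
        res = run_transition(plant, plan.with_encoded(x), episode_cfg)
        return 100.0 * (1.0 - res.episode.t_sim / res.episode.t_max)

    result = cma.minimize(
        objective,
        plan.encode(),
        cfg.sigma0,
        seed=seed,
        popsize=cfg.popsize,
        max_generations=cfg.max_generations,
        improve_tol=cfg.improve_tol,
        improve_window=cfg.improve_window,
        f_target=0.0,
    )
    return plan.with_encoded(result.x_best), result
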