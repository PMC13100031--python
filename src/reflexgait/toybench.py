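"""Desk-scale fixtures: a muscle-driven hopper and synthetic speed datasets.

The toy plant is a point-mass body on one massless telescoping leg actuated
by an extensor/flexor MTU pair through the *same* Hill-muscle and reflex
machinery as the full biped.  Stable hopping is obtainable with a tiny
optimization budget, so the whole speed-modulation pipeline (optimize ->
harvest -> PCA -> restricted optimize -> regression -> sweep -> online) runs
end-to-end in minutes.

Vertical and horizontal dynamics are deliberately decoupled: the leg
telescopes vertically (leg length = body height during stance, smooth force
engagement at the rest length), while the stance force acts along a
touchdown tilt set by the extensor activation when the leg lands ("extensor
tone pushes the leg backward").  Propulsion from the tilt is balanced by
linear drag, so forward speed increases smoothly and monotonically with the
extensor homonymous force gain over roughly [0.4, 1.9] around the committed
baseline.

Synthetic parameter-vs-speed datasets with known polynomial ground truth
support exact recovery tests of the PCA key selection and the
speed-modulation regression.  The toy is a test fixture for the machinery;
it does not emulate human gait.
"""

from __future__ import annotations

import importlib.resources as resources
import math
import time
from collections import namedtuple
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .controller import (
    ConnectionMatrix,
    ParameterVector,
    build_connection_matrix,
    parameter_names,
)
from .episode import MAXIMIZE, MINIMIZE, EpisodeConfig, run_episode
from .key_params import fit_pca, restricted_problem, select_keys
from .muscles import (
    MTUParams,
    MTUState,
    mtu_init,
    mtu_relax,
    mtu_step,
    normalize_signals,
    tendon_force,
)
from .online import Schedule, run_online
from .smf import fit_smf, monotonicity_report, offline_sweep, online_target_bounds
from .speed_opt import CmaConfig, SpeedDataset, build_omega, optimize

TOY_MUSCLES = ("EXT", "FLX")


def toy_connection_matrix() -> ConnectionMatrix:
    """2 homonymous + 2 antagonistic connections, 10 free parameters."""
    return build_connection_matrix(
        {"EXT": ("FLX",), "FLX": ("EXT",)}, muscles=TOY_MUSCLES, expected_total=4
    )


@dataclass(frozen=True)
class ToyPlantConfig:
    """Point-mass hopper on a telescoping muscle-driven leg.

    The leg compresses vertically during stance; the stance force is tilted
    backward by the touchdown angle, which grows with the extensor
    activation at landing (``swing_angle0 + tilt_gain * act``, capped at
    ``swing_max``).  Since the force-feedback gain raises the extensor
    activation carried into flight (the extensor deactivates slowly), a
    larger extensor force gain lands with a more inclined leg, pushes
    forward harder against the linear drag, and therefore hops faster."""

    mass: float = 80.0  # kg
    leg_length: float = 1.0  # m, natural leg length
    gravity: float = 9.81
    drag: float = 90.0  # N s/m, linear drag on the body
    dt: float = 1.0e-3  # s
    rho_ext: float = 0.5  # extensor path shortening per m of leg extension
    rho_flx: float = 0.5
    swing_angle0: float = 0.05  # rad, touchdown leg angle at zero extensor tone
    tilt_gain: float = 0.60  # rad of touchdown angle per unit extensor activation
    swing_max: float = 0.65  # rad, maximum touchdown angle
    extensor: MTUParams = field(
        default_factory=lambda: MTUParams(
            "EXT", f_max=22000.0, l_opt=0.10, l_slack=0.40, tau_deact=0.15
        )
    )
    flexor: MTUParams = field(
        default_factory=lambda: MTUParams("FLX", f_max=2000.0, l_opt=0.10, l_slack=0.40)
    )
    delay: float = 0.020  # s, sensor delay of both muscles
    fall_height: float = 0.9  # m

    def __post_init__(self) -> None:
        if not 0 < self.swing_max < math.pi / 2 or self.swing_angle0 <= 0:
            raise ValueError("swing angles must lie in (0, pi/2)")
        for f in ("mass", "leg_length", "gravity", "dt", "rho_ext", "rho_flx",
                  "tilt_gain"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be positive")

    def touchdown_angle(self, extensor_activation: float) -> float:
        return min(self.swing_angle0 + self.tilt_gain * extensor_activation,
                   self.swing_max)


HopperObs = namedtuple(
    "HopperObs",
    "L F com_x com_y torso_x torso_vx seg_x contact_fy joint_angles",
)


@dataclass
class HopperState:
    x: float
    y: float
    vx: float
    vy: float
    stance: bool
    foot_x: float
    mtu: list[MTUState]
    t: float = 0.0
    flight_time: float = 0.0
    td_armed: bool = True  # touchdown allowed once the flight passed apex


class HopperPlant:
    """One-legged hopper sharing muscle and controller machinery."""

    segment_names = ("body",)

    def __init__(self, config: ToyPlantConfig | None = None) -> None:
        self.config = config or ToyPlantConfig()
        self.dt = self.config.dt
        self.mtu_params = [self.config.extensor, self.config.flexor]
        self.muscle_names = list(TOY_MUSCLES)
        self.legs = [[0, 1]]
        self.group_names = TOY_MUSCLES
        self.connection_matrix = toy_connection_matrix()
        self.sensor_delays = np.array([self.config.delay, self.config.delay])

    @property
    def n_muscles(self) -> int:
        return 2

    @property
    def n_feet(self) -> int:
        return 1

    def _paths(self, leg_len: float) -> tuple[float, float]:
        c = self.config
        compression = c.leg_length - leg_len
        return (
            c.extensor.l_ref + c.rho_ext * compression,
            c.flexor.l_ref - c.rho_flx * compression,
        )

    def initial_state(self, overrides: Mapping[str, float] | None = None) -> HopperState:
        """Flight, slightly above leg length, descending into the first hop."""
        ov = dict(overrides or {})
        c = self.config
        y = ov.pop("y", c.leg_length + 0.05)
        vx = ov.pop("vx", 0.1)
        vy = ov.pop("vy", 0.0)
        if ov:
            raise ValueError(f"unknown initial-state fields: {sorted(ov)}")
        le, lf = self._paths(c.leg_length)
        mtu = [mtu_init(c.extensor, le), mtu_init(c.flexor, lf)]
        return HopperState(
            x=0.0, y=y, vx=vx, vy=vy, stance=False, foot_x=0.0, mtu=mtu,
            flight_time=0.25,
        )

    def _stance_signals(self, mtu: Sequence[MTUState], leg_len: float):
        paths = self._paths(leg_len)
        L = np.empty(2)
        F = np.empty(2)
        for i, (p, st) in enumerate(zip(self.mtu_params, mtu)):
            f = tendon_force(p, paths[i] - st.l_ce)
            L[i], F[i] = normalize_signals(p, st, f)
        return L, F

    def _flight_signals(self, mtu: Sequence[MTUState]):
        # unloaded swing leg: the tendon carries no force
        L = np.array([st.l_ce / p.l_opt for p, st in zip(self.mtu_params, mtu)])
        return L, np.zeros(2)

    def _leg_length(self, state: HopperState) -> float:
        if not state.stance:
            return self.config.leg_length
        return min(state.y, self.config.leg_length)

    def signals(self, state: HopperState):
        if state.stance:
            return self._stance_signals(state.mtu, self._leg_length(state))
        return self._flight_signals(state.mtu)

    def observe(self, state: HopperState) -> HopperObs:
        L, F = self.signals(state)
        fy = 0.0
        if state.stance:
            l = self._leg_length(state)
            tilt = state.foot_x
            fy = max(self._leg_force(state.mtu, l), 0.0) * math.sqrt(1 - tilt * tilt)
        return HopperObs(
            L=L,
            F=F,
            com_x=state.x,
            com_y=state.y,
            torso_x=state.x,
            torso_vx=state.vx,
            seg_x=(state.x,),
            contact_fy=(fy,),
            joint_angles=(),
        )

    def _leg_force(self, mtu: Sequence[MTUState], leg_len: float) -> float:
        c = self.config
        le, lf = self._paths(leg_len)
        f_ext = tendon_force(c.extensor, le - mtu[0].l_ce)
        f_flx = tendon_force(c.flexor, lf - mtu[1].l_ce)
        return c.rho_ext * f_ext - c.rho_flx * f_flx

    def step(
        self, state: HopperState, stimulation: np.ndarray, dt: float | None = None
    ) -> tuple[HopperState, HopperObs]:
        dt = self.dt if dt is None else dt
        c = self.config
        x, y, vx, vy = state.x, state.y, state.vx, state.vy
        stance = state.stance
        tf = state.flight_time
        tilt = state.foot_x  # during stance: sin of the touchdown leg angle

        fy = 0.0
        if stance:
            leg_len = min(y, c.leg_length)
            paths = self._paths(leg_len)
            st_e, f_ext = mtu_step(
                state.mtu[0], float(stimulation[0]), paths[0], dt, c.extensor
            )
            st_f, f_flx = mtu_step(
                state.mtu[1], float(stimulation[1]), paths[1], dt, c.flexor
            )
            mtu = [st_e, st_f]
            f_leg = max(c.rho_ext * f_ext - c.rho_flx * f_flx, 0.0)
            cos_t = math.sqrt(1.0 - tilt * tilt)
            ax = (f_leg * tilt - c.drag * vx) / c.mass
            ay = (f_leg * cos_t - c.drag * vy) / c.mass - c.gravity
            fy = f_leg * cos_t
        else:
            # flight: the unloaded leg swings forward, muscles relax
            st_e, _ = mtu_relax(state.mtu[0], float(stimulation[0]), dt, c.extensor)
            st_f, _ = mtu_relax(state.mtu[1], float(stimulation[1]), dt, c.flexor)
            mtu = [st_e, st_f]
            ax = -c.drag * vx / c.mass
            ay = -c.drag * vy / c.mass - c.gravity

        vx += ax * dt
        vy += ay * dt
        x += vx * dt
        y += vy * dt

        if stance:
            if y >= c.leg_length:
                stance = False  # leg reaches rest length: takeoff
                tf = 0.0
                fy = 0.0
        else:
            tf += dt
            if vy < 0.0 and y <= c.leg_length:
                stance = True  # smooth engagement: zero force at contact
                tilt = math.sin(c.touchdown_angle(st_e.act))

        new_state = HopperState(
            x=x, y=y, vx=vx, vy=vy, stance=stance, foot_x=tilt, mtu=mtu,
            t=state.t + dt, flight_time=tf,
        )
        if stance:
            L, F = self._stance_signals(mtu, min(y, c.leg_length))
        else:
            L, F = self._flight_signals(mtu)
        obs = HopperObs(
            L=L,
            F=F,
            com_x=x,
            com_y=y,
            torso_x=x,
            torso_vx=vx,
            seg_x=(x,),
            contact_fy=(fy,),
            joint_angles=(),
        )
        return new_state, obs


def toy_episode_config(
    t_max: float = 10.0, transient: float = 3.0, **kw
) -> EpisodeConfig:
    """Episode settings matched to the hopper (lower CoM, shorter episodes)."""
    return EpisodeConfig(
        t_max=t_max, fall_height=0.9, transient=transient, record_dt=0.005, **kw
    )


def load_toy_baseline(matrix: ConnectionMatrix | None = None) -> ParameterVector:
    """Committed baseline reflex parameters producing sustained hopping."""
    matrix = matrix or toy_connection_matrix()
    with resources.files("reflexgait.data").joinpath("toy_baseline.csv").open() as fh:
        df = pd.read_csv(fh)
    vec = df[parameter_names(matrix)].iloc[0].to_numpy(float)
    return ParameterVector.decode(matrix, vec)


def make_toy_plant(
    config: ToyPlantConfig | None = None,
) -> tuple[HopperPlant, ParameterVector]:
    """The hopper plant plus its committed stable baseline parameters."""
    plant = HopperPlant(config)
    return plant, load_toy_baseline(plant.connection_matrix)


# ----------------------------------------------------------------------
# synthetic parameter-vs-speed datasets
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class SyntheticDatasetSpec:
    """Ground-truth description of a synthetic speed dataset.

    True-key columns follow their cubic-coefficient polynomials in speed
    (ascending powers) plus Gaussian noise; all other columns are constant
    plus noise.  ``noise_sd`` is a scalar for all columns or one value per
    column."""

    n_params: int = 71
    n_v: int = 200
    true_keys: tuple[int, ...] = ()
    coeffs: np.ndarray | None = None  # (n_true, 4)
    noise_sd: float | np.ndarray = 0.0
    speed_range: tuple[float, float] = (0.7, 1.6)
    seed: int = 0
    base_value: float = 0.5

    def validate(self) -> None:
        if self.n_params < 1 or self.n_v < 5:
            raise ValueError("need n_params >= 1 and n_v >= 5 (degree + 2)")
        if len(set(self.true_keys)) != len(self.true_keys):
            raise ValueError("true keys must be unique")
        if any(not 0 <= k < self.n_params for k in self.true_keys):
            raise ValueError("true key index out of range")
        if self.true_keys:
            c = np.asarray(self.coeffs, dtype=float)
            if c.shape != (len(self.true_keys), 4):
                raise ValueError("coeffs must have shape (n_true_keys, 4)")
        if self.speed_range[1] <= self.speed_range[0]:
            raise ValueError("speed_range must be increasing")


def gen_param_speed_dataset(spec: SyntheticDatasetSpec) -> SpeedDataset:
    """Seeded synthetic dataset with known polynomial structure."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.speed_range
    v = np.sort(rng.uniform(lo, hi, spec.n_v))
    P = np.full((spec.n_v, spec.n_params), spec.base_value, dtype=float)
    if spec.true_keys:
        coeffs = np.asarray(spec.coeffs, dtype=float)
        V = np.vander(v, 4, increasing=True)  # [1, v, v^2, v^3]
        for row, idx in enumerate(spec.true_keys):
            P[:, idx] = V @ coeffs[row]
    sd = np.broadcast_to(np.asarray(spec.noise_sd, dtype=float), (spec.n_params,))
    if np.any(sd > 0):
        P = P + rng.normal(0.0, 1.0, P.shape) * sd
    prov = [{"direction": "synthetic", "seed": spec.seed, "generation": i}
            for i in range(spec.n_v)]
    ds = SpeedDataset(P, v, prov)
    return ds


def key_recovery_experiment(
    n_replicates: int = 100,
    n_true: int = 5,
    n_params: int = 71,
    noise_ratio: float = 0.1,
    seed: int = 0,
) -> float:
    """Fraction of replicates in which PCA selection recovers the true keys.

    Each replicate draws random true keys and random cubic speed trends;
    per-column noise is ``noise_ratio`` times the trend's standard
    deviation over the speed range (non-key columns use the mean key
    signal).  Selection asks for exactly ``n_true`` keys.
    """
    successes = 0
    for r in range(n_replicates):
        rng = np.random.default_rng(seed * 100003 + r)
        keys = tuple(sorted(rng.choice(n_params, size=n_true, replace=False)))
        coeffs = rng.normal(0.0, 1.0, (n_true, 4))
        lo, hi = 0.7, 1.6
        vg = np.linspace(lo, hi, 200)
        V = np.vander(vg, 4, increasing=True)
        signal_sd = (V @ coeffs.T).std(axis=0)
        sd = np.full(n_params, noise_ratio * signal_sd.mean())
        sd[list(keys)] = noise_ratio * signal_sd
        spec = SyntheticDatasetSpec(
            n_params=n_params,
            n_v=200,
            true_keys=keys,
            coeffs=coeffs,
            noise_sd=sd,
            speed_range=(lo, hi),
            seed=seed * 100003 + r,
        )
        ds = gen_param_speed_dataset(spec)
        sel = select_keys(fit_pca(ds), n_true)
        if set(sel.indices) == set(keys):
            successes += 1
    return successes / n_replicates


# ----------------------------------------------------------------------
# end-to-end desk-scale pipeline
# ----------------------------------------------------------------------
class SmokeError(RuntimeError):
    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class SmokeReport:
    omega1_size: int
    omega1_speed_range: float
    n_keys: int
    key_indices: tuple[int, ...]
    omega2_size: int
    omega2_speed_range: float
    sweep_points: int
    sweep_stable: int
    sweep_stable_range: tuple[float, float] | None
    mod_speed_range: float
    monotonicity_violations: int
    violation_fraction: float
    step_stable: bool
    ramp_stable: bool
    wall_time_s: float


def pipeline_smoke(
    seed: int = 0,
    config: ToyPlantConfig | None = None,
    n_seeds: int = 2,
    max_generations: int = 12,
    popsize: int = 6,
    n_key: int = 4,
    degree: int = 2,
) -> SmokeReport:
    """Run the full speed-modulation pipeline on the toy hopper.

    Optimize (both directions, reduced budget) -> harvest -> merge ->
    PCA key selection -> restricted optimize -> polynomial regression ->
    offline sweep -> online step and ramp, asserting each stage's
    invariants.  Raises :class:`SmokeError` naming the failing stage.
    """
    t0 = time.perf_counter()
    plant, p0 = make_toy_plant(config)
    ecfg = toy_episode_config()
    cma_cfg = CmaConfig(
        sigma0=0.05,
        n_seeds=n_seeds,
        improve_window=max(30, max_generations),
        max_generations=max_generations,
        popsize=popsize,
    )

    base = run_episode(plant, p0, ecfg)
    if not base.stable:
        raise SmokeError("baseline", "committed baseline fell")

    histories = {MINIMIZE: [], MAXIMIZE: []}
    for d_idx, direction in enumerate((MINIMIZE, MAXIMIZE)):
        for s in range(n_seeds):
            histories[direction].append(
                optimize(
                    plant, p0, direction, cma_cfg, ecfg,
                    seed=(seed * 1009 + d_idx * 101 + s) % (2**31 - 1),
                )
            )

    omega1 = build_omega(plant, histories[MINIMIZE], histories[MAXIMIZE], ecfg)
    if len(omega1) < 5:
        raise SmokeError("omega1", f"only {len(omega1)} stable records")
    if np.any(np.diff(omega1.v_act) < 0):
        raise SmokeError("omega1", "dataset not sorted by speed")

    pca = fit_pca(omega1)
    if not np.allclose(pca.loadings @ pca.loadings.T,
                       np.eye(pca.loadings.shape[0]), atol=1e-8):
        raise SmokeError("pca", "loadings not orthonormal")
    keys = select_keys(pca, n_key, plant.connection_matrix)

    rp = restricted_problem(p0, keys)
    histories2 = {MINIMIZE: [], MAXIMIZE: []}
    for d_idx, direction in enumerate((MINIMIZE, MAXIMIZE)):
        histories2[direction].append(
            optimize(
                plant, p0, direction, cma_cfg, ecfg,
                seed=(seed * 1013 + 7 * d_idx) % (2**31 - 1),
                keys=keys.indices,
            )
        )
        for rec in histories2[direction][-1].records:
            frozen = np.delete(rec.x, list(keys.indices))
            ref = np.delete(p0.encode(), list(keys.indices))
            if not np.array_equal(frozen, ref):
                raise SmokeError("restricted", "non-key parameter moved")
    omega2 = build_omega(plant, histories2[MINIMIZE], histories2[MAXIMIZE], ecfg)
    if len(omega2) <= degree + 1:
        raise SmokeError("omega2", f"only {len(omega2)} stable records")

    model = fit_smf(omega2, keys, degree, p0)
    lo = float(omega2.v_act.min())
    hi = float(omega2.v_act.max())
    if hi - lo < 0.1:
        lo, hi = lo - 0.05, hi + 0.05
    grid = np.arange(lo, hi + 1e-9, 0.025)
    sweep = offline_sweep(plant, model, grid, ecfg)
    n_stable = int(sweep.stable.sum())
    if n_stable == 0:
        raise SmokeError("sweep", "no stable target speed")

    mono = monotonicity_report(sweep)
    frac = mono.n_violations / len(grid)
    if frac > 0.10:
        raise SmokeError("monotonicity", f"{mono.n_violations} violations "
                                         f"on {len(grid)} grid points")

    v_lo, v_hi = online_target_bounds(sweep)
    if v_hi < v_lo:
        v_lo, v_hi = v_hi, v_lo
    online_cfg = toy_episode_config(
        t_max=float(min(45.0, 20.0 + max(5.0, Schedule(
            kind="ramp", v_min=v_lo, v_max=max(v_hi, v_lo + 1e-3)).period))),
        transient=3.0,
    )
    step_sched = Schedule(kind="step", v_min=v_lo, v_max=max(v_hi, v_lo + 0.05), j=1)
    step_res = run_online(plant, model, step_sched, online_cfg)
    ramp_sched = Schedule(kind="ramp", v_min=v_lo, v_max=max(v_hi, v_lo + 0.05))
    ramp_res = run_online(plant, model, ramp_sched, online_cfg)

    return SmokeReport(
        omega1_size=len(omega1),
        omega1_speed_range=omega1.speed_range(),
        n_keys=keys.n_key,
        key_indices=keys.indices,
        omega2_size=len(omega2),
        omega2_speed_range=omega2.speed_range(),
        sweep_points=len(grid),
        sweep_stable=n_stable,
        sweep_stable_range=sweep.stable_target_range(),
        mod_speed_range=sweep.actual_speed_range(),
        monotonicity_violations=mono.n_violations,
        violation_fraction=frac,
        step_stable=step_res.stable,
        ramp_stable=ramp_res.stable,
        wall_time_s=time.perf_counter() - t0,
    )
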