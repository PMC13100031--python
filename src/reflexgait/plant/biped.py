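"""Planar seven-segment humanoid driven by 18 Hill-type MTUs.

Torso plus femur, tibia and foot per leg, connected by hinge hips, knees and
ankles, with viscoelastic heel/toe ground contact.  The default
parameterization represents an adult male of 74.5 kg and 1.80 m using
standard anthropometric segment fractions; every constant can be overridden
through :class:`PlantConfig`.

Coordinate conventions: x forward, y up; all angles in radians internally.
Joint angles are zero in the standing configuration with flexion positive
(ankle: dorsiflexion positive).  Muscle paths use constant moment arms per
spanned joint, so the MTU path length is affine in the joint angles.
"""

from __future__ import annotations

from collections import namedtuple
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from ..controller import MUSCLES, ConnectionMatrix, standard_connection_matrix
from ..muscles import MTUParams, MTUState, mtu_init, mtu_step, normalize_signals
from .contact import ContactParams, ContactPoint, point_contact_force
from .rigid import BodySpec, PlanarTree


class ConfigurationError(ValueError):
    """A plant configuration field violates an invariant."""


@dataclass(frozen=True)
class SegmentSpec:
    """Inertial properties of one segment (per side for leg segments)."""

    mass: float  # kg
    length: float  # m
    com_offset: float  # m, CoM distance from the proximal joint
    inertia: float  # kg m^2, about the CoM

    def __post_init__(self) -> None:
        for f in ("mass", "length", "inertia"):
            if getattr(self, f) <= 0:
                raise ConfigurationError(f"segment {f} must be positive")


def _rod(mass: float, length: float, com_offset: float | None = None) -> SegmentSpec:
    off = length / 2 if com_offset is None else com_offset
    return SegmentSpec(mass, length, off, mass * length**2 / 12.0)


# standard anthropometric mass fractions (head+arms+trunk lumped into torso)
_FRACTIONS = {"femur": 0.10625, "tibia": 0.04375, "foot": 0.015625}


def default_segments(total_mass: float, height: float) -> dict[str, SegmentSpec]:
    """Segment table scaled from a 74.5 kg / 1.80 m reference."""
    s = height / 1.80
    m_femur = _FRACTIONS["femur"] * total_mass
    m_tibia = _FRACTIONS["tibia"] * total_mass
    m_foot = _FRACTIONS["foot"] * total_mass
    m_torso = total_mass - 2.0 * (m_femur + m_tibia + m_foot)
    return {
        "torso": _rod(m_torso, 0.80 * s, com_offset=0.35 * s),
        "femur": _rod(m_femur, 0.46 * s, com_offset=0.20 * s),
        "tibia": _rod(m_tibia, 0.46 * s, com_offset=0.20 * s),
        "foot": SegmentSpec(m_foot, 0.20 * s, 0.06 * s, m_foot * (0.20 * s) ** 2 / 12),
    }


def default_mtu_table() -> dict[str, MTUParams]:
    """Muscle constants of the nine modeled muscles (one leg)."""
    tbl = {
        #        f_max  l_opt  l_slack
        "GLU": (1500.0, 0.11, 0.13),
        "ILI": (1500.0, 0.11, 0.10),
        "RF": (1200.0, 0.08, 0.35),
        "HAM": (3000.0, 0.10, 0.31),
        "BF": (800.0, 0.11, 0.10),
        "VAS": (6000.0, 0.08, 0.23),
        "GAS": (1500.0, 0.05, 0.40),
        "TA": (800.0, 0.06, 0.24),
        "SOL": (4000.0, 0.04, 0.26),
    }
    return {n: MTUParams(n, *v) for n, v in tbl.items()}


#: Constant moment arms (m) per spanned joint, flexion/dorsiflexion positive.
#: Biarticular muscles (RF, HAM, GAS) span exactly two joints.
DEFAULT_MOMENT_ARMS: dict[str, dict[str, float]] = {
    "GLU": {"hip": -0.062},
    "ILI": {"hip": 0.062},
    "RF": {"hip": 0.042, "knee": -0.042},
    "HAM": {"hip": -0.055, "knee": 0.035},
    "BF": {"knee": 0.035},
    "VAS": {"knee": -0.042},
    "GAS": {"knee": 0.020, "ankle": -0.053},
    "TA": {"ankle": 0.040},
    "SOL": {"ankle": -0.053},
}

#: Reflex conduction delays by neural path length (s): hip-proximal 5 ms,
#: thigh 10 ms, shank 20 ms.
DEFAULT_DELAYS: dict[str, float] = {
    "GLU": 0.005,
    "ILI": 0.005,
    "RF": 0.010,
    "HAM": 0.010,
    "BF": 0.010,
    "VAS": 0.010,
    "GAS": 0.020,
    "TA": 0.020,
    "SOL": 0.020,
}

_JOINTS = ("hip", "knee", "ankle")
#: engine rotation = sign * conventional angle (knee flexion is clockwise)
_JOINT_SIGNS = {"hip": 1.0, "knee": -1.0, "ankle": 1.0}


@dataclass(frozen=True)
class PlantConfig:
    """Anthropometrics, muscle constants and simulation constants."""

    total_mass: float = 74.5  # kg
    height: float = 1.80  # m
    gravity: float = 9.81  # m/s^2
    dt: float = 5.0e-4  # s, integrator timestep
    segments: Mapping[str, SegmentSpec] | None = None
    mtus: Mapping[str, MTUParams] | None = None
    moment_arms: Mapping[str, Mapping[str, float]] | None = None
    delays: Mapping[str, float] | None = None
    contact: ContactParams = field(default_factory=ContactParams)

    def resolved_segments(self) -> dict[str, SegmentSpec]:
        return dict(self.segments) if self.segments is not None else default_segments(
            self.total_mass, self.height
        )

    def validate(self) -> None:
        if self.total_mass <= 0:
            raise ConfigurationError("total_mass must be positive")
        if self.height <= 0:
            raise ConfigurationError("height must be positive")
        if self.dt <= 0:
            raise ConfigurationError("dt must be positive")
        segs = self.resolved_segments()
        for name in ("torso", "femur", "tibia", "foot"):
            if name not in segs:
                raise ConfigurationError(f"missing segment spec: {name}")
        total = segs["torso"].mass + 2.0 * (
            segs["femur"].mass + segs["tibia"].mass + segs["foot"].mass
        )
        if abs(total - self.total_mass) > 1e-9:
            raise ConfigurationError(
                f"segment masses sum to {total!r}, expected total_mass {self.total_mass!r}"
            )


BipedObs = namedtuple(
    "BipedObs",
    "L F com_x com_y torso_x torso_vx seg_x contact_fy joint_angles",
)


@dataclass
class BipedState:
    q: np.ndarray  # 9 generalized coordinates (x, y, pitch, 6 engine joints)
    qd: np.ndarray
    mtu: list[MTUState]  # 18, left leg then right leg in canonical order
    t: float = 0.0


class BipedPlant:
    """Seven segments, six hinge joints, 18 MTUs, heel/toe contact."""

    segment_names = (
        "torso",
        "femur_L",
        "tibia_L",
        "foot_L",
        "femur_R",
        "tibia_R",
        "foot_R",
    )

    def __init__(self, config: PlantConfig) -> None:
        config.validate()
        self.config = config
        self.dt = config.dt
        segs = config.resolved_segments()
        self.mtu_params_by_name = (
            dict(config.mtus) if config.mtus is not None else default_mtu_table()
        )
        self.moment_arms = (
            {m: dict(v) for m, v in config.moment_arms.items()}
            if config.moment_arms is not None
            else {m: dict(v) for m, v in DEFAULT_MOMENT_ARMS.items()}
        )
        delays = dict(config.delays) if config.delays is not None else dict(DEFAULT_DELAYS)
        for m in MUSCLES:
            if m not in self.mtu_params_by_name:
                raise ConfigurationError(f"missing MTU parameters for {m}")
            ma = self.moment_arms.get(m, {})
            n_joints = len(ma)
            expected = 2 if m in ("RF", "HAM", "GAS") else 1
            if n_joints != expected:
                raise ConfigurationError(
                    f"muscle {m} must span {expected} joint(s), spans {n_joints}"
                )

        t, f, s, ft = segs["torso"], segs["femur"], segs["tibia"], segs["foot"]
        self._leg_len = f.length + s.length
        self._ankle_h = 0.4 * ft.length  # ankle height above the sole
        bodies = [
            BodySpec("base_x", -1, "px", (0.0, 0.0), 0.0, (0.0, 0.0), 0.0),
            BodySpec("base_y", 0, "py", (0.0, 0.0), 0.0, (0.0, 0.0), 0.0),
            BodySpec("torso", 1, "rz", (0.0, 0.0), t.mass, (0.0, t.com_offset), t.inertia),
        ]
        for side in ("L", "R"):
            femur = BodySpec(
                f"femur_{side}", 2, "rz", (0.0, 0.0), f.mass, (0.0, -f.com_offset), f.inertia
            )
            tibia = BodySpec(
                f"tibia_{side}",
                len(bodies),
                "rz",
                (0.0, -f.length),
                s.mass,
                (0.0, -s.com_offset),
                s.inertia,
            )
            foot = BodySpec(
                f"foot_{side}",
                len(bodies) + 1,
                "rz",
                (0.0, -s.length),
                ft.mass,
                (ft.com_offset, -0.5 * self._ankle_h),
                ft.inertia,
            )
            bodies += [femur, tibia, foot]
        self.tree = PlanarTree(bodies, gravity=config.gravity)
        self._segment_bodies = (2, 3, 4, 5, 6, 7, 8)
        # heel and toe spheres per foot (local sole level below the ankle)
        heel_x, toe_x = -0.25 * ft.length, 0.75 * ft.length
        self.contact_points = [
            ContactPoint(5, (heel_x, -self._ankle_h), "heel_L"),
            ContactPoint(5, (toe_x, -self._ankle_h), "toe_L"),
            ContactPoint(8, (heel_x, -self._ankle_h), "heel_R"),
            ContactPoint(8, (toe_x, -self._ankle_h), "toe_R"),
        ]

        # muscle bookkeeping: left leg 0..8, right leg 9..17, canonical order
        self.muscle_names = [f"{m}_L" for m in MUSCLES] + [f"{m}_R" for m in MUSCLES]
        self.mtu_params = [self.mtu_params_by_name[m] for m in MUSCLES] * 2
        self.legs = [list(range(9)), list(range(9, 18))]
        self.group_names = MUSCLES
        self.connection_matrix: ConnectionMatrix = standard_connection_matrix()
        self.sensor_delays = np.array([delays[m] for m in MUSCLES] * 2)
        # per-muscle (joint index within leg, moment arm) lists
        self._arms: list[list[tuple[int, float]]] = []
        for m in MUSCLES:
            self._arms.append(
                [(_JOINTS.index(j), r) for j, r in self.moment_arms[m].items()]
            )

    # ------------------------------------------------------------------
    @property
    def n_muscles(self) -> int:
        return 18

    @property
    def n_feet(self) -> int:
        return 2

    def standing_hip_height(self) -> float:
        return self._leg_len + self._ankle_h

    def joint_angles(self, q: np.ndarray) -> np.ndarray:
        """Six conventional joint angles (hip, knee, ankle) x (L, R)."""
        signs = np.array([_JOINT_SIGNS[j] for j in _JOINTS] * 2)
        return signs * np.asarray(q)[3:9]

    def _mtu_lengths(self, angles_conv: np.ndarray) -> np.ndarray:
        """Path length of all 18 muscles; affine in the joint angles."""
        out = np.empty(18)
        for leg in range(2):
            base = 3 * leg
            for k, p in enumerate(self.mtu_params[:9]):
                l = p.l_ref
                for j, r in self._arms[k]:
                    l -= r * angles_conv[base + j]
                out[9 * leg + k] = l
        return out

    def initial_state(self, overrides: Mapping[str, float] | None = None) -> BipedState:
        """Standing pose with a forward push; override fields as needed.

        Recognized overrides: torso_x, torso_y, pitch, vx, vy, pitch_rate,
        and per-joint conventional angles/velocities ``<joint>_<side>`` /
        ``<joint>_<side>_vel`` (e.g. ``knee_L``).
        """
        ov = dict(overrides or {})
        q = np.zeros(9)
        qd = np.zeros(9)
        q[0] = ov.pop("torso_x", 0.0)
        q[1] = ov.pop("torso_y", self.standing_hip_height())
        q[2] = ov.pop("pitch", 0.0)
        qd[0] = ov.pop("vx", 1.2)
        qd[1] = ov.pop("vy", 0.0)
        qd[2] = ov.pop("pitch_rate", 0.0)
        for i, (j, side) in enumerate(
            (j, s) for s in ("L", "R") for j in _JOINTS
        ):
            sign = _JOINT_SIGNS[j]
            q[3 + i] = sign * ov.pop(f"{j}_{side}", 0.0)
            qd[3 + i] = sign * ov.pop(f"{j}_{side}_vel", 0.0)
        if ov:
            raise ConfigurationError(f"unknown initial-state fields: {sorted(ov)}")
        angles = self.joint_angles(q)
        lengths = self._mtu_lengths(angles)
        mtu = [mtu_init(p, l) for p, l in zip(self.mtu_params, lengths)]
        return BipedState(q=q, qd=qd, mtu=mtu, t=0.0)

    def signals(self, state: BipedState) -> tuple[np.ndarray, np.ndarray]:
        """Normalized (L~, F~) of all muscles at the current state."""
        from ..muscles import tendon_force

        angles = self.joint_angles(state.q)
        lengths = self._mtu_lengths(angles)
        L = np.empty(18)
        F = np.empty(18)
        for i, (p, st) in enumerate(zip(self.mtu_params, state.mtu)):
            f = tendon_force(p, lengths[i] - st.l_ce)
            L[i], F[i] = normalize_signals(p, st, f)
        return L, F

    def contact_wrench(self, state: BipedState) -> np.ndarray:
        """Per-foot (fx, fy) contact force, shape (2, 2), left then right."""
        out = np.zeros((2, 2))
        for cp in self.contact_points:
            x, y, vx, vy = self.tree.point_state(state.q, state.qd, cp.body, cp.local)
            fx, fy = point_contact_force(self.config.contact, y, vx, vy)
            foot = 0 if cp.body == 5 else 1
            out[foot, 0] += fx
            out[foot, 1] += fy
        return out

    def step(
        self, state: BipedState, stimulation: np.ndarray, dt: float | None = None
    ) -> tuple[BipedState, BipedObs]:
        """Advance muscles, contacts and linkage dynamics by one step."""
        dt = self.dt if dt is None else dt
        q, qd = state.q, state.qd
        angles = self.joint_angles(q)
        lengths = self._mtu_lengths(angles)

        mtu_new: list[MTUState] = []
        forces = np.empty(18)
        for i, (p, st) in enumerate(zip(self.mtu_params, state.mtu)):
            st2, f = mtu_step(st, float(stimulation[i]), lengths[i], dt, p)
            mtu_new.append(st2)
            forces[i] = f

        # joint torques: conventional flexion-positive, then engine signs
        tau = np.zeros(9)
        for leg in range(2):
            for k in range(9):
                for j, r in self._arms[k]:
                    idx = 3 + 3 * leg + j
                    tau[idx] += _JOINT_SIGNS[_JOINTS[j]] * r * forces[9 * leg + k]

        ext: dict[int, list[tuple[float, float, float, float]]] = {}
        foot_fy = [0.0, 0.0]
        for cp in self.contact_points:
            x, y, vx, vy = self.tree.point_state(q, qd, cp.body, cp.local)
            fx, fy = point_contact_force(self.config.contact, y, vx, vy)
            if fx != 0.0 or fy != 0.0:
                ext.setdefault(cp.body, []).append((x, y, fx, fy))
            foot_fy[0 if cp.body == 5 else 1] += fy

        q2, qd2 = self.tree.step(q, qd, tau, dt, ext or None)
        state2 = BipedState(q=q2, qd=qd2, mtu=mtu_new, t=state.t + dt)

        coms = self.tree.body_coms(q2)
        m = np.array([b.mass for b in self.tree.bodies])
        com_x = float((coms[:, 0] * m).sum() / m.sum())
        com_y = float((coms[:, 1] * m).sum() / m.sum())
        L = np.empty(18)
        F = np.empty(18)
        angles2 = self.joint_angles(q2)
        lengths2 = self._mtu_lengths(angles2)
        from ..muscles import tendon_force

        for i, (p, st) in enumerate(zip(self.mtu_params, mtu_new)):
            f = tendon_force(p, lengths2[i] - st.l_ce)
            L[i], F[i] = normalize_signals(p, st, f)
        obs = BipedObs(
            L=L,
            F=F,
            com_x=com_x,
            com_y=com_y,
            torso_x=float(q2[0]),
            torso_vx=float(qd2[0]),
            seg_x=tuple(float(coms[b, 0]) for b in self._segment_bodies),
            contact_fy=(foot_fy[0], foot_fy[1]),
            joint_angles=tuple(float(a) for a in angles2),
        )
        return state2, obs

    def observe(self, state: BipedState) -> BipedObs:
        """Observation of the current state without advancing it."""
        coms = self.tree.body_coms(state.q)
        m = np.array([b.mass for b in self.tree.bodies])
        L, F = self.signals(state)
        wrench = self.contact_wrench(state)
        return BipedObs(
            L=L,
            F=F,
            com_x=float((coms[:, 0] * m).sum() / m.sum()),
            com_y=float((coms[:, 1] * m).sum() / m.sum()),
            torso_x=float(state.q[0]),
            torso_vx=float(state.qd[0]),
            seg_x=tuple(float(coms[b, 0]) for b in self._segment_bodies),
            contact_fy=(float(wrench[0, 1]), float(wrench[1, 1])),
            joint_angles=tuple(float(a) for a in self.joint_angles(state.q)),
        )

    # ------------------------------------------------------------------
    def mirror_state(self, state: BipedState) -> BipedState:
        """Swap left and right legs (sagittal model: mirrored trajectory)."""
        q = state.q.copy()
        qd = state.qd.copy()
        q[3:6], q[6:9] = state.q[6:9].copy(), state.q[3:6].copy()
        qd[3:6], qd[6:9] = state.qd[6:9].copy(), state.qd[3:6].copy()
        mtu = state.mtu[9:] + state.mtu[:9]
        return BipedState(q=q, qd=qd, mtu=list(mtu), t=state.t)

    @staticmethod
    def mirror_controls(stimulation: np.ndarray) -> np.ndarray:
        return np.concatenate([stimulation[9:], stimulation[:9]])


def build_standard_human(config: PlantConfig | None = None) -> BipedPlant:
    """Build the planar seven-segment model (default: 74.5 kg, 1.80 m)."""
    return BipedPlant(config or PlantConfig())
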