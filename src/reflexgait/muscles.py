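"""Hill-type musculotendon unit (MTU).

A contractile element (CE) with Gaussian force-length and hyperbolic
force-velocity characteristics in series with a quadratic-stiffness elastic
tendon, driven by first-order activation dynamics.  The CE velocity is
obtained per step by inverting the force-velocity relation so that CE and
tendon forces balance, the standard formulation for reflex-gait models.
All muscle constants live in :class:`MTUParams`; nothing is hard-coded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


@dataclass(frozen=True)
class MTUParams:
    """Constants of one musculotendon unit.

    ``v_max`` is expressed in optimal CE lengths per second; ``eps_ref`` is
    the tendon strain at which tendon force equals ``f_max``.
    """

    name: str
    f_max: float  # N, maximum isometric force
    l_opt: float  # m, optimal CE length
    l_slack: float  # m, tendon slack length
    v_max: float = 12.0  # l_opt/s
    tau_act: float = 0.010  # s
    tau_deact: float = 0.040  # s
    eps_ref: float = 0.04  # tendon reference strain
    fl_width: float = 0.56  # Gaussian force-length width
    fv_curv: float = 5.0  # Hill curvature (concentric)
    fv_ecc: float = 1.5  # eccentric force plateau
    fv_ecc_curv: float = 7.56  # eccentric curvature
    act_floor: float = 0.01  # numerical floor in the force balance

    def __post_init__(self) -> None:
        for f in ("f_max", "l_opt", "l_slack", "v_max", "tau_act", "tau_deact",
                  "eps_ref", "fl_width"):
            if getattr(self, f) <= 0:
                raise ValueError(f"MTU {self.name!r}: {f} must be positive")

    @property
    def l_ref(self) -> float:
        """MTU path length at which CE is optimal and tendon just taut."""
        return self.l_opt + self.l_slack


@dataclass(frozen=True)
class MTUState:
    act: float  # activation in [0, 1]
    l_ce: float  # m, contractile element length


def mtu_init(params: MTUParams, l_mtu: float) -> MTUState:
    """Initial state: tendon unstretched, CE takes up the remaining path."""
    l_ce = min(max(l_mtu - params.l_slack, 0.2 * params.l_opt), 2.0 * params.l_opt)
    return MTUState(act=0.0, l_ce=l_ce)


def tendon_force(params: MTUParams, l_tendon: float) -> float:
    """Series-elastic force; zero when slack (a tendon cannot push)."""
    eps = (l_tendon - params.l_slack) / params.l_slack
    if eps <= 0.0:
        return 0.0
    return params.f_max * (eps / params.eps_ref) ** 2


def force_length(params: MTUParams, l_ce: float) -> float:
    x = (l_ce / params.l_opt - 1.0) / params.fl_width
    return math.exp(-x * x)


def _invert_force_velocity(params: MTUParams, phi: float) -> float:
    """CE velocity (l_opt/s, lengthening positive) with force ratio ``phi``.

    Concentric branch: phi = (v_max - s) / (v_max + K s) for shortening
    speed s; eccentric branch saturates at ``fv_ecc``.
    """
    if phi < 1.0:
        s = params.v_max * (1.0 - phi) / (1.0 + params.fv_curv * phi)
        return -s
    phi = min(phi, params.fv_ecc - 1e-6)
    v = params.v_max * (phi - 1.0) / (params.fv_ecc_curv * (params.fv_ecc - phi))
    return min(v, params.v_max)  # bounded yielding rate near the plateau


def mtu_step(
    state: MTUState,
    stimulation: float,
    l_mtu: float,
    dt: float,
    params: MTUParams,
) -> tuple[MTUState, float]:
    """Advance one MTU by ``dt`` and return its tendon force (>= 0).

    Activation follows first-order dynamics toward the stimulation with
    asymmetric time constants; the CE state is advanced by the velocity that
    balances tendon and CE force.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if not (math.isfinite(stimulation) and math.isfinite(l_mtu)):
        raise FloatingPointError("non-finite MTU input")

    u = min(max(stimulation, 0.0), 1.0)
    tau = params.tau_act if u > state.act else params.tau_deact
    act = state.act + dt * (u - state.act) / tau
    act = min(max(act, 0.0), 1.0)

    f_se = tendon_force(params, l_mtu - state.l_ce)
    v_cap = params.v_max * params.l_opt * dt
    if f_se <= 0.0:
        # slack tendon: the CE follows the path toward the just-taut length
        # (rate-limited); force transmission resumes once the tendon is taut
        target = l_mtu - params.l_slack
        l_ce = state.l_ce + min(max(target - state.l_ce, -v_cap), v_cap)
    else:
        f_l = force_length(params, state.l_ce)
        denom = params.f_max * (act * f_l + params.act_floor)
        v_ce = _invert_force_velocity(params, f_se / denom)  # l_opt/s
        l_ce = state.l_ce + v_ce * params.l_opt * dt
    l_ce = min(max(l_ce, 0.2 * params.l_opt), 2.0 * params.l_opt)
    return MTUState(act=act, l_ce=l_ce), f_se


def mtu_relax(
    state: MTUState, stimulation: float, dt: float, params: MTUParams
) -> tuple[MTUState, float]:
    """Advance an *unloaded* MTU: activation dynamics continue, the CE
    relaxes toward its optimal length (rate-limited by ``v_max``) and the
    tendon carries no force.  Used for limbs swinging freely in flight."""
    u = min(max(stimulation, 0.0), 1.0)
    tau = params.tau_act if u > state.act else params.tau_deact
    act = min(max(state.act + dt * (u - state.act) / tau, 0.0), 1.0)
    v_cap = params.v_max * params.l_opt * dt
    l_ce = state.l_ce + min(max(params.l_opt - state.l_ce, -v_cap), v_cap)
    return MTUState(act=act, l_ce=l_ce), 0.0


def normalize_signals(
    params: MTUParams, state: MTUState, force: float
) -> tuple[float, float]:
    """Normalized proprioceptive signals (L~, F~) fed to the reflex network."""
    return state.l_ce / params.l_opt, max(force, 0.0) / params.f_max
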