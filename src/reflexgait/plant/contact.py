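"""Viscoelastic ground contact with regularized Coulomb friction.

Normal force follows a Hunt-Crossley-style law, smooth in penetration depth
and rate; tangential force is Coulomb friction regularized by a tanh of the
sliding speed, saturating at mu times the normal force.  The ground is the
half-plane y <= 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


@dataclass(frozen=True)
class ContactParams:
    stiffness: float = 8.0e5  # N / m^exponent
    exponent: float = 1.5  # penetration exponent of the stiffness law
    damping: float = 1.0  # s/m, Hunt-Crossley rate coefficient
    mu: float = 0.9  # Coulomb friction coefficient
    v_reg: float = 0.05  # m/s, sliding-speed regularization scale

    def __post_init__(self) -> None:
        if min(self.stiffness, self.exponent, self.mu, self.v_reg) <= 0:
            raise ValueError("contact parameters must be positive")
        if self.damping < 0:
            raise ValueError("contact damping must be >= 0")


@dataclass(frozen=True)
class ContactPoint:
    """A contact sphere center fixed to a body (radius folded into offset)."""

    body: int
    local: tuple[float, float]
    label: str = ""


def normal_force(p: ContactParams, depth: float, depth_rate: float) -> float:
    """Hunt-Crossley normal force, zero when not penetrating, never adhesive."""
    if depth <= 0.0:
        return 0.0
    f = p.stiffness * depth**p.exponent * (1.0 + p.damping * depth_rate)
    return max(f, 0.0)


def friction_force(p: ContactParams, fn: float, v_tangential: float) -> float:
    """Regularized Coulomb friction; |f_t| <= mu * fn, opposing sliding."""
    if fn <= 0.0:
        return 0.0
    return -p.mu * fn * math.tanh(v_tangential / p.v_reg)


def point_contact_force(
    p: ContactParams, y: float, vx: float, vy: float
) -> tuple[float, float]:
    """World-frame (fx, fy) on a point at height ``y`` with velocity (vx, vy)."""
    fn = normal_force(p, -y, -vy)
    if fn == 0.0:
        return 0.0, 0.0
    return friction_force(p, fn, vx), fn
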