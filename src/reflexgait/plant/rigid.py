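"""Planar rigid-body tree dynamics.

A minimal recursive Newton-Euler engine for planar kinematic trees with
revolute (``rz``) and prismatic (``px``/``py``) joints.  The floating base is
modeled as a px-py-rz joint chain of massless links.  Forward dynamics uses
the unit-acceleration trick: the joint-space mass matrix is assembled column
by column from inverse-dynamics calls, then ``M qdd = tau - bias`` is solved
directly.  Everything is deterministic pure float arithmetic.

Scalar (non-numpy) inner loops are used deliberately: the trees are small
(<= 9 bodies) and per-body scalar math is several times faster than small
ndarray operations in this regime.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

_JOINT_TYPES = ("rz", "px", "py")


class IntegrationError(RuntimeError):
    """The state became non-finite during integration."""


@dataclass(frozen=True)
class BodySpec:
    """One rigid body attached to its parent by a single-dof joint.

    ``anchor`` is the joint position in the parent frame (ignored rotation
    for prismatic joints); ``com`` and ``inertia`` (about the CoM) are in the
    body frame whose origin sits at the joint.
    """

    name: str
    parent: int  # index of parent body, -1 for ground
    joint: str  # "rz" | "px" | "py"
    anchor: tuple[float, float]
    mass: float
    com: tuple[float, float]
    inertia: float

    def __post_init__(self) -> None:
        if self.joint not in _JOINT_TYPES:
            raise ValueError(f"unknown joint type {self.joint!r}")
        if self.mass < 0 or self.inertia < 0:
            raise ValueError(f"body {self.name!r}: mass/inertia must be >= 0")


class PlanarTree:
    """Planar articulated tree with one generalized coordinate per body."""

    def __init__(self, bodies: Sequence[BodySpec], gravity: float = 9.81) -> None:
        self.bodies = list(bodies)
        self.n = len(self.bodies)
        self.gravity = float(gravity)
        for i, b in enumerate(self.bodies):
            if b.parent >= i:
                raise ValueError("bodies must be topologically ordered")
        self._children: list[list[int]] = [[] for _ in range(self.n)]
        for i, b in enumerate(self.bodies):
            if b.parent >= 0:
                self._children[b.parent].append(i)

    # ------------------------------------------------------------------
    # kinematics
    # ------------------------------------------------------------------
    def _forward(self, q, qd, qdd, gravity_on: bool):
        """Propagate positions, velocities and accelerations root-to-leaf.

        Returns per-body tuples; gravity is folded into the linear
        acceleration (d'Alembert) when ``gravity_on``.
        """
        n = self.n
        th = [0.0] * n
        px = [0.0] * n
        py = [0.0] * n
        w = [0.0] * n
        vx = [0.0] * n
        vy = [0.0] * n
        al = [0.0] * n
        ax = [0.0] * n
        ay = [0.0] * n
        ax0 = 0.0
        ay0 = self.gravity if gravity_on else 0.0  # base accelerates "up"

        for i, b in enumerate(self.bodies):
            p = b.parent
            if p < 0:
                thp = 0.0
                pxp = pyp = 0.0
                wp = 0.0
                vxp = vyp = 0.0
                alp = 0.0
                axp, ayp = ax0, ay0
            else:
                thp, pxp, pyp = th[p], px[p], py[p]
                wp, vxp, vyp = w[p], vx[p], vy[p]
                alp, axp, ayp = al[p], ax[p], ay[p]

            c, s = math.cos(thp), math.sin(thp)
            arx, ary = b.anchor
            rx = c * arx - s * ary
            ry = s * arx + c * ary
            # anchor point kinematics
            Ax, Ay = pxp + rx, pyp + ry
            vAx = vxp - wp * ry
            vAy = vyp + wp * rx
            aAx = axp - alp * ry - wp * wp * rx
            aAy = ayp + alp * rx - wp * wp * ry

            if b.joint == "rz":
                th[i] = thp + q[i]
                px[i], py[i] = Ax, Ay
                w[i] = wp + qd[i]
                vx[i], vy[i] = vAx, vAy
                al[i] = alp + qdd[i]
                ax[i], ay[i] = aAx, aAy
            else:
                if b.joint == "px":
                    ux, uy = c, s
                else:  # py
                    ux, uy = -s, c
                dx, dy = ux * q[i], uy * q[i]
                th[i] = thp
                px[i], py[i] = Ax + dx, Ay + dy
                w[i] = wp
                vrx, vry = ux * qd[i], uy * qd[i]
                vx[i] = vAx - wp * dy + vrx
                vy[i] = vAy + wp * dx + vry
                al[i] = alp
                ax[i] = aAx - alp * dy - wp * wp * dx - 2.0 * wp * vry + ux * qdd[i]
                ay[i] = aAy + alp * dx - wp * wp * dy + 2.0 * wp * vrx + uy * qdd[i]
        return th, px, py, w, vx, vy, al, ax, ay

    def fk(self, q) -> list[tuple[float, float, float]]:
        """Per-body (theta, x, y) of the body frame origin."""
        z = [0.0] * self.n
        th, px, py, *_ = self._forward(q, z, z, gravity_on=False)
        return list(zip(th, px, py))

    def point_state(
        self, q, qd, body: int, local: tuple[float, float]
    ) -> tuple[float, float, float, float]:
        """World position and velocity of a body-fixed point."""
        z = [0.0] * self.n
        th, px, py, w, vx, vy, *_ = self._forward(q, qd, z, gravity_on=False)
        c, s = math.cos(th[body]), math.sin(th[body])
        rx = c * local[0] - s * local[1]
        ry = s * local[0] + c * local[1]
        return (
            px[body] + rx,
            py[body] + ry,
            vx[body] - w[body] * ry,
            vy[body] + w[body] * rx,
        )

    # ------------------------------------------------------------------
    # dynamics
    # ------------------------------------------------------------------
    def inverse_dynamics(
        self,
        q,
        qd,
        qdd,
        gravity_on: bool = True,
        ext_forces: dict[int, list[tuple[float, float, float, float]]] | None = None,
    ) -> np.ndarray:
        """Generalized forces realizing ``qdd`` at state (q, qd).

        ``ext_forces`` maps body index to world-frame point forces
        ``(Px, Py, Fx, Fy)``; they enter with a minus sign, so the returned
        tau satisfies ``M qdd + bias = tau + J^T F_ext``.
        """
        th, px, py, w, vx, vy, al, ax, ay = self._forward(q, qd, qdd, gravity_on)
        n = self.n
        fx = [0.0] * n
        fy = [0.0] * n
        nz = [0.0] * n  # moment about own joint anchor (= body origin area)
        tau = np.zeros(n)

        for i in range(n - 1, -1, -1):
            b = self.bodies[i]
            c, s = math.cos(th[i]), math.sin(th[i])
            rcx = c * b.com[0] - s * b.com[1]
            rcy = s * b.com[0] + c * b.com[1]
            # com acceleration (gravity already folded into base accel)
            aCx = ax[i] - al[i] * rcy - w[i] * w[i] * rcx
            aCy = ay[i] + al[i] * rcx - w[i] * w[i] * rcy
            Fx = b.mass * aCx
            Fy = b.mass * aCy
            Nz = b.inertia * al[i]

            fxi = Fx
            fyi = Fy
            nzi = Nz + rcx * Fy - rcy * Fx
            if ext_forces and i in ext_forces:
                for (Px, Py, Fex, Fey) in ext_forces[i]:
                    fxi -= Fex
                    fyi -= Fey
                    nzi -= (Px - px[i]) * Fey - (Py - py[i]) * Fex
            for ch in self._children[i]:
                fxi += fx[ch]
                fyi += fy[ch]
                nzi += nz[ch] + (px[ch] - px[i]) * fy[ch] - (py[ch] - py[i]) * fx[ch]
            fx[i], fy[i], nz[i] = fxi, fyi, nzi

            if b.joint == "rz":
                tau[i] = nzi
            else:
                p = b.parent
                thp = th[p] if p >= 0 else 0.0
                cp, sp = math.cos(thp), math.sin(thp)
                if b.joint == "px":
                    ux, uy = cp, sp
                else:
                    ux, uy = -sp, cp
                tau[i] = fxi * ux + fyi * uy
        return tau

    def mass_matrix(self, q) -> np.ndarray:
        n = self.n
        M = np.empty((n, n))
        z = [0.0] * n
        for j in range(n):
            e = [0.0] * n
            e[j] = 1.0
            M[:, j] = self.inverse_dynamics(q, z, e, gravity_on=False)
        return 0.5 * (M + M.T)

    def forward_dynamics(
        self,
        q,
        qd,
        tau: np.ndarray,
        ext_forces=None,
    ) -> np.ndarray:
        z = [0.0] * self.n
        bias = self.inverse_dynamics(q, qd, z, gravity_on=True, ext_forces=ext_forces)
        M = self.mass_matrix(q)
        qdd = np.linalg.solve(M, np.asarray(tau, dtype=float) - bias)
        if not np.all(np.isfinite(qdd)):
            raise IntegrationError("non-finite accelerations")
        return qdd

    def step(self, q, qd, tau, dt: float, ext_forces=None):
        """Semi-implicit Euler step; returns (q, qd) as ndarrays."""
        qdd = self.forward_dynamics(q, qd, tau, ext_forces)
        qd2 = np.asarray(qd, dtype=float) + dt * qdd
        q2 = np.asarray(q, dtype=float) + dt * qd2
        return q2, qd2

    # ------------------------------------------------------------------
    # observables
    # ------------------------------------------------------------------
    def body_coms(self, q) -> np.ndarray:
        """World CoM of every body, shape (n, 2)."""
        frames = self.fk(q)
        out = np.empty((self.n, 2))
        for i, b in enumerate(self.bodies):
            th, x, y = frames[i]
            c, s = math.cos(th), math.sin(th)
            out[i, 0] = x + c * b.com[0] - s * b.com[1]
            out[i, 1] = y + s * b.com[0] + c * b.com[1]
        return out

    @property
    def total_mass(self) -> float:
        return sum(b.mass for b in self.bodies)

    def com(self, q) -> tuple[float, float]:
        coms = self.body_coms(q)
        m = np.array([b.mass for b in self.bodies])
        M = m.sum()
        return float((coms[:, 0] * m).sum() / M), float((coms[:, 1] * m).sum() / M)

    def total_energy(self, q, qd) -> float:
        """Kinetic plus gravitational potential energy."""
        z = [0.0] * self.n
        th, px, py, w, vx, vy, *_ = self._forward(q, qd, z, gravity_on=False)
        E = 0.0
        for i, b in enumerate(self.bodies):
            c, s = math.cos(th[i]), math.sin(th[i])
            rcx = c * b.com[0] - s * b.com[1]
            rcy = s * b.com[0] + c * b.com[1]
            vCx = vx[i] - w[i] * rcy
            vCy = vy[i] + w[i] * rcx
            E += 0.5 * b.mass * (vCx * vCx + vCy * vCy)
            E += 0.5 * b.inertia * w[i] * w[i]
            E += b.mass * self.gravity * (py[i] + rcy)
        return E
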