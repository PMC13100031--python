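"""Delayed length/force reflex network.

The stimulation of muscle *i* is an affine function of delayed, normalized
proprioceptive signals:

    u_i(t) = clip( c_i + sum_{j in R_i} [ kL_ij * L~_j(t - dt_j)
                                        + kF_ij * F~_j(t - dt_j) ] )

where ``R_i`` contains the homonymous pathway (j = i) plus the antagonistic
pathways feeding *i*, ``L~`` is contractile-element length normalized by
optimal fiber length, ``F~`` is tendon force normalized by maximum isometric
force, and ``dt_j`` is the neural conduction delay of the source muscle.
One parameter set drives both legs; each leg reads its own sensors.

For the standard nine-muscle leg the network has 31 connections
(9 homonymous + 22 antagonistic), giving 31 length gains, 31 force gains and
9 constant offsets: 71 free parameters in total.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

#: Canonical muscle order of one leg: gluteus, iliopsoas, rectus femoris,
#: hamstrings, biceps femoris (short head), vastus, gastrocnemius,
#: tibialis anterior, soleus.
MUSCLES: tuple[str, ...] = ("GLU", "ILI", "RF", "HAM", "BF", "VAS", "GAS", "TA", "SOL")

#: Mutual antagonist pairs crossing a shared joint.  Hip: flexors ILI/RF vs
#: extensors GLU/HAM.  Knee: extensors VAS/RF vs flexors HAM/BF/GAS.
#: Ankle: plantarflexors SOL/GAS vs dorsiflexor TA.  Eleven mutual pairs give
#: 22 directed antagonistic connections, 31 connections with the homonymous
#: ones.
DEFAULT_ANTAGONIST_PAIRS: tuple[tuple[str, str], ...] = (
    ("GLU", "ILI"),
    ("GLU", "RF"),
    ("HAM", "ILI"),
    ("HAM", "RF"),
    ("VAS", "HAM"),
    ("VAS", "BF"),
    ("VAS", "GAS"),
    ("RF", "BF"),
    ("RF", "GAS"),
    ("SOL", "TA"),
    ("GAS", "TA"),
)

STANDARD_N_CONNECTIONS = 31
STANDARD_N_PARAMETERS = 71


class TopologyError(ValueError):
    """Connection network violates a structural invariant."""


class CodecError(ValueError):
    """Parameter vector has the wrong shape for its network."""


def default_antagonist_map() -> dict[str, tuple[str, ...]]:
    """Mutual antagonist map of the standard nine-muscle leg."""
    out: dict[str, list[str]] = {m: [] for m in MUSCLES}
    for a, b in DEFAULT_ANTAGONIST_PAIRS:
        out[a].append(b)
        out[b].append(a)
    return {m: tuple(v) for m, v in out.items()}


@dataclass(frozen=True)
class Connection:
    target: str
    source: str
    relation: str  # "homonymous" | "antagonistic"


@dataclass(frozen=True)
class ConnectionMatrix:
    """Ordered reflex connection topology shared by both legs.

    Canonical connection order: by target muscle, homonymous pathway first,
    then antagonistic pathways by source muscle order.
    """

    muscles: tuple[str, ...]
    connections: tuple[Connection, ...]

    @property
    def n_muscles(self) -> int:
        return len(self.muscles)

    @property
    def n_connections(self) -> int:
        return len(self.connections)

    @property
    def n_parameters(self) -> int:
        """Length gains + force gains + per-muscle offsets."""
        return 2 * self.n_connections + self.n_muscles

    def muscle_index(self, name: str) -> int:
        return self.muscles.index(name)

    def sources_of(self, target: str) -> tuple[str, ...]:
        return tuple(c.source for c in self.connections if c.target == target)

    def gain_matrices(
        self, kappa_L: np.ndarray, kappa_F: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        """Dense (n_muscles, n_muscles) gain matrices KL[i, j], KF[i, j]."""
        n = self.n_muscles
        KL = np.zeros((n, n))
        KF = np.zeros((n, n))
        for k, c in enumerate(self.connections):
            i = self.muscle_index(c.target)
            j = self.muscle_index(c.source)
            KL[i, j] = kappa_L[k]
            KF[i, j] = kappa_F[k]
        return KL, KF


def build_connection_matrix(
    antagonist_map: Mapping[str, Sequence[str]] | None = None,
    muscles: Sequence[str] = MUSCLES,
    expected_total: int | None = None,
) -> ConnectionMatrix:
    """Build the reflex connection topology from a mutual antagonist map.

    Parameters
    ----------
    antagonist_map
        Maps each muscle to its antagonists; must be mutual.  ``None`` uses
        the default map of the standard nine-muscle leg.
    muscles
        Muscle names in canonical order (targets and sources).
    expected_total
        Required connection count.  Defaults to 31 for the standard
        nine-muscle leg, unchecked for other muscle sets.

    Raises
    ------
    TopologyError
        If the map is not mutual, references unknown muscles, or the
        connection count differs from ``expected_total``.
    """
    muscles = tuple(muscles)
    if antagonist_map is None:
        if muscles != MUSCLES:
            raise TopologyError("no default antagonist map for non-standard muscles")
        antagonist_map = default_antagonist_map()
    if expected_total is None and muscles == MUSCLES:
        expected_total = STANDARD_N_CONNECTIONS

    amap = {m: tuple(antagonist_map.get(m, ())) for m in muscles}
    for m, ants in amap.items():
        for a in ants:
            if a not in muscles:
                raise TopologyError(f"unknown antagonist {a!r} of {m!r}")
            if m not in amap[a]:
                raise TopologyError(f"antagonist map not mutual: {m!r} -> {a!r}")
            if a == m:
                raise TopologyError(f"muscle {m!r} listed as its own antagonist")
        if len(set(ants)) != len(ants):
            raise TopologyError(f"duplicate antagonists for {m!r}")

    connections: list[Connection] = []
    for m in muscles:
        connections.append(Connection(m, m, "homonymous"))
        for a in sorted(amap[m], key=muscles.index):
            connections.append(Connection(m, a, "antagonistic"))

    matrix = ConnectionMatrix(muscles, tuple(connections))
    if expected_total is not None and matrix.n_connections != expected_total:
        raise TopologyError(
            f"expected {expected_total} connections, got {matrix.n_connections}"
        )
    return matrix


def standard_connection_matrix() -> ConnectionMatrix:
    """The 31-connection network of the standard nine-muscle leg."""
    return build_connection_matrix()


@dataclass
class ParameterVector:
    """Reflex gains and offsets in canonical order.

    Encoded layout: all length gains in connection order, then all force
    gains, then the per-muscle constant offsets.  For the standard network
    this is a 71-vector.
    """

    matrix: ConnectionMatrix
    kappa_L: np.ndarray
    kappa_F: np.ndarray
    offsets: np.ndarray

    def __post_init__(self) -> None:
        self.kappa_L = np.asarray(self.kappa_L, dtype=float)
        self.kappa_F = np.asarray(self.kappa_F, dtype=float)
        self.offsets = np.asarray(self.offsets, dtype=float)
        nc, nm = self.matrix.n_connections, self.matrix.n_muscles
        if self.kappa_L.shape != (nc,) or self.kappa_F.shape != (nc,):
            raise CodecError(f"gain vectors must have shape ({nc},)")
        if self.offsets.shape != (nm,):
            raise CodecError(f"offsets must have shape ({nm},)")

    @property
    def size(self) -> int:
        return self.matrix.n_parameters

    def encode(self) -> np.ndarray:
        return np.concatenate([self.kappa_L, self.kappa_F, self.offsets])

    @classmethod
    def decode(cls, matrix: ConnectionMatrix, vec: np.ndarray) -> "ParameterVector":
        vec = np.asarray(vec, dtype=float)
        n = matrix.n_parameters
        if vec.shape != (n,):
            raise CodecError(f"expected a {n}-vector, got shape {vec.shape}")
        nc = matrix.n_connections
        return cls(matrix, vec[:nc].copy(), vec[nc : 2 * nc].copy(), vec[2 * nc :].copy())

    @classmethod
    def zeros(cls, matrix: ConnectionMatrix) -> "ParameterVector":
        return cls.decode(matrix, np.zeros(matrix.n_parameters))

    def copy(self) -> "ParameterVector":
        return ParameterVector.decode(self.matrix, self.encode())

    def names(self) -> list[str]:
        """Canonical column names: kL_<tgt>_<src>, kF_<tgt>_<src>, c_<muscle>."""
        cols = [f"kL_{c.target}_{c.source}" for c in self.matrix.connections]
        cols += [f"kF_{c.target}_{c.source}" for c in self.matrix.connections]
        cols += [f"c_{m}" for m in self.matrix.muscles]
        return cols


def parameter_names(matrix: ConnectionMatrix) -> list[str]:
    return ParameterVector.zeros(matrix).names()


#: Index of each parameter kind within the encoded vector.
def parameter_kinds(matrix: ConnectionMatrix) -> list[str]:
    nc, nm = matrix.n_connections, matrix.n_muscles
    return ["kL"] * nc + ["kF"] * nc + ["c"] * nm


class SensorHistory:
    """Ring buffers of normalized length/force signals with per-muscle delays.

    Lookups earlier than the recorded history return the initial sample; the
    delayed sample is the nearest recorded one (controller rate = push rate).
    """

    def __init__(
        self,
        delay_steps: Sequence[int],
        init_L: np.ndarray,
        init_F: np.ndarray,
    ) -> None:
        self.delay_steps = np.asarray(delay_steps, dtype=int)
        if np.any(self.delay_steps < 0):
            raise ValueError("delays must be non-negative")
        self.n = len(self.delay_steps)
        self.horizon = int(self.delay_steps.max()) + 1
        self._L = np.tile(np.asarray(init_L, dtype=float), (self.horizon, 1))
        self._F = np.tile(np.asarray(init_F, dtype=float), (self.horizon, 1))
        self._ptr = 0
        self._cols = np.arange(self.n)

    def push(self, L: np.ndarray, F: np.ndarray) -> None:
        self._ptr = (self._ptr + 1) % self.horizon
        self._L[self._ptr] = L
        self._F[self._ptr] = F

    def delayed(self) -> tuple[np.ndarray, np.ndarray]:
        rows = (self._ptr - self.delay_steps) % self.horizon
        return self._L[rows, self._cols], self._F[rows, self._cols]


def compute_stimulation(
    offsets: np.ndarray,
    KL: np.ndarray,
    KF: np.ndarray,
    L_delayed: np.ndarray,
    F_delayed: np.ndarray,
    u_min: float = 0.0,
    u_max: float = 1.0,
) -> np.ndarray:
    """Affine reflex law with clipping to the physical stimulation range."""
    u = offsets + KL @ L_delayed + KF @ F_delayed
    return np.clip(u, u_min, u_max)


class ReflexController:
    """Applies one parameter set symmetrically to every leg of a plant.

    ``legs`` maps each leg to plant-muscle indices in canonical muscle order,
    so a biped passes two nine-index groups and a one-legged plant one group.
    """

    def __init__(
        self,
        matrix: ConnectionMatrix,
        legs: Sequence[Sequence[int]],
        delays_s: Sequence[float],
        dt: float,
        u_min: float = 0.0,
        u_max: float = 1.0,
    ) -> None:
        if dt <= 0:
            raise ValueError("dt must be positive")
        self.matrix = matrix
        self.legs = [np.asarray(g, dtype=int) for g in legs]
        for g in self.legs:
            if len(g) != matrix.n_muscles:
                raise TopologyError("each leg must supply one index per muscle")
        self.n_total = sum(len(g) for g in self.legs)
        delays_s = np.asarray(delays_s, dtype=float)
        if delays_s.shape != (self.n_total,):
            raise ValueError("one delay per plant muscle required")
        self.delay_steps = np.maximum(1, np.rint(delays_s / dt).astype(int))
        self.dt = dt
        self.u_min, self.u_max = u_min, u_max
        self._KL: np.ndarray | None = None
        self._KF: np.ndarray | None = None
        self._c: np.ndarray | None = None
        self.history: SensorHistory | None = None

    def set_params(self, params: ParameterVector) -> None:
        if params.matrix is not self.matrix and params.matrix != self.matrix:
            raise TopologyError("parameter vector built for a different network")
        self._KL, self._KF = self.matrix.gain_matrices(params.kappa_L, params.kappa_F)
        self._c = params.offsets.copy()

    def reset(self, L0: np.ndarray, F0: np.ndarray) -> None:
        self.history = SensorHistory(self.delay_steps, L0, F0)

    def step(self, L: np.ndarray, F: np.ndarray) -> np.ndarray:
        """Push current signals, return stimulations from delayed ones."""
        if self.history is None:
            self.reset(L, F)
        assert self._c is not None, "set_params() before stepping"
        self.history.push(L, F)
        Ld, Fd = self.history.delayed()
        u = np.empty(self.n_total)
        for g in self.legs:
            u[g] = compute_stimulation(
                self._c, self._KL, self._KF, Ld[g], Fd[g], self.u_min, self.u_max
            )
        return u
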