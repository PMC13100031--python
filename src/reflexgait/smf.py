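"""Speed-modulation function (SMF).

For each key parameter k, an ordinary least-squares polynomial of degree
``d_reg`` in (actual) speed is fitted over a speed dataset:

    SMF_k(v) = beta_0k + beta_1k v + beta_2k v^2 + beta_3k v^3,

with beta_nk = 0 for n > d_reg.  A full controller parameter vector for any
target speed is assembled by evaluating the polynomials at v for the key
entries and copying the frozen initial values for all others.  An offline
sweep evaluates the assembled vectors over a grid of target speeds and
records which are stable and at which actual speed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
import numpy as np
from numpy.polynomial import polynomial as npoly

from .controller import ParameterVector
from .episode import EpisodeConfig, run_episode
from .key_params import KeySelection
from .speed_opt import SpeedDataset

MAX_DEGREE = 3


def default_grid(
    v_min: float = 0.5, v_max: float = 3.5, step: float = 0.025
) -> np.ndarray:
    """Target-speed grid; the default spans 0.5-3.5 m/s in 121 points."""
    n = int(round((v_max - v_min) / step)) + 1
    return np.linspace(v_min, v_max, n)


@dataclass
class SMFModel:
    """Per-key polynomial coefficients plus the frozen baseline vector."""

    degree: int
    keys: KeySelection
    beta: np.ndarray  # (n_key, 4), ascending powers, zero above degree
    p_init: ParameterVector
    stable_range: tuple[float, float] | None = None  # [v_tgt_min, v_tgt_max]

    def __post_init__(self) -> None:
        if not 1 <= self.degree <= MAX_DEGREE:
            raise ValueError("degree must be 1, 2 or 3")
        self.beta = np.asarray(self.beta, dtype=float)
        if self.beta.shape != (self.keys.n_key, MAX_DEGREE + 1):
            raise ValueError("beta must have shape (n_key, 4)")
        if np.any(self.beta[:, self.degree + 1 :] != 0.0):
            raise ValueError("beta entries above the degree must be zero")


def fit_smf(
    dataset: SpeedDataset,
    keys: KeySelection,
    degree: int,
    p_init: ParameterVector,
) -> SMFModel:
    """Least-squares polynomial fit of each key parameter against speed."""
    if not 1 <= degree <= MAX_DEGREE:
        raise ValueError("degree must be 1, 2 or 3")
    if len(dataset) <= degree + 1:
        raise ValueError(
            f"need more than {degree + 1} records for degree {degree}, "
            f"got {len(dataset)}"
        )
    v = dataset.v_act
    if np.ptp(v) <= 0:
        raise ValueError("degenerate design: all speeds equal")
    beta = np.zeros((keys.n_key, MAX_DEGREE + 1))
    for row, idx in enumerate(keys.indices):
        coeffs = npoly.polyfit(v, dataset.params[:, idx], degree)
        beta[row, : degree + 1] = coeffs
    return SMFModel(degree=degree, keys=keys, beta=beta, p_init=p_init.copy())


def assemble(model: SMFModel, v_tgt: float) -> ParameterVector:
    """Parameter vector for a target speed: polynomials for key entries,
    frozen initial values elsewhere.  Extrapolation outside the stable range
    is allowed (the sweep records that range separately)."""
    full = model.p_init.encode()
    powers = np.array([1.0, v_tgt, v_tgt**2, v_tgt**3])
    full[list(model.keys.indices)] = model.beta @ powers
    return ParameterVector.decode(model.p_init.matrix, full)


@dataclass
class SweepResult:
    """Offline evaluation of the SMF over a target-speed grid."""

    v_tgt: np.ndarray
    stable: np.ndarray  # bool
    v_act: np.ndarray  # nan where unstable
    gait: list[str]

    def __post_init__(self) -> None:
        self.v_tgt = np.asarray(self.v_tgt, dtype=float)
        if np.any(np.diff(self.v_tgt) <= 0):
            raise ValueError("sweep grid must be strictly increasing")

    def stable_points(self) -> tuple[np.ndarray, np.ndarray]:
        m = self.stable
        return self.v_tgt[m], self.v_act[m]

    def stable_target_range(self) -> tuple[float, float] | None:
        v = self.v_tgt[self.stable]
        if v.size == 0:
            return None
        return float(v.min()), float(v.max())

    def actual_speed_range(self) -> float:
        """Span of achieved speeds over the stable grid points."""
        v = self.v_act[self.stable]
        return float(v.max() - v.min()) if v.size else 0.0


def offline_sweep(
    plant,
    model: SMFModel,
    grid: np.ndarray | None = None,
    episode_cfg: EpisodeConfig | None = None,
) -> SweepResult:
    """One deterministic episode per grid point; updates the model's stable
    target range in place."""
    grid = default_grid() if grid is None else np.asarray(grid, dtype=float)
    episode_cfg = episode_cfg or EpisodeConfig()
    stable = np.zeros(len(grid), dtype=bool)
    v_act = np.full(len(grid), np.nan)
    gait: list[str] = []
    for i, v in enumerate(grid):
        result = run_episode(plant, assemble(model, float(v)), episode_cfg)
        stable[i] = result.stable
        gait.append(result.gait if result.stable else "none")
        if result.stable and result.v_act is not None:
            v_act[i] = result.v_act
    sweep = SweepResult(v_tgt=grid, stable=stable, v_act=v_act, gait=gait)
    rng = sweep.stable_target_range()
    if rng is None:
        warnings.warn("offline sweep found no stable target speed")
    model.stable_range = rng
    return sweep


def online_target_bounds(sweep: SweepResult) -> tuple[float, float]:
    """Stable target-speed bounds for online use.

    The targets at which the actual speed is minimal/maximal among stable
    points, with the slowest and fastest stable targets excluded to avoid
    operating at the edge of instability.
    """
    v_tgt, v_act = sweep.stable_points()
    if len(v_tgt) < 3:
        raise ValueError("need at least 3 stable sweep points")
    inner = slice(1, -1)  # exclude slowest and fastest stable targets
    vt, va = v_tgt[inner], v_act[inner]
    return float(vt[np.argmin(va)]), float(vt[np.argmax(va)])


@dataclass(frozen=True)
class MonotonicityReport:
    n_stable: int
    violations: tuple[int, ...]  # indices i where v_act[i+1] < v_act[i]
    longest_monotone_run: int
    max_identity_deviation: float  # max |v_act - v_tgt| over stable points
    rms_identity_deviation: float

    @property
    def n_violations(self) -> int:
        return len(self.violations)


def monotonicity_report(sweep: SweepResult) -> MonotonicityReport:
    """Diagnostics of the v_act-vs-v_tgt relation over the stable points."""
    v_tgt, v_act = sweep.stable_points()
    if len(v_tgt) < 2:
        raise ValueError("need at least 2 stable sweep points")
    dv = np.diff(v_act)
    violations = tuple(int(i) for i in np.nonzero(dv < 0)[0])
    longest = run = 1
    for d in dv:
        run = run + 1 if d >= 0 else 1
        longest = max(longest, run)
    dev = v_act - v_tgt
    return MonotonicityReport(
        n_stable=len(v_tgt),
        violations=violations,
        longest_monotone_run=longest,
        max_identity_deviation=float(np.max(np.abs(dev))),
        rms_identity_deviation=float(np.sqrt(np.mean(dev**2))),
    )
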