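"""Speed min/max optimization and harvesting of speed datasets.

The optimization cost combines a velocity reward and a fall penalty,

    J = 100 * J_vel + 100 * J_fall,
    J_vel  = +- d_sim / t_max   (+ minimize, - maximize),
    J_fall = 1 - t_sim / t_max,

so stable solutions (t_sim = t_max) have J_fall = 0 and J is proportional to
the (signed) average speed.  CMA-ES performs a local search around a
parameter set known to produce stable gait; every generation's best
candidate is re-simulated deterministically and, when stable, harvested into
a dataset of (parameter vector, actual speed) records.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import cma
from .controller import ParameterVector, parameter_names
from .episode import (
    MAXIMIZE,
    MINIMIZE,
    EpisodeConfig,
    EpisodeResult,
    episode_distance,
    run_episode,
)


@dataclass(frozen=True)
class CostBreakdown:
    J: float
    J_vel: float
    J_fall: float
    direction: str

    def __post_init__(self) -> None:
        assert self.direction in (MINIMIZE, MAXIMIZE)
        assert abs(self.J - 100.0 * (self.J_vel + self.J_fall)) < 1e-9
        assert -1e-12 <= self.J_fall <= 1.0 + 1e-12


def cost(result: EpisodeResult, direction: str) -> CostBreakdown:
    """Velocity-reward + fall-penalty cost of a finished episode."""
    if direction not in (MINIMIZE, MAXIMIZE):
        raise ValueError(f"unknown direction {direction!r}")
    d_sim = episode_distance(result, direction)
    j_vel = d_sim / result.t_max
    if direction == MAXIMIZE:
        j_vel = -j_vel
    j_fall = 1.0 - result.t_sim / result.t_max
    return CostBreakdown(
        J=100.0 * (j_vel + j_fall), J_vel=j_vel, J_fall=j_fall, direction=direction
    )


@dataclass(frozen=True)
class CmaConfig:
    """CMA-ES driver settings for the speed search."""

    sigma0: float = 0.01
    n_seeds: int = 20
    improve_tol: float = 1e-5
    improve_window: int = 500
    max_generations: int = 3000  # safety net beyond the improvement rule
    popsize: int | None = None

    def __post_init__(self) -> None:
        if self.sigma0 <= 0:
            raise ValueError("sigma0 must be positive")
        if self.n_seeds < 1:
            raise ValueError("n_seeds must be >= 1")


@dataclass
class GenerationRecord:
    """Best candidate of one CMA-ES generation."""

    generation: int
    x: np.ndarray  # full encoded parameter vector
    J: float
    t_sim: float
    stable: bool
    v_act: float | None


@dataclass
class OptimizationHistory:
    direction: str
    seed: int
    records: list[GenerationRecord]
    stop_reason: str
    restricted_keys: tuple[int, ...] | None = None

    @property
    def best(self) -> GenerationRecord:
        return min(self.records, key=lambda r: r.J)


def _evaluate(plant, matrix, x, episode_cfg, direction):
    params = ParameterVector.decode(matrix, x)
    result = run_episode(plant, params, episode_cfg)
    return result, cost(result, direction)


def optimize(
    plant,
    p_init: ParameterVector,
    direction: str,
    cfg: CmaConfig | None = None,
    episode_cfg: EpisodeConfig | None = None,
    seed: int = 0,
    keys: Sequence[int] | None = None,
) -> OptimizationHistory:
    """One CMA-ES run toward slower (minimize) or faster (maximize) gait.

    ``keys`` restricts the search to those parameter indices; the remaining
    entries stay fixed at their values in ``p_init``.
    """
    cfg = cfg or CmaConfig()
    episode_cfg = episode_cfg or EpisodeConfig()
    matrix = p_init.matrix
    x_full = p_init.encode()

    init_result, _ = _evaluate(plant, matrix, x_full, episode_cfg, direction)
    if not init_result.stable:
        warnings.warn("initial parameter set does not produce a stable episode")

    if keys is not None:
        keys_arr = np.asarray(sorted(keys), dtype=int)
        x0 = x_full[keys_arr]

        def expand(xs: np.ndarray) -> np.ndarray:
            full = x_full.copy()
            full[keys_arr] = xs
            return full

    else:
        keys_arr = None
        x0 = x_full

        def expand(xs: np.ndarray) -> np.ndarray:
            return xs

    records: list[GenerationRecord] = []

    def objective(x: np.ndarray) -> float:
        _, br = _evaluate(plant, matrix, expand(x), episode_cfg, direction)
        return br.J

    def callback(gen: int, x_best: np.ndarray, f_best: float) -> None:
        full = expand(x_best)
        result, br = _evaluate(plant, matrix, full, episode_cfg, direction)
        records.append(
            GenerationRecord(
                generation=gen,
                x=np.asarray(full, dtype=float).copy(),
                J=br.J,
                t_sim=result.t_sim,
                stable=result.stable,
                v_act=result.v_act,
            )
        )

    res = cma.minimize(
        objective,
        x0,
        cfg.sigma0,
        seed=seed,
        popsize=cfg.popsize,
        max_generations=cfg.max_generations,
        improve_tol=cfg.improve_tol,
        improve_window=cfg.improve_window,
        callback=callback,
    )
    return OptimizationHistory(
        direction=direction,
        seed=seed,
        records=records,
        stop_reason=res.stop_reason,
        restricted_keys=tuple(keys_arr) if keys_arr is not None else None,
    )


@dataclass
class SpeedDataset:
    """Stable (parameter vector, actual speed) records, sorted by speed."""

    params: np.ndarray  # (n, n_parameters)
    v_act: np.ndarray  # (n,)
    provenance: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.params = np.atleast_2d(np.asarray(self.params, dtype=float))
        self.v_act = np.asarray(self.v_act, dtype=float)
        if self.params.shape[0] != self.v_act.shape[0]:
            raise ValueError("params and v_act lengths differ")
        if not self.provenance:
            self.provenance = [{} for _ in range(len(self.v_act))]

    def __len__(self) -> int:
        return len(self.v_act)

    @property
    def n_v(self) -> int:
        return len(self.v_act)

    def speed_range(self) -> float:
        """v_max - v_min across the records (the span reported per dataset)."""
        if len(self) == 0:
            return 0.0
        return float(self.v_act.max() - self.v_act.min())

    def sorted_deduped(self) -> "SpeedDataset":
        """Sort by v_act and drop records with identical parameter vectors."""
        order = np.argsort(self.v_act, kind="stable")
        p = self.params[order]
        v = self.v_act[order]
        prov = [self.provenance[i] for i in order]
        seen: set[bytes] = set()
        keep = []
        for i in range(len(v)):
            key = p[i].tobytes()
            if key not in seen:
                seen.add(key)
                keep.append(i)
        return SpeedDataset(p[keep], v[keep], [prov[i] for i in keep])

    def merge(self, other: "SpeedDataset") -> "SpeedDataset":
        return SpeedDataset(
            np.vstack([self.params, other.params]),
            np.concatenate([self.v_act, other.v_act]),
            self.provenance + other.provenance,
        ).sorted_deduped()

    def to_frame(self, matrix) -> pd.DataFrame:
        df = pd.DataFrame(self.params, columns=parameter_names(matrix))
        df["v_act"] = self.v_act
        df["stable"] = True
        for key in ("direction", "seed", "generation"):
            if any(key in p for p in self.provenance):
                df[key] = [p.get(key) for p in self.provenance]
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, matrix) -> "SpeedDataset":
        cols = parameter_names(matrix)
        prov_cols = [c for c in ("direction", "seed", "generation") if c in df]
        prov = [
            {c: row[c] for c in prov_cols} for _, row in df[prov_cols].iterrows()
        ] if prov_cols else []
        return cls(df[cols].to_numpy(float), df["v_act"].to_numpy(float), prov)


def harvest(
    plant,
    history: OptimizationHistory,
    episode_cfg: EpisodeConfig | None = None,
) -> SpeedDataset:
    """Re-evaluate each generation's best candidate; keep the stable ones.

    Every kept record satisfies t_sim = t_max and carries its measured
    actual speed.  An empty harvest is valid (warned).
    """
    if not history.records:
        raise ValueError("empty optimization history")
    episode_cfg = episode_cfg or EpisodeConfig()
    matrix_needed = None
    rows: list[np.ndarray] = []
    speeds: list[float] = []
    prov: list[dict] = []
    for rec in history.records:
        result = run_episode(
            plant,
            ParameterVector.decode(plant.connection_matrix, rec.x),
            episode_cfg,
        )
        if result.stable and result.v_act is not None:
            rows.append(rec.x)
            speeds.append(result.v_act)
            prov.append(
                {
                    "direction": history.direction,
                    "seed": history.seed,
                    "generation": rec.generation,
                }
            )
    if not rows:
        warnings.warn("harvest produced no stable records")
        n = len(history.records[0].x)
        return SpeedDataset(np.empty((0, n)), np.empty(0), [])
    return SpeedDataset(np.vstack(rows), np.array(speeds), prov).sorted_deduped()


def build_omega(
    plant,
    min_histories: Sequence[OptimizationHistory],
    max_histories: Sequence[OptimizationHistory],
    episode_cfg: EpisodeConfig | None = None,
) -> SpeedDataset:
    """Merge the widest-span harvest of each direction into one dataset.

    Per direction, the seed whose harvested records span the largest range
    of actual speeds is selected; the two harvests are concatenated, sorted
    by speed and deduplicated.
    """
    if not min_histories and not max_histories:
        raise ValueError("at least one optimization history per direction required")

    def best_harvest(histories):
        harvests = [harvest(plant, h, episode_cfg) for h in histories]
        non_empty = [h for h in harvests if len(h)]
        if not non_empty:
            return None
        return max(non_empty, key=lambda d: d.speed_range())

    best_min = best_harvest(min_histories) if min_histories else None
    best_max = best_harvest(max_histories) if max_histories else None
    if best_min is None and best_max is None:
        raise ValueError("no stable records harvested in either direction")
    if best_min is None:
        return best_max.sorted_deduped()
    if best_max is None:
        return best_min.sorted_deduped()
    return best_min.merge(best_max)
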