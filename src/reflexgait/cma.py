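"""Covariance matrix adaptation evolution strategy (CMA-ES).

A compact implementation of the standard (mu/mu_w, lambda)-CMA-ES with
cumulative step-size adaptation, rank-one and rank-mu covariance updates
(Hansen's reference formulation).  Deterministic given the seed.

Termination follows the gait-optimization convention used throughout this
package: stop when the average relative improvement of the best cost over a
trailing window falls below a tolerance per iteration, with a hard
generation cap as a safety net.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np


@dataclass
class CmaResult:
    x_best: np.ndarray
    f_best: float
    n_generations: int
    stop_reason: str
    best_per_generation: list[float] = field(default_factory=list)


class CmaEs:
    """Ask/tell interface; minimizes the objective."""

    def __init__(
        self,
        x0: Sequence[float],
        sigma0: float,
        seed: int = 0,
        popsize: int | None = None,
    ) -> None:
        if sigma0 <= 0:
            raise ValueError("sigma0 must be positive")
        self.mean = np.asarray(x0, dtype=float).copy()
        self.n = len(self.mean)
        self.sigma = float(sigma0)
        self.rng = np.random.default_rng(seed)

        self.lam = popsize or 4 + int(3 * math.log(self.n))
        self.mu = self.lam // 2
        w = math.log(self.mu + 0.5) - np.log(np.arange(1, self.mu + 1))
        self.weights = w / w.sum()
        self.mueff = 1.0 / np.sum(self.weights**2)

        n, mueff = self.n, self.mueff
        self.cc = (4 + mueff / n) / (n + 4 + 2 * mueff / n)
        self.cs = (mueff + 2) / (n + mueff + 5)
        self.c1 = 2 / ((n + 1.3) ** 2 + mueff)
        self.cmu = min(
            1 - self.c1, 2 * (mueff - 2 + 1 / mueff) / ((n + 2) ** 2 + mueff)
        )
        self.damps = 1 + 2 * max(0.0, math.sqrt((mueff - 1) / (n + 1)) - 1) + self.cs
        self.chi_n = math.sqrt(n) * (1 - 1 / (4 * n) + 1 / (21 * n**2))

        self.pc = np.zeros(n)
        self.ps = np.zeros(n)
        self.C = np.eye(n)
        self._decompose()
        self.generation = 0

    def _decompose(self) -> None:
        self.C = 0.5 * (self.C + self.C.T)
        d, B = np.linalg.eigh(self.C)
        d = np.maximum(d, 1e-20)
        self.B = B
        self.D = np.sqrt(d)
        self._inv_sqrt = B @ np.diag(1.0 / self.D) @ B.T

    def ask(self) -> np.ndarray:
        """Sample a population, shape (lambda, n)."""
        z = self.rng.standard_normal((self.lam, self.n))
        self._y = z @ np.diag(self.D) @ self.B.T  # y ~ N(0, C)
        return self.mean + self.sigma * self._y

    def tell(self, xs: np.ndarray, fs: Sequence[float]) -> None:
        fs = np.asarray(fs, dtype=float)
        order = np.argsort(fs, kind="stable")
        y = (xs[order[: self.mu]] - self.mean) / self.sigma
        y_w = self.weights @ y
        self.mean = self.mean + self.sigma * y_w

        self.ps = (1 - self.cs) * self.ps + math.sqrt(
            self.cs * (2 - self.cs) * self.mueff
        ) * (self._inv_sqrt @ y_w)
        hsig = float(
            np.linalg.norm(self.ps)
            / math.sqrt(1 - (1 - self.cs) ** (2 * (self.generation + 1)))
            < (1.4 + 2 / (self.n + 1)) * self.chi_n
        )
        self.pc = (1 - self.cc) * self.pc + hsig * math.sqrt(
            self.cc * (2 - self.cc) * self.mueff
        ) * y_w

        rank_mu = sum(w * np.outer(yi, yi) for w, yi in zip(self.weights, y))
        self.C = (
            (1 - self.c1 - self.cmu) * self.C
            + self.c1
            * (np.outer(self.pc, self.pc) + (1 - hsig) * self.cc * (2 - self.cc) * self.C)
            + self.cmu * rank_mu
        )
        self.sigma *= math.exp(
            (self.cs / self.damps) * (np.linalg.norm(self.ps) / self.chi_n - 1)
        )
        self.generation += 1
        self._decompose()


def improvement_stalled(
    best_history: Sequence[float], window: int, tol: float
) -> bool:
    """True when the mean relative improvement per iteration over the last
    ``window`` iterations drops below ``tol``."""
    if len(best_history) <= window:
        return False
    a = best_history[-window - 1]
    b = best_history[-1]
    rel = (a - b) / (window * (abs(a) + 1e-12))
    return rel < tol


def minimize(
    objective: Callable[[np.ndarray], float],
    x0: Sequence[float],
    sigma0: float,
    seed: int = 0,
    popsize: int | None = None,
    max_generations: int = 3000,
    improve_tol: float = 1e-5,
    improve_window: int = 500,
    f_target: float | None = None,
    callback: Callable[[int, np.ndarray, float], None] | None = None,
) -> CmaResult:
    """Minimize ``objective`` with CMA-ES; returns the best point found.

    ``callback(generation, x_best_of_generation, f_best_of_generation)`` is
    invoked once per generation, after evaluation.
    """
    es = CmaEs(x0, sigma0, seed=seed, popsize=popsize)
    x_best = np.asarray(x0, dtype=float).copy()
    f_best = math.inf
    best_per_gen: list[float] = []
    stop = "max_generations"
    for g in range(max_generations):
        xs = es.ask()
        fs = np.array([objective(x) for x in xs])
        if not np.any(np.isfinite(fs)):
            raise RuntimeError("all objective evaluations non-finite")
        es.tell(xs, fs)
        k = int(np.argmin(fs))
        if fs[k] < f_best:
            f_best = float(fs[k])
            x_best = xs[k].copy()
        best_per_gen.append(f_best)
        if callback is not None:
            callback(g, xs[k], float(fs[k]))
        if f_target is not None and f_best <= f_target:
            stop = "f_target"
            break
        if improvement_stalled(best_per_gen, improve_window, improve_tol):
            stop = "improvement_stalled"
            break
        if es.sigma < 1e-14:
            stop = "sigma_collapse"
            break
    return CmaResult(
        x_best=x_best,
        f_best=f_best,
        n_generations=len(best_per_gen),
        stop_reason=stop,
        best_per_generation=best_per_gen,
    )
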