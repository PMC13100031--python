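"""Key-parameter selection by principal component analysis.

A speed dataset holds controller parameter vectors at different speeds.  The
71 columns are standardized (z-scored) and decomposed by PCA; because speed
is the dominant axis of variation in harvested datasets, the first principal
component separates the records by speed, and the parameters with the
largest absolute PC1 loadings are the *key parameters* for speed
modulation.  A restricted optimization problem varies only those entries,
all others staying fixed at the initial parameter set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.decomposition import PCA

from .controller import ConnectionMatrix, ParameterVector, parameter_kinds
from .speed_opt import SpeedDataset


@dataclass(frozen=True)
class PCASummary:
    """Loadings, explained variance and the standardization constants."""

    loadings: np.ndarray  # (n_components, n_parameters), orthonormal rows
    explained_variance_ratio: np.ndarray
    center: np.ndarray
    scale: np.ndarray

    @property
    def pc1(self) -> np.ndarray:
        return self.loadings[0]


def fit_pca(dataset: SpeedDataset) -> PCASummary:
    """PCA of the standardized parameter matrix of a speed dataset.

    Columns are centered and scaled by their standard deviation
    (zero-variance columns keep unit scale).  Loading signs follow a
    deterministic convention: the largest-magnitude loading of each
    component is positive.
    """
    X = dataset.params
    if X.shape[0] < 3:
        raise ValueError(f"PCA needs at least 3 records, got {X.shape[0]}")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite parameter values")
    center = X.mean(axis=0)
    scale = X.std(axis=0)
    scale = np.where(scale > 0, scale, 1.0)
    Z = (X - center) / scale
    pca = PCA(svd_solver="full")
    pca.fit(Z)
    loadings = pca.components_.copy()
    for r in range(loadings.shape[0]):
        k = int(np.argmax(np.abs(loadings[r])))
        if loadings[r, k] < 0:
            loadings[r] *= -1.0
    return PCASummary(
        loadings=loadings,
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
        center=center,
        scale=scale,
    )


@dataclass(frozen=True)
class KeySelection:
    """Indices of the selected key parameters in the canonical vector."""

    n_key: int
    indices: tuple[int, ...]
    kinds: tuple[str, ...]  # "kL" | "kF" | "c" per index

    def __post_init__(self) -> None:
        assert len(self.indices) == self.n_key == len(set(self.indices))


def select_keys(
    pca: PCASummary,
    n_key: int,
    matrix: ConnectionMatrix | None = None,
) -> KeySelection:
    """The ``n_key`` parameters with the largest |PC1 loading|.

    Ties break toward the lower canonical index.  The selected indices are
    returned in canonical order.
    """
    n_params = pca.loadings.shape[1]
    if not 1 <= n_key <= n_params:
        raise ValueError(f"n_key must be in [1, {n_params}], got {n_key}")
    mag = np.abs(pca.pc1)
    order = sorted(range(n_params), key=lambda i: (-mag[i], i))
    chosen = tuple(sorted(order[:n_key]))
    if matrix is not None:
        kinds = parameter_kinds(matrix)
        kind_tuple = tuple(kinds[i] for i in chosen)
    else:
        kind_tuple = ("?",) * n_key
    return KeySelection(n_key=n_key, indices=chosen, kinds=kind_tuple)


@dataclass(frozen=True)
class RestrictedProblem:
    """Optimization over the key entries only; the rest is frozen.

    ``expand`` writes an n_key candidate into a copy of the initial encoded
    vector; all non-key entries remain bit-equal to the initial values.
    """

    p_init: ParameterVector
    keys: KeySelection

    @property
    def dimension(self) -> int:
        return self.keys.n_key

    @property
    def x0(self) -> np.ndarray:
        return self.p_init.encode()[list(self.keys.indices)]

    def expand(self, x_sub: Sequence[float]) -> np.ndarray:
        x_sub = np.asarray(x_sub, dtype=float)
        if x_sub.shape != (self.keys.n_key,):
            raise ValueError(f"candidate must have shape ({self.keys.n_key},)")
        full = self.p_init.encode()
        full[list(self.keys.indices)] = x_sub
        return full

    def expand_params(self, x_sub: Sequence[float]) -> ParameterVector:
        return ParameterVector.decode(self.p_init.matrix, self.expand(x_sub))


def restricted_problem(p_init: ParameterVector, keys: KeySelection) -> RestrictedProblem:
    if max(keys.indices) >= p_init.size:
        raise ValueError("key index outside the parameter vector")
    return RestrictedProblem(p_init=p_init, keys=keys)
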