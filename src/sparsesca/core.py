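"""Unpenalized simultaneous component analysis and variance accounting.

The SCA model decomposes every block as ``X_k = T P_k' + E_k`` with a single
orthonormal score matrix ``T`` shared across blocks.  The least-squares
solution follows from the SVD of the concatenated data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import MultiblockData, concatenate

__all__ = ["ComponentModel", "VAFResult", "fit_sca", "compute_vaf"]

_RANK_RTOL = 1e-10


@dataclass
class ComponentModel:
    """Scores ``T`` (I x R, orthonormal) plus concatenated loadings ``P_C``.

    ``partition`` maps each block name to its ``(start, stop)`` row range of
    ``P_C`` (equivalently its column range of the concatenated data).
    """

    T: np.ndarray
    P_C: np.ndarray
    partition: dict[str, tuple[int, int]]

    def __post_init__(self) -> None:
        self.T = np.asarray(self.T, dtype=float)
        self.P_C = np.asarray(self.P_C, dtype=float)
        if self.T.ndim != 2 or self.P_C.ndim != 2:
            raise ValueError("T and P_C must be matrices")
        if self.T.shape[1] != self.P_C.shape[1]:
            raise ValueError("T and P_C must have the same number of components")
        stops = [stop for _, stop in self.partition.values()]
        starts = [start for start, _ in self.partition.values()]
        if starts and (starts[0] != 0 or any(
            s != t for s, t in zip(stops[:-1], starts[1:])
        ) or stops[-1] != self.P_C.shape[0]):
            raise ValueError("partition does not tile the rows of P_C")

    @property
    def R(self) -> int:
        return self.T.shape[1]

    def block_loadings(self, name: str) -> np.ndarray:
        start, stop = self.partition[name]
        return self.P_C[start:stop]

    def reconstruct(self) -> np.ndarray:
        """Fitted concatenated data ``T P_C'``."""
        return self.T @ self.P_C.T

    def sse(self, data: MultiblockData) -> float:
        X_C, _ = concatenate(data)
        return float(((X_C - self.reconstruct()) ** 2).sum())

    def orthonormality_error(self) -> float:
        R = self.R
        return float(np.max(np.abs(self.T.T @ self.T - np.eye(R))))


@dataclass
class VAFResult:
    """Per-block and per-component-per-block variance accounted for."""

    block_vaf: np.ndarray
    component_vaf: np.ndarray  # shape (K, R)
    block_names: list[str]
    R_evaluated: int

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.component_vaf,
            index=self.block_names,
            columns=[f"comp_{r + 1}" for r in range(self.R_evaluated)],
        )
        df.insert(0, "block_vaf", self.block_vaf)
        return df


def _fix_signs(T: np.ndarray, P_C: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Flip each component so the largest-magnitude loading is positive."""
    T = T.copy()
    P_C = P_C.copy()
    for r in range(P_C.shape[1]):
        col = P_C[:, r]
        if col.size and col[np.argmax(np.abs(col))] < 0:
            P_C[:, r] = -col
            T[:, r] = -T[:, r]
    return T, P_C


def fit_sca(data: MultiblockData, R: int) -> ComponentModel:
    """Least-squares SCA with ``R`` components via SVD of the concatenation.

    ``T`` holds the first R left singular vectors of the concatenated data
    and ``P_C = X_C' T``, which minimises the summed squared residuals over
    all orthonormal score matrices.
    """
    X_C, partition = concatenate(data)
    max_R = min(X_C.shape)
    if not 1 <= R <= max_R:
        raise ValueError(f"R must be in [1, {max_R}], got {R}")
    U, s, _ = np.linalg.svd(X_C, full_matrices=False)
    rank = int(np.sum(s > s[0] * _RANK_RTOL)) if s.size and s[0] > 0 else 0
    if R > rank:
        raise ValueError(
            f"R={R} exceeds the numerical rank of the data ({rank} attainable)"
        )
    T = U[:, :R]
    P_C = X_C.T @ T
    T, P_C = _fix_signs(T, P_C)
    return ComponentModel(T=T, P_C=P_C, partition=partition)


def compute_vaf(data: MultiblockData, R: int) -> VAFResult:
    """Proportion of each block's sum of squares explained per component.

    Because ``T`` is orthonormal, component r explains ``||p_r^k||^2`` of
    block k, and the block total is the sum over components.
    """
    model = fit_sca(data, R)
    K = data.n_blocks
    component_vaf = np.zeros((K, R))
    block_vaf = np.zeros(K)
    for k, name in enumerate(data.block_names):
        P_k = model.block_loadings(name)
        total = float((data.blocks[k] ** 2).sum())
        component_vaf[k] = (P_k**2).sum(axis=0) / total
        block_vaf[k] = component_vaf[k].sum()
    return VAFResult(
        block_vaf=block_vaf,
        component_vaf=component_vaf,
        block_names=list(data.block_names),
        R_evaluated=R,
    )
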