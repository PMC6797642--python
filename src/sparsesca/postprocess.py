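"""Undo penalty-induced shrinkage and compare component solutions."""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np

from .core import ComponentModel, fit_sca
from .io import MultiblockData, concatenate
from .solvers import update_T

__all__ = ["SparsityPattern", "undo_shrinkage", "match_components", "tucker_congruence"]


@dataclass(frozen=True)
class SparsityPattern:
    """Binary free/fixed-zero mask over the concatenated loading matrix."""

    mask: np.ndarray  # (sum J_k) x R; 1 = free, 0 = fixed zero

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask, dtype=int)
        if mask.ndim != 2 or not np.isin(mask, (0, 1)).all():
            raise ValueError("mask must be a binary matrix")
        object.__setattr__(self, "mask", mask)

    @classmethod
    def from_loadings(cls, P_C: np.ndarray) -> "SparsityPattern":
        """Exact-zero test: the solvers produce bit-zeros, not near-zeros."""
        return cls((np.asarray(P_C) != 0).astype(int))


def undo_shrinkage(
    data: MultiblockData,
    R: int,
    pattern: SparsityPattern,
    tol: float = 1e-9,
    max_iter: int = 10000,
    update_scores: bool = True,
    T_init: np.ndarray | None = None,
) -> ComponentModel:
    """OLS re-estimation of the free loadings at a fixed zero pattern.

    Alternates the Procrustes score update with exact per-component masked
    least squares until the SSE stabilises.  Fixed-zero cells stay bit-zero
    in every iterate.  With ``update_scores=False`` the score matrix is
    frozen at ``T_init`` (or the SCA scores) and a single loadings pass is
    already optimal.
    """
    mask = pattern.mask
    X_C, partition = concatenate(data)
    if mask.shape != (data.total_width, R):
        raise ValueError(f"pattern must be {data.total_width} x {R}")
    if not mask.any():
        warnings.warn("all-zero pattern: returning the zero model", stacklevel=2)
        if T_init is None:
            U, _, _ = np.linalg.svd(X_C, full_matrices=False)
            T_init = U[:, :R]
        return ComponentModel(
            T=T_init, P_C=np.zeros((data.total_width, R)), partition=partition
        )
    T = T_init.copy() if T_init is not None else fit_sca(data, R).T
    P_C = np.zeros((data.total_width, R))
    prev = np.inf
    for _ in range(max_iter):
        # exact masked OLS per component (Gauss-Seidel over components)
        G = T.T @ T
        B = X_C.T @ T
        for r in range(R):
            g = B[:, r] - P_C @ G[:, r] + P_C[:, r] * G[r, r]
            P_C[:, r] = np.where(mask[:, r] == 1, g, 0.0)
        if update_scores:
            T = update_T(X_C, P_C)
        sse = float(((X_C - T @ P_C.T) ** 2).sum())
        if np.isfinite(prev) and abs(prev - sse) <= tol * max(1.0, abs(prev)):
            break
        if not update_scores:
            break
        prev = sse
    return ComponentModel(T=T, P_C=P_C, partition=partition)


def tucker_congruence(p: np.ndarray, q: np.ndarray) -> float:
    """Normalized inner product of two loading vectors (0 if either is 0)."""
    np_, nq = np.linalg.norm(p), np.linalg.norm(q)
    if np_ == 0 or nq == 0:
        return 0.0
    return float(p @ q / (np_ * nq))


def match_components(
    P_est: np.ndarray, P_ref: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Resolve permutation/sign invariance between two loading matrices.

    Finds the column permutation and signs maximizing the mean absolute
    Tucker congruence between matched columns — exactly (enumeration) for
    R <= 8, greedily above.  Returns ``(perm, signs, congruences)`` such
    that ``P_est[:, perm] * signs`` matches ``P_ref`` column-wise;
    ``congruences[r] >= 0`` is the agreement of matched pair r.
    """
    P_est = np.asarray(P_est, dtype=float)
    P_ref = np.asarray(P_ref, dtype=float)
    if P_est.shape != P_ref.shape:
        raise ValueError("P_est and P_ref must have equal shapes")
    R = P_est.shape[1]
    C = np.zeros((R, R))
    for i in range(R):
        for j in range(R):
            C[i, j] = tucker_congruence(P_est[:, i], P_ref[:, j])
    absC = np.abs(C)
    if R <= 8:
        best_perm = min(
            itertools.permutations(range(R)),
            key=lambda perm: -sum(absC[perm[j], j] for j in range(R)),
        )
        perm = np.array(best_perm)
    else:
        perm = np.full(R, -1)
        used = set()
        work = absC.copy()
        for _ in range(R):
            i, j = np.unravel_index(np.argmax(work), work.shape)
            perm[j] = i
            work[i, :] = -1
            work[:, j] = -1
            used.add(i)
    signs = np.array(
        [1.0 if C[perm[j], j] >= 0 else -1.0 for j in range(R)]
    )
    congruences = np.array([absC[perm[j], j] for j in range(R)])
    return perm, signs, congruences
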