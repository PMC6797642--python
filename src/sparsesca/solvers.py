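"""Penalized SCA estimation.

Conditional updates are exact closed forms: given orthonormal scores the
loadings problem is a sparse Group Lasso with an orthonormal design, solved
by soft-thresholding followed by a group-kill positive-part factor; given
loadings the score update is an orthogonal Procrustes problem solved by SVD.
Alternating the two weakly decreases the objective, so the full algorithms
are monotone descent methods combined with a multi-start procedure.

Two grouping conventions are supported:

* ``block``: one group per block (the whole of ``P_k``), which can discard
  an entire data block;
* ``component``: one group per component within each block (a column of
  ``P_k``), which yields common/distinctive component structures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

from .core import ComponentModel, fit_sca
from .io import MultiblockData, concatenate, split

__all__ = [
    "PenaltyConfig",
    "FitResult",
    "soft_threshold",
    "update_T",
    "update_block_loadings",
    "update_component_loadings",
    "objective",
    "fit_sparse_sca",
    "fit_structured_sca",
]


@dataclass(frozen=True)
class PenaltyConfig:
    """Lasso weight, Group Lasso weight and the grouping convention."""

    lambda_L: float = 0.0
    lambda_G: float = 0.0
    method: Literal["component", "block"] = "component"

    def __post_init__(self) -> None:
        if self.lambda_L < 0 or self.lambda_G < 0:
            raise ValueError("penalty weights must be nonnegative")
        if self.method not in ("component", "block"):
            raise ValueError(f"unknown method {self.method!r}")


@dataclass
class FitResult:
    """Outcome of an alternating fit: winning model plus diagnostics."""

    model: ComponentModel
    loss_history: np.ndarray
    converged: bool
    n_iterations: int
    start_index: int
    config: dict = field(default_factory=dict)


def soft_threshold(x: np.ndarray | float, lam: float) -> np.ndarray | float:
    """Elementwise ``sign(x) * max(|x| - lam, 0)``."""
    if lam < 0:
        raise ValueError("threshold must be nonnegative")
    x = np.asarray(x, dtype=float)
    out = np.sign(x) * np.maximum(np.abs(x) - lam, 0.0)
    return out if out.ndim else float(out)


def update_T(X_C: np.ndarray, P_C: np.ndarray) -> np.ndarray:
    """Procrustes score update: ``T = V U'`` with ``U S V' = svd(P_C' X_C')``.

    Maximizes ``trace(T' X_C P_C)`` over orthonormal T.  If ``P_C' X_C'`` is
    rank deficient the returned T is still orthonormal (economy SVD).
    """
    M = P_C.T @ X_C.T  # R x I
    U, _, Vt = np.linalg.svd(M, full_matrices=False)
    return Vt.T @ U.T


def _group_factor(s_norm: float, lambda_G: float, sqrt_J: float) -> float:
    """The positive-part block/component kill factor of the closed form."""
    if s_norm <= 0.0:
        return 0.0
    return max(0.5 - lambda_G * sqrt_J / (2.0 * s_norm), 0.0)


def update_block_loadings(
    X_k: np.ndarray, T: np.ndarray, lambda_L: float, lambda_G: float
) -> np.ndarray:
    """Closed-form sparse Group Lasso update for a whole block's loadings.

    With ``S = soft_threshold(2 X_k' T, lambda_L)`` the solution is
    ``[1/2 - lambda_G sqrt(J_k) / (2 ||S||_2)]_+ * S`` (the Kronecker-product
    formulation evaluated in matrix form).  The update returns an exactly
    zero matrix when the positive part clamps.
    """
    J_k = X_k.shape[1]
    S = soft_threshold(2.0 * (X_k.T @ T), lambda_L)
    factor = _group_factor(float(np.linalg.norm(S)), lambda_G, np.sqrt(J_k))
    if factor == 0.0:
        return np.zeros_like(S)
    return factor * S


def update_component_loadings(
    R_k: np.ndarray, t_r: np.ndarray, lambda_L: float, lambda_G: float
) -> np.ndarray:
    """Closed-form update for one component's loadings within one block.

    ``R_k`` is the block's transposed partial residual (J_k x I), i.e. the
    data with every other component's contribution removed; ``t_r`` the unit
    score vector of the component being refreshed.
    """
    J_k = R_k.shape[0]
    s = soft_threshold(2.0 * (R_k @ t_r), lambda_L)
    factor = _group_factor(float(np.linalg.norm(s)), lambda_G, np.sqrt(J_k))
    if factor == 0.0:
        return np.zeros_like(s)
    return factor * s


def objective(
    data: MultiblockData, model: ComponentModel, penalties: PenaltyConfig
) -> float:
    """Penalized loss: SSE + Lasso term + Group Lasso term (per convention)."""
    X_C, _ = concatenate(data)
    value = float(((X_C - model.reconstruct()) ** 2).sum())
    for name in data.block_names:
        P_k = model.block_loadings(name)
        sqrt_J = np.sqrt(P_k.shape[0])
        value += penalties.lambda_L * float(np.abs(P_k).sum())
        if penalties.method == "block":
            value += penalties.lambda_G * sqrt_J * float(np.linalg.norm(P_k))
        else:
            value += penalties.lambda_G * sqrt_J * float(
                np.linalg.norm(P_k, axis=0).sum()
            )
    return value


def _objective_arrays(
    blocks: Sequence[np.ndarray],
    T: np.ndarray,
    P_blocks: Sequence[np.ndarray],
    lambda_L: float,
    lambda_G: float,
    method: str,
) -> float:
    value = 0.0
    for X_k, P_k in zip(blocks, P_blocks):
        value += float(((X_k - T @ P_k.T) ** 2).sum())
        sqrt_J = np.sqrt(P_k.shape[0])
        value += lambda_L * float(np.abs(P_k).sum())
        if method == "block":
            value += lambda_G * sqrt_J * float(np.linalg.norm(P_k))
        else:
            value += lambda_G * sqrt_J * float(np.linalg.norm(P_k, axis=0).sum())
    return value


def _component_sweep(
    blocks: Sequence[np.ndarray],
    T: np.ndarray,
    P_blocks: list[np.ndarray],
    lambda_L: float,
    lambda_G: float,
) -> None:
    """Gauss-Seidel cycle over blocks then components, in index order.

    The partial residual is refreshed after every component update.  The
    product ``R_k t_r`` is formed without materializing ``R_k``:
    ``R_k t_r = X_k' t_r - P_k (T' t_r) + p_r (t_r' t_r)``.
    """
    R = T.shape[1]
    G = T.T @ T  # = I up to round-off; kept for exact Gauss-Seidel algebra
    for X_k, P_k in zip(blocks, P_blocks):
        B = X_k.T @ T  # J_k x R
        for r in range(R):
            g = B[:, r] - P_k @ G[:, r] + P_k[:, r] * G[r, r]
            s = soft_threshold(2.0 * g, lambda_L)
            factor = _group_factor(
                float(np.linalg.norm(s)), lambda_G, np.sqrt(P_k.shape[0])
            )
            P_k[:, r] = factor * s if factor > 0.0 else 0.0


def _block_sweep(
    blocks: Sequence[np.ndarray],
    T: np.ndarray,
    P_blocks: list[np.ndarray],
    lambda_L: float,
    lambda_G: float,
) -> None:
    for k, X_k in enumerate(blocks):
        P_blocks[k][...] = update_block_loadings(X_k, T, lambda_L, lambda_G)


def _stack(P_blocks: Sequence[np.ndarray]) -> np.ndarray:
    return np.vstack(P_blocks)


def _alternate(
    blocks: Sequence[np.ndarray],
    X_C: np.ndarray,
    P_C0: np.ndarray,
    widths: Sequence[int],
    loadings_step,
    loss_fn,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, np.ndarray, list[float], bool, int]:
    """Generic alternating loop shared by the penalized fitters."""
    edges = np.cumsum([0, *widths])
    P_blocks = [P_C0[edges[k] : edges[k + 1]].copy() for k in range(len(widths))]
    T = update_T(X_C, _stack(P_blocks)) if np.any(P_C0) else np.linalg.svd(
        X_C, full_matrices=False
    )[0][:, : P_C0.shape[1]]
    history: list[float] = []
    converged = False
    n_iter = 0
    prev = np.inf
    for n_iter in range(1, max_iter + 1):
        loadings_step(blocks, T, P_blocks)
        P_C = _stack(P_blocks)
        if np.any(P_C):
            T = update_T(X_C, P_C)
        loss = loss_fn(blocks, T, P_blocks)
        history.append(loss)
        if np.isfinite(prev) and abs(prev - loss) <= tol * max(1.0, abs(prev)):
            converged = True
            break
        prev = loss
    return _stack(P_blocks), T, history, converged, n_iter


def _run_multistart(
    data: MultiblockData,
    R: int,
    loadings_step,
    loss_fn,
    n_starts: int,
    seed: int | None,
    tol: float,
    max_iter: int,
    init_svd: bool,
    init_mask: np.ndarray | None = None,
) -> tuple[ComponentModel, list[float], bool, int, int]:
    X_C, partition = concatenate(data)
    blocks = data.blocks
    widths = data.block_widths
    rng = np.random.default_rng(seed)
    best = None
    for start in range(n_starts):
        if start == 0 and init_svd:
            try:
                P_C0 = fit_sca(data, R).P_C
            except ValueError:
                P_C0 = rng.standard_normal((data.total_width, R))
        else:
            P_C0 = rng.standard_normal((data.total_width, R))
        if init_mask is not None:
            P_C0 = P_C0 * init_mask
        P_C, T, history, converged, n_iter = _alternate(
            blocks, X_C, P_C0, widths, loadings_step, loss_fn, tol, max_iter
        )
        final = history[-1]
        if best is None or final < best[0]:
            best = (final, P_C, T, history, converged, n_iter, start)
    assert best is not None
    _, P_C, T, history, converged, n_iter, start = best
    model = ComponentModel(T=T, P_C=P_C, partition=partition)
    return model, history, converged, n_iter, start


def fit_sparse_sca(
    data: MultiblockData,
    R: int,
    penalties: PenaltyConfig,
    n_starts: int = 20,
    seed: int | None = None,
    tol: float = 1e-9,
    max_iter: int = 10000,
    init_svd: bool = True,
) -> FitResult:
    """Alternating sparse Group Lasso SCA with multi-start.

    Start 0 uses the unpenalized SCA loadings when ``init_svd`` (default);
    all other starts draw i.i.d. standard-normal loadings from ``seed``.
    The lowest-final-loss start wins (ties: lowest start index).
    Non-convergence within ``max_iter`` is flagged, not raised.
    """
    if n_starts < 1:
        raise ValueError("n_starts must be at least 1")
    lam_L, lam_G = penalties.lambda_L, penalties.lambda_G

    if penalties.method == "component":
        def step(blocks, T, P_blocks):
            _component_sweep(blocks, T, P_blocks, lam_L, lam_G)
    else:
        def step(blocks, T, P_blocks):
            _block_sweep(blocks, T, P_blocks, lam_L, lam_G)

    def loss(blocks, T, P_blocks):
        return _objective_arrays(blocks, T, P_blocks, lam_L, lam_G, penalties.method)

    model, history, converged, n_iter, start = _run_multistart(
        data, R, step, loss, n_starts, seed, tol, max_iter, init_svd
    )
    return FitResult(
        model=model,
        loss_history=np.asarray(history),
        converged=converged,
        n_iterations=n_iter,
        start_index=start,
        config={
            "R": R,
            "lambda_L": lam_L,
            "lambda_G": lam_G,
            "method": penalties.method,
            "n_starts": n_starts,
            "seed": seed,
            "tol": tol,
            "max_iter": max_iter,
        },
    )


def fit_structured_sca(
    data: MultiblockData,
    R: int,
    target,
    position: Iterable[int] | None = None,
    lambda_L: float = 0.0,
    n_starts: int = 20,
    seed: int | None = None,
    tol: float = 1e-9,
    max_iter: int = 10000,
    init_svd: bool = True,
) -> FitResult:
    """Penalized SCA with a known K x R common/distinctive structure.

    ``target`` is a K x R binary matrix (or :class:`TargetStructure`): a zero
    cell forces the whole block-component to zero in every iterate.
    ``position`` lists the zero-based component indices estimated with the
    Lasso at ``lambda_L``; the remaining components are estimated by
    unpenalized least squares on their allowed cells.  No Group Lasso is
    involved (the structure is known).
    """
    status = np.asarray(getattr(target, "status", target), dtype=int)
    if status.shape != (data.n_blocks, R):
        raise ValueError(f"target must be {data.n_blocks} x {R}")
    if (status.sum(axis=0) == 0).any():
        raise ValueError("target has an all-zero column (empty component)")
    if lambda_L < 0:
        raise ValueError("lambda_L must be nonnegative")
    position_set = set(range(R)) if position is None else set(position)
    if not position_set <= set(range(R)):
        raise ValueError("position indices must lie in [0, R)")

    widths = data.block_widths

    def step(blocks, T, P_blocks):
        G = T.T @ T
        for k, (X_k, P_k) in enumerate(zip(blocks, P_blocks)):
            B = X_k.T @ T
            for r in range(R):
                if status[k, r] == 0:
                    P_k[:, r] = 0.0
                    continue
                g = B[:, r] - P_k @ G[:, r] + P_k[:, r] * G[r, r]
                if r in position_set and lambda_L > 0:
                    P_k[:, r] = soft_threshold(2.0 * g, lambda_L) / 2.0
                else:
                    P_k[:, r] = g

    def loss(blocks, T, P_blocks):
        value = 0.0
        for X_k, P_k in zip(blocks, P_blocks):
            value += float(((X_k - T @ P_k.T) ** 2).sum())
            for r in position_set:
                value += lambda_L * float(np.abs(P_k[:, r]).sum())
        return value

    edges = np.cumsum([0, *widths])
    init_mask = np.zeros((data.total_width, R))
    for k in range(data.n_blocks):
        init_mask[edges[k] : edges[k + 1]] = status[k]

    model, history, converged, n_iter, start = _run_multistart(
        data, R, step, loss, n_starts, seed, tol, max_iter, init_svd, init_mask
    )
    return FitResult(
        model=model,
        loss_history=np.asarray(history),
        converged=converged,
        n_iterations=n_iter,
        start_index=start,
        config={
            "R": R,
            "lambda_L": lambda_L,
            "position": sorted(position_set),
            "n_starts": n_starts,
            "seed": seed,
            "tol": tol,
            "max_iter": max_iter,
        },
    )
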