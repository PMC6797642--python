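"""Model selection: maximal penalties, cell-wise cross-validation with the
one-standard-error rule, DISCO rotation search and PCA-GCA screening."""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .core import ComponentModel, fit_sca
from .io import MultiblockData, concatenate
from .solvers import (
    FitResult,
    PenaltyConfig,
    fit_sparse_sca,
    fit_structured_sca,
    soft_threshold,
)

__all__ = [
    "TargetStructure",
    "CVResult",
    "PcaGcaReport",
    "max_lambdas",
    "make_cell_folds",
    "cv_sparse_sca",
    "cv_structured_sca",
    "one_se_select",
    "enumerate_structures",
    "rotate_to_target",
    "disco_sca",
    "pca_gca",
    "eigen_screen",
]


@dataclass(frozen=True)
class TargetStructure:
    """K x R binary status matrix: 1 = block may load, 0 = forced zero.

    A column of all ones is a common component; a column with at least one
    zero is distinctive.  All-zero columns are rejected (a component must
    touch at least one block).
    """

    status: np.ndarray

    def __post_init__(self) -> None:
        status = np.asarray(self.status, dtype=int)
        if status.ndim != 2:
            raise ValueError("status must be a K x R matrix")
        if not np.isin(status, (0, 1)).all():
            raise ValueError("status entries must be 0 or 1")
        if status.shape[1] and (status.sum(axis=0) == 0).any():
            raise ValueError("status has an all-zero column")
        object.__setattr__(self, "status", status)

    @property
    def K(self) -> int:
        return self.status.shape[0]

    @property
    def R(self) -> int:
        return self.status.shape[1]

    def is_all_common(self) -> bool:
        return bool((self.status == 1).all())

    def expand(self, widths: Sequence[int]) -> np.ndarray:
        """Variable-level mask of shape (sum(widths), R)."""
        return np.repeat(self.status, list(widths), axis=0)

    def column_multiset(self) -> tuple[tuple[int, ...], ...]:
        return tuple(sorted(map(tuple, self.status.T), reverse=True))

    def to_csv(self, path, block_names: Sequence[str] | None = None) -> None:
        names = block_names or [f"block_{k + 1}" for k in range(self.K)]
        pd.DataFrame(
            self.status,
            index=names,
            columns=[f"comp_{r + 1}" for r in range(self.R)],
        ).to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "TargetStructure":
        return cls(pd.read_csv(path, index_col=0).to_numpy(dtype=int))


@dataclass
class CVResult:
    """Cross-validation summary over a penalty grid."""

    grid: list
    mspe: np.ndarray
    se: np.ndarray
    best_index: int
    selected_index: int
    selected: object
    n_folds: int
    seed: int | None
    region: tuple[float, float] | None = None
    fold_errors: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        grid = self.grid
        if grid and isinstance(grid[0], tuple):
            df = pd.DataFrame(grid, columns=["lambda_L", "lambda_G"])
        else:
            df = pd.DataFrame({"lambda_L": grid})
        df["mspe"] = self.mspe
        df["se"] = self.se
        return df


def max_lambdas(
    data: MultiblockData, R: int, method: Literal["component", "block"] = "component"
) -> tuple[float, float]:
    """Smallest penalty weights that zero the entire loading matrix.

    Evaluated on the unpenalized SCA scores T: the Lasso maximum is
    ``2 max |(X_k' T)_{jr}|`` (the soft threshold then kills every entry);
    the Group Lasso maximum is the largest ``2 ||group||_2 / sqrt(J_k)``
    (the positive-part factor then clamps every group).
    """
    X_C, _ = concatenate(data)
    if not np.any(X_C):
        return 0.0, 0.0
    T = fit_sca(data, R).T
    lam_L = 0.0
    lam_G = 0.0
    for k, name in enumerate(data.block_names):
        A = data.blocks[k].T @ T  # J_k x R
        sqrt_J = np.sqrt(A.shape[0])
        lam_L = max(lam_L, 2.0 * float(np.max(np.abs(A))))
        if method == "block":
            lam_G = max(lam_G, 2.0 * float(np.linalg.norm(A)) / sqrt_J)
        else:
            lam_G = max(
                lam_G, 2.0 * float(np.max(np.linalg.norm(A, axis=0))) / sqrt_J
            )
    return lam_L, lam_G


def make_cell_folds(
    I: int, total_J: int, n_folds: int, seed: int | None
) -> np.ndarray:
    """Random balanced partition of the I x total_J cell grid into folds.

    Returns an integer matrix of fold labels in ``[0, n_folds)``; fold sizes
    differ by at most one.  Reproducible under ``seed``.
    """
    if n_folds < 2:
        raise ValueError("n_folds must be at least 2")
    rng = np.random.default_rng(seed)
    n_cells = I * total_J
    labels = np.empty(n_cells, dtype=int)
    order = rng.permutation(n_cells)
    for f, chunk in enumerate(np.array_split(order, n_folds)):
        labels[chunk] = f
    return labels.reshape(I, total_J)


def one_se_select(
    mspe: Sequence[float],
    se: Sequence[float],
    grid: Sequence,
    mode: Literal["not_higher", "closest"] = "not_higher",
) -> tuple[int, object]:
    """One-standard-error rule on a penalty grid.

    With ``b = argmin mspe`` and ``threshold = mspe[b] + se[b]``:
    ``not_higher`` picks, among points with mspe <= threshold, the one whose
    mspe is closest to the threshold; ``closest`` picks the point with
    ``|mspe - threshold|`` minimal.  Ties break toward the larger penalty.
    Returns ``(index, grid point)``.
    """
    mspe = np.asarray(mspe, dtype=float)
    se = np.asarray(se, dtype=float)
    if not (len(mspe) == len(se) == len(grid)):
        raise ValueError("mspe, se and grid must have equal length")
    b = int(np.argmin(mspe))
    threshold = mspe[b] + se[b]

    def magnitude(i: int) -> float:
        # ties break toward the larger penalty; non-numeric grids fall back
        # to position (grids are conventionally sorted ascending)
        try:
            return float(np.sum(np.atleast_1d(np.asarray(grid[i], dtype=float))))
        except (TypeError, ValueError):
            return float(i)

    if mode == "not_higher":
        candidates = [i for i in range(len(grid)) if mspe[i] <= threshold]
    elif mode == "closest":
        candidates = list(range(len(grid)))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    best_i = min(
        candidates, key=lambda i: (abs(mspe[i] - threshold), -magnitude(i))
    )
    return best_i, grid[best_i]


def _default_grid(lo: float, hi: float, n: int) -> np.ndarray:
    if hi <= lo:
        hi = lo + 1e-8
    return np.linspace(lo, hi, n)


def _cv_errors(
    data: MultiblockData,
    fit_one,
    folds: np.ndarray,
    n_folds: int,
) -> np.ndarray:
    """Fold-level MSPEs for a single penalty setting.

    Held-out cells are replaced by the column mean over retained cells, the
    model is fit on the imputed matrix, and the squared error of the fitted
    low-rank reconstruction is accumulated over the held-out cells.
    """
    X_C, partition = concatenate(data)
    errors = np.empty(n_folds)
    for f in range(n_folds):
        mask = folds == f
        X_train = X_C.copy()
        X_train[mask] = np.nan
        col_means = np.nanmean(X_train, axis=0)
        col_means = np.where(np.isfinite(col_means), col_means, 0.0)
        X_train[mask] = np.take(col_means, np.nonzero(mask)[1])
        train = MultiblockData(
            blocks=[
                X_train[:, start:stop] for start, stop in partition.values()
            ],
            row_ids=list(data.row_ids),
            block_names=list(data.block_names),
            var_names=[list(v) for v in data.var_names],
        )
        model = fit_one(train).model
        resid = X_C - model.reconstruct()
        errors[f] = float((resid[mask] ** 2).mean())
    return errors


def cv_sparse_sca(
    data: MultiblockData,
    R: int,
    lambda_L_grid: Sequence[float] | None = None,
    lambda_G_grid: Sequence[float] | None = None,
    n_folds: int = 10,
    method: Literal["component", "block"] = "component",
    n_starts: int = 1,
    seed: int | None = None,
    max_iter: int = 400,
    se_scaled: bool = False,
    mode: Literal["not_higher", "closest"] = "closest",
) -> CVResult:
    """K-fold cell-wise cross-validation over a (lambda_L, lambda_G) grid.

    Default grids are 20 points from 1e-8 to the respective
    :func:`max_lambdas` value.  One fixed cell partition is drawn per run so
    every grid point is scored on identical folds.
    """
    lam_L_max, lam_G_max = max_lambdas(data, R, method)
    if lambda_L_grid is None:
        lambda_L_grid = _default_grid(1e-8, lam_L_max, 20)
    if lambda_G_grid is None:
        lambda_G_grid = _default_grid(1e-8, lam_G_max, 20)
    if len(lambda_L_grid) == 0 or len(lambda_G_grid) == 0:
        raise ValueError("penalty grids must be non-empty")
    folds = make_cell_folds(data.n_samples, data.total_width, n_folds, seed)
    grid = [(float(l), float(g)) for l in lambda_L_grid for g in lambda_G_grid]
    fold_errors = np.empty((len(grid), n_folds))
    for i, (lam_L, lam_G) in enumerate(grid):
        penalties = PenaltyConfig(lam_L, lam_G, method)

        def fit_one(train):
            return fit_sparse_sca(
                train, R, penalties, n_starts=n_starts, seed=seed,
                max_iter=max_iter, tol=1e-8,
            )

        fold_errors[i] = _cv_errors(data, fit_one, folds, n_folds)
    mspe = fold_errors.mean(axis=1)
    se = fold_errors.std(axis=1, ddof=1)
    if se_scaled:
        se = se / np.sqrt(n_folds)
    best = int(np.argmin(mspe))
    sel_i, sel = one_se_select(mspe, se, grid, mode)
    return CVResult(
        grid=grid, mspe=mspe, se=se, best_index=best,
        selected_index=sel_i, selected=sel, n_folds=n_folds, seed=seed,
        fold_errors=fold_errors,
    )


def cv_structured_sca(
    data: MultiblockData,
    R: int,
    target: TargetStructure,
    position: Iterable[int] | None = None,
    lambda_L_grid: Sequence[float] | None = None,
    n_folds: int = 10,
    n_starts: int = 1,
    seed: int | None = None,
    max_iter: int = 400,
    n_grid: int = 50,
    se_scaled: bool = False,
) -> CVResult:
    """Cross-validate the Lasso weight of the known-structure model.

    The default grid is ``n_grid`` points from 1e-7 to the Lasso maximum.
    ``region`` is the closed interval between the not-higher one-SE choice
    and the closest-mode recommendation.
    """
    if lambda_L_grid is None:
        lam_L_max, _ = max_lambdas(data, R)
        lambda_L_grid = _default_grid(1e-7, lam_L_max, n_grid)
    if len(lambda_L_grid) == 0:
        raise ValueError("penalty grid must be non-empty")
    grid = [float(l) for l in lambda_L_grid]
    folds = make_cell_folds(data.n_samples, data.total_width, n_folds, seed)
    fold_errors = np.empty((len(grid), n_folds))
    for i, lam_L in enumerate(grid):

        def fit_one(train):
            return fit_structured_sca(
                train, R, target, position, lam_L, n_starts=n_starts,
                seed=seed, max_iter=max_iter, tol=1e-8,
            )

        fold_errors[i] = _cv_errors(data, fit_one, folds, n_folds)
    mspe = fold_errors.mean(axis=1)
    se = fold_errors.std(axis=1, ddof=1)
    if se_scaled:
        se = se / np.sqrt(n_folds)
    best = int(np.argmin(mspe))
    lo_i, lo = one_se_select(mspe, se, grid, "not_higher")
    sel_i, sel = one_se_select(mspe, se, grid, "closest")
    region = (min(lo, sel), max(lo, sel))
    return CVResult(
        grid=grid, mspe=mspe, se=se, best_index=best,
        selected_index=sel_i, selected=sel, n_folds=n_folds, seed=seed,
        region=region, fold_errors=fold_errors,
    )


def enumerate_structures(K: int, R: int, cap: int = 100_000) -> list[TargetStructure]:
    """All K x R status matrices up to column permutation.

    Columns range over the nonzero binary K-patterns; candidates are
    multisets of R such patterns (no all-zero column by construction).
    """
    if K < 1 or R < 1:
        raise ValueError("K and R must be positive")
    n_patterns = 2**K - 1
    count = math.comb(n_patterns + R - 1, R)
    if count > cap:
        raise ValueError(
            f"{count} candidate structures exceed the cap of {cap}"
        )
    patterns = sorted(
        (tuple(bits) for bits in itertools.product((0, 1), repeat=K) if any(bits)),
        reverse=True,
    )
    out = []
    for combo in itertools.combinations_with_replacement(patterns, R):
        out.append(TargetStructure(np.array(combo, dtype=int).T))
    return out


def _random_orthonormal(R: int, rng: np.random.Generator) -> np.ndarray:
    Q, Rm = np.linalg.qr(rng.standard_normal((R, R)))
    return Q * np.sign(np.diag(Rm))


def _polish_rotation(
    P_C: np.ndarray, B0: np.ndarray, zero_mask: np.ndarray
) -> tuple[np.ndarray, float]:
    """Quasi-Newton refinement on the rotation group.

    Parameterizes rotations near ``B0`` as ``B0 expm(S)`` with S skew
    (alternating projections converge only linearly, which is too slow for
    exactly-satisfiable masks)."""
    from scipy.linalg import expm
    from scipy.optimize import minimize as _minimize

    R = B0.shape[1]
    tri = np.triu_indices(R, k=1)
    if len(tri[0]) == 0:  # R = 1: only sign flips, nothing to polish
        loss = float(((P_C @ B0) ** 2)[zero_mask].sum())
        return B0, loss

    def build(x):
        S = np.zeros((R, R))
        S[tri] = x
        S -= S.T
        return B0 @ expm(S)

    def fun(x):
        return float(((P_C @ build(x)) ** 2)[zero_mask].sum())

    result = _minimize(
        fun,
        np.zeros(len(tri[0])),
        method="BFGS",
        options={"maxiter": 500, "gtol": 1e-12},
    )
    B = build(result.x)
    return B, fun(result.x)


def rotate_to_target(
    P_C: np.ndarray,
    target: TargetStructure,
    widths: Sequence[int],
    n_restarts: int = 10,
    seed: int = 0,
    tol: float = 1e-9,
    max_iter: int = 1000,
) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormal rotation minimizing the squared loadings in intended-zero
    cells of the variable-level expansion of ``target``.

    Alternating scheme: copy the free cells of the current rotation into a
    partially specified target (zeros elsewhere), then solve the orthogonal
    Procrustes problem toward it.  Identity start plus ``n_restarts`` seeded
    random orthonormal restarts.  Returns ``(rotation, rotated P_C)``.
    """
    P_C = np.asarray(P_C, dtype=float)
    R = P_C.shape[1]
    zero_mask = target.expand(widths) == 0
    if not zero_mask.any():
        return np.eye(R), P_C.copy()
    rng = np.random.default_rng(seed)
    starts = [np.eye(R)] + [_random_orthonormal(R, rng) for _ in range(n_restarts)]
    best_B = np.eye(R)
    best_loss = np.inf
    for B in starts:
        prev = np.inf
        for _ in range(max_iter):
            rotated = P_C @ B
            Y = np.where(zero_mask, 0.0, rotated)
            U, _, Vt = np.linalg.svd(P_C.T @ Y, full_matrices=False)
            B = U @ Vt
            loss = float((((P_C @ B) ** 2)[zero_mask]).sum())
            if abs(prev - loss) <= tol * max(1.0, abs(prev)):
                break
            prev = loss
        B, loss = _polish_rotation(P_C, B, zero_mask)
        if loss < best_loss - 1e-15:
            best_loss = loss
            best_B = B
    return best_B, P_C @ best_B


def _pstr_rotation(
    P_C: np.ndarray,
    zero_mask: np.ndarray,
    max_iter: int = 5000,
    tol: float = 1e-4,
) -> np.ndarray:
    """Majorization search for the partially specified target rotation.

    Minimizes the squared rotated loadings over masked cells, restarting
    from every column-sign reflection of the identity (deterministic).  The
    loose default tolerance mirrors the reference rotation this criterion
    was calibrated with.
    """
    R = P_C.shape[1]
    B1 = P_C.T @ P_C
    alpha = float(np.linalg.eigvalsh(B1).max())
    best_loss, best_B = np.inf, np.eye(R)
    for signs in itertools.product((1.0, -1.0), repeat=R - 1):
        B = np.diag(np.array((1.0, *signs)))
        prev = float(((P_C @ B) ** 2)[zero_mask].sum())
        for _ in range(max_iter):
            Y = np.where(zero_mask, 0.0, P_C @ B)
            F = -2.0 * Y.T @ P_C + 2.0 * B.T @ B1.T - 2.0 * alpha * B.T
            U, _, Vt = np.linalg.svd(-F)
            B = Vt.T @ U.T
            loss = float(((P_C @ B) ** 2)[zero_mask].sum())
            if abs(prev - loss) < tol:
                prev = loss
                break
            prev = loss
        if prev < best_loss:
            best_loss, best_B = prev, B
    return best_B


def _vaf_balance_distance(
    rotated: np.ndarray,
    cand: TargetStructure,
    block_ssq: np.ndarray,
    edges: np.ndarray,
) -> float:
    """Worst-component VAF criterion: a common component should explain a
    similar share in every block, a distinctive one (nearly) nothing in its
    zero blocks.  Shares are relative to the block's rank-R explained sum
    of squares (rotation invariant)."""
    K, R = cand.status.shape
    ratio = np.empty((K, R))
    for k in range(K):
        ratio[k] = (rotated[edges[k] : edges[k + 1]] ** 2).sum(axis=0) / block_ssq[k]
    worst = 0.0
    for r in range(R):
        col = cand.status[:, r]
        if col.all():
            d = max(
                abs(ratio[k, r] - ratio[l, r])
                for k, l in itertools.combinations(range(K), 2)
            )
        else:
            d = max(ratio[k, r] for k in range(K) if col[k] == 0)
        worst = max(worst, d)
    return float(worst)


def disco_sca(
    data: MultiblockData,
    R: int,
    criterion: Literal["vaf_balance", "zero_loading"] = "vaf_balance",
    cap: int = 100_000,
    floor_frac: float = 0.01,
    seed: int = 0,
) -> tuple[TargetStructure, ComponentModel, pd.DataFrame]:
    """DISCO structure search: rotate the SCA loadings toward every candidate
    common/distinctive configuration and keep the best-fitting one.

    ``vaf_balance`` (default) scores each candidate by its worst component:
    for a common component the largest between-block difference in the
    share of explained variance, for a distinctive component the largest
    share left in a block that should be silent.  Components sharing a
    block pattern are first re-oriented to principal axes within their
    subspace.  The all-common structure cannot win under this criterion
    (every rotation of it is equivalent) and it needs ``R >= 2``.

    ``zero_loading`` scores candidates by the mean squared rotated loading
    over intended-zero cells; the all-common structure (empty mask) is only
    selected when every other candidate's criterion exceeds ``floor_frac``
    times the overall mean squared loading.
    """
    model = fit_sca(data, R)
    widths = data.block_widths
    edges = np.cumsum([0, *widths])
    candidates = enumerate_structures(data.n_blocks, R, cap)
    if criterion == "vaf_balance" and R < 2:
        raise ValueError("vaf_balance needs R >= 2; use criterion='zero_loading'")
    block_ssq = np.array(
        [
            (model.P_C[edges[k] : edges[k + 1]] ** 2).sum()
            for k in range(data.n_blocks)
        ]
    )
    rows = []
    rotations = []
    for cand in candidates:
        zero_mask = cand.expand(widths) == 0
        n_zero = int(zero_mask.sum())
        if criterion == "vaf_balance":
            if cand.is_all_common():
                B = np.eye(R)
                rotated = model.P_C.copy()
                crit = np.nan
            else:
                B = _pstr_rotation(model.P_C, zero_mask)
                rotated = model.P_C @ B
                # principal axes within duplicated block patterns
                patterns = [tuple(cand.status[:, r]) for r in range(R)]
                for pat in set(patterns):
                    idx = [r for r, p in enumerate(patterns) if p == pat]
                    if len(idx) > 1:
                        _, _, Vt = np.linalg.svd(rotated[:, idx], full_matrices=False)
                        rotated[:, idx] = rotated[:, idx] @ Vt.T
                        B = B.copy()
                        B[:, idx] = B[:, idx] @ Vt.T
                crit = _vaf_balance_distance(rotated, cand, block_ssq, edges)
        else:
            B, rotated = rotate_to_target(model.P_C, cand, widths, seed=seed)
            crit = (
                float((rotated[zero_mask] ** 2).sum() / n_zero) if n_zero else np.nan
            )
        rows.append(
            {
                "structure": "|".join(
                    "".join(map(str, col)) for col in cand.status.T
                ),
                "n_zero_cells": n_zero,
                "criterion": crit,
            }
        )
        rotations.append((B, rotated))
    table = pd.DataFrame(rows)
    non_common = [i for i, c in enumerate(candidates) if not c.is_all_common()]
    best_i = min(non_common, key=lambda i: table.loc[i, "criterion"])
    if criterion == "zero_loading":
        floor = floor_frac * float((model.P_C**2).mean())
        if table.loc[best_i, "criterion"] > floor and any(
            c.is_all_common() for c in candidates
        ):
            best_i = next(i for i, c in enumerate(candidates) if c.is_all_common())
    B, rotated = rotations[best_i]
    rotated_model = ComponentModel(
        T=model.T @ B, P_C=rotated, partition=model.partition
    )
    return candidates[best_i], rotated_model, table


@dataclass
class PcaGcaReport:
    """Outcome of the PCA-per-block / canonical-correlation screen."""

    eigenvalues: list[np.ndarray]
    per_block_R: list[int]
    pair_correlations: dict[tuple[int, int], np.ndarray]
    pair_common: dict[tuple[int, int], int]
    threshold: float
    implied_structure: TargetStructure | None = None
    implied_R: int | None = None


def eigen_screen(
    data: MultiblockData, block_index: int, max_R: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Descending covariance eigenvalues of one block plus cumulative VAF.

    Eigenvalues are squared singular values of the (preprocessed) block
    divided by ``I - 1``; cumulative proportions are relative to the trace.
    """
    X_k = data.blocks[block_index]
    I = X_k.shape[0]
    if max_R is None:
        max_R = min(X_k.shape)
    if max_R > min(X_k.shape):
        raise ValueError(f"max_R exceeds min(I, J_k) = {min(X_k.shape)}")
    s = np.linalg.svd(X_k, compute_uv=False)
    eig = s**2 / (I - 1)
    cum = np.cumsum(eig) / eig.sum()
    return eig[:max_R], cum[:max_R]


def pca_gca(
    data: MultiblockData,
    per_block_R: Sequence[int],
    threshold: float = 0.7,
) -> PcaGcaReport:
    """Count common components between block pairs via canonical correlations.

    PCA is run per block; the canonical correlations between two blocks'
    orthonormal score matrices are the singular values of ``T_k' T_l``.  A
    correlation at or above ``threshold`` counts as one common component.
    For K = 2 the implied structure/total R are reported; for K > 2 only
    the pairwise counts are given.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    if len(per_block_R) != data.n_blocks:
        raise ValueError("per_block_R must have one entry per block")
    scores = []
    eigenvalues = []
    for k, X_k in enumerate(data.blocks):
        R_k = per_block_R[k]
        if R_k > min(X_k.shape):
            raise ValueError(f"per_block_R[{k}] exceeds min(I, J_k)")
        U, s, _ = np.linalg.svd(X_k, full_matrices=False)
        scores.append(U[:, :R_k])
        eigenvalues.append(s**2 / (X_k.shape[0] - 1))
    pair_correlations = {}
    pair_common = {}
    for k, l in itertools.combinations(range(data.n_blocks), 2):
        rho = np.clip(np.linalg.svd(scores[k].T @ scores[l], compute_uv=False), 0, 1)
        pair_correlations[(k, l)] = rho
        pair_common[(k, l)] = int((rho >= threshold).sum())
    implied_structure = None
    implied_R = None
    if data.n_blocks == 2:
        c = pair_common[(0, 1)]
        R1, R2 = per_block_R
        implied_R = R1 + R2 - c
        cols = (
            [(1, 1)] * c + [(1, 0)] * (R1 - c) + [(0, 1)] * (R2 - c)
        )
        implied_structure = TargetStructure(np.array(cols, dtype=int).T)
    return PcaGcaReport(
        eigenvalues=eigenvalues,
        per_block_R=list(per_block_R),
        pair_correlations=pair_correlations,
        pair_common=pair_common,
        threshold=threshold,
        implied_structure=implied_structure,
        implied_R=implied_R,
    )
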