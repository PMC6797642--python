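"""Synthetic multiblock data with known score/loading ground truth.

Generates data from the same generative structure the estimators assume: an
orthonormal score matrix, block-wise loadings with designated zero blocks
(distinctive components) and optional within-component sparsity, plus
Gaussian noise at an exactly controlled proportion of total variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import MultiblockData, PreprocessConfig, pre_process
from .postprocess import match_components
from .selection import TargetStructure

__all__ = ["SimulationDesign", "simulate_multiblock", "recovery_report", "delete_cells"]


@dataclass(frozen=True)
class SimulationDesign:
    """Recipe for one synthetic multiblock dataset.

    ``within_sparsity`` is the proportion of additional zero loadings inside
    every allowed block-component cell group; ``noise_proportion`` the exact
    fraction of total sum of squares due to noise.
    """

    I: int
    J: tuple[int, ...]
    R: int
    structure: TargetStructure
    within_sparsity: float = 0.0
    noise_proportion: float = 0.0
    balance_blocks: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.within_sparsity < 1:
            raise ValueError("within_sparsity must be in [0, 1)")
        if not 0 <= self.noise_proportion < 1:
            raise ValueError("noise_proportion must be in [0, 1)")
        if self.structure.status.shape != (len(self.J), self.R):
            raise ValueError("structure must be K x R")
        if self.I <= self.R:
            raise ValueError("I must exceed R")


def _centered_orthonormal(I: int, R: int, rng: np.random.Generator) -> np.ndarray:
    """Orthonormal I x R matrix whose columns are also mean-centered."""
    G = rng.standard_normal((I, R))
    G -= G.mean(axis=0)
    Q, Rm = np.linalg.qr(G)
    return Q * np.sign(np.diag(Rm))


def simulate_multiblock(
    design: SimulationDesign,
    preprocess: bool = True,
) -> tuple[MultiblockData, np.ndarray, np.ndarray]:
    """Draw one dataset; returns ``(preprocessed data, true T, true P_C)``.

    The score matrix is orthonormal with centered columns, so the noiseless
    signal survives column centering unchanged.  The returned true loadings
    are expressed on the post-preprocessing scale (column rescaling of the
    data rescales the corresponding loading rows), so zero patterns and
    congruences can be compared directly against fitted models.
    """
    rng = np.random.default_rng(design.seed)
    K = len(design.J)
    total_J = sum(design.J)
    T = _centered_orthonormal(design.I, design.R, rng)
    P_C = rng.standard_normal((total_J, design.R))
    mask = design.structure.expand(design.J).astype(float)
    edges = np.cumsum([0, *design.J])
    for k in range(K):
        J_k = design.J[k]
        n_zero = int(np.floor(design.within_sparsity * J_k))
        if n_zero >= J_k:
            raise ValueError(
                f"within_sparsity would empty block {k} (J_k={J_k})"
            )
        for r in range(design.R):
            if design.structure.status[k, r] == 0:
                continue
            if n_zero:
                idx = rng.choice(J_k, size=n_zero, replace=False)
                mask[edges[k] + idx, r] = 0.0
            if not mask[edges[k] : edges[k + 1], r].any():
                raise ValueError("within_sparsity emptied an allowed cell group")
    P_C *= mask
    if design.balance_blocks:
        # normalize every nonzero block-component section to unit norm so a
        # common component explains comparable shares in all its blocks
        for k in range(K):
            seg = P_C[edges[k] : edges[k + 1]]
            norms = np.linalg.norm(seg, axis=0)
            nz = norms > 0
            seg[:, nz] /= norms[nz]
    signal = T @ P_C.T
    if design.noise_proportion > 0:
        E0 = rng.standard_normal(signal.shape)
        # scale c solves ||cE||^2 / ||S + cE||^2 = nu exactly
        nu = design.noise_proportion
        a = float((E0**2).sum()) * (1 - nu)
        b = -2 * nu * float((signal * E0).sum())
        c_term = -nu * float((signal**2).sum())
        scale = (-b + np.sqrt(b**2 - 4 * a * c_term)) / (2 * a)
        X = signal + scale * E0
    else:
        X = signal.copy()
    raw = MultiblockData(
        blocks=[X[:, edges[k] : edges[k + 1]].copy() for k in range(K)],
        row_ids=[f"s{i + 1}" for i in range(design.I)],
        block_names=[f"block_{k + 1}" for k in range(K)],
        var_names=[
            [f"b{k + 1}v{j + 1}" for j in range(design.J[k])] for k in range(K)
        ],
    )
    if not preprocess:
        return raw, T, P_C
    data = pre_process(raw, PreprocessConfig())
    # express the true loadings on the preprocessed column scale
    X_centered = X - X.mean(axis=0)
    col_ss = np.sqrt((X_centered**2).sum(axis=0))
    col_ss[col_ss < 1e-12] = 1.0
    P_true = P_C / col_ss[:, None]
    return data, T, P_true


def recovery_report(
    P_true: np.ndarray,
    P_est: np.ndarray,
    widths: tuple[int, ...],
) -> dict[str, float]:
    """Score an estimated loading matrix against the generative truth.

    After permutation/sign matching reports: the proportion of
    block-component zero/nonzero statuses recovered, the proportion of cells
    whose zero/nonzero status is recovered, and the mean Tucker congruence
    of matched columns.
    """
    P_true = np.asarray(P_true, dtype=float)
    P_est = np.asarray(P_est, dtype=float)
    if P_true.shape != P_est.shape:
        raise ValueError("shapes must match")
    perm, signs, congruences = match_components(P_est, P_true)
    aligned = P_est[:, perm] * signs
    edges = np.cumsum([0, *widths])
    K, R = len(widths), P_true.shape[1]
    status_true = np.zeros((K, R), dtype=bool)
    status_est = np.zeros((K, R), dtype=bool)
    for k in range(K):
        status_true[k] = np.any(P_true[edges[k] : edges[k + 1]] != 0, axis=0)
        status_est[k] = np.any(aligned[edges[k] : edges[k + 1]] != 0, axis=0)
    return {
        "structure_accuracy": float((status_true == status_est).mean()),
        "cell_accuracy": float(((P_true != 0) == (aligned != 0)).mean()),
        "mean_congruence": float(congruences.mean()),
    }


def delete_cells(
    data: MultiblockData, fraction: float, seed: int = 0
) -> MultiblockData:
    """Punch uniform random NaN holes (for exercising imputation)."""
    if not 0 <= fraction < 1:
        raise ValueError("fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    out = data.copy()
    for idx, X in enumerate(out.blocks):
        holes = rng.random(X.shape) < fraction
        X = X.copy()
        X[holes] = np.nan
        out.blocks[idx] = X
    return out
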