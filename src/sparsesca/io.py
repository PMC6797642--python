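"""Reading, validation, pre-processing and concatenation of multiblock data.

A *multiblock* dataset is a collection of K numeric matrices that share the
same I rows (samples) but have block-specific variables.  All downstream
estimators in this package expect blocks that have been column-centered and
scaled, which is what :func:`pre_process` produces.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MultiblockData",
    "PreprocessConfig",
    "AlignmentError",
    "BlockParseError",
    "read_blocks",
    "read_wide_table",
    "impute_missing",
    "pre_process",
    "concatenate",
    "split",
    "write_blocks",
]


class AlignmentError(ValueError):
    """Raised when the per-block sample ID sets cannot be aligned."""


class BlockParseError(ValueError):
    """Raised when a block file contains cells that cannot be parsed."""


@dataclass
class MultiblockData:
    """K numeric blocks over an identical, identically ordered row set.

    Parameters
    ----------
    blocks
        List of K arrays, each of shape ``(I, J_k)``.  Missing entries are
        encoded as NaN.
    row_ids
        The I sample identifiers, shared by every block.
    block_names
        K block labels.
    var_names
        Per-block lists of variable names (unique within a block).
    """

    blocks: list[np.ndarray]
    row_ids: list[str]
    block_names: list[str]
    var_names: list[list[str]]

    def __post_init__(self) -> None:
        self.blocks = [np.asarray(b, dtype=float) for b in self.blocks]
        if not self.blocks:
            raise ValueError("at least one block is required")
        if len(self.blocks) != len(self.block_names) or len(self.blocks) != len(
            self.var_names
        ):
            raise ValueError("blocks, block_names and var_names must have equal length")
        n_rows = len(self.row_ids)
        for name, block, names in zip(self.block_names, self.blocks, self.var_names):
            if block.ndim != 2:
                raise ValueError(f"block {name!r} is not a matrix")
            if block.shape[0] != n_rows:
                raise ValueError(
                    f"block {name!r} has {block.shape[0]} rows, expected {n_rows}"
                )
            if block.shape[1] < 1:
                raise ValueError(f"block {name!r} has no variables")
            if block.shape[1] != len(names):
                raise ValueError(f"block {name!r}: variable-name count mismatch")
            if len(set(names)) != len(names):
                raise ValueError(f"block {name!r}: duplicate variable names")

    # -- basic geometry ---------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.row_ids)

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    @property
    def block_widths(self) -> tuple[int, ...]:
        return tuple(b.shape[1] for b in self.blocks)

    @property
    def total_width(self) -> int:
        return sum(self.block_widths)

    @property
    def partition(self) -> dict[str, tuple[int, int]]:
        """Map block name -> ``(start, stop)`` column range in the concatenation."""
        out: dict[str, tuple[int, int]] = {}
        start = 0
        for name, j in zip(self.block_names, self.block_widths):
            out[name] = (start, start + j)
            start += j
        return out

    def has_missing(self) -> bool:
        return any(np.isnan(b).any() for b in self.blocks)

    def copy(self) -> "MultiblockData":
        return MultiblockData(
            [b.copy() for b in self.blocks],
            list(self.row_ids),
            list(self.block_names),
            [list(v) for v in self.var_names],
        )


@dataclass(frozen=True)
class PreprocessConfig:
    """Options controlling :func:`pre_process`.

    ``scale_mode='norm_one'`` scales every column so its sum of squares is 1
    (hence a block's squared Frobenius norm equals its variable count);
    ``'unit_variance'`` divides by the sample standard deviation instead.
    ``block_weight`` additionally multiplies block k by ``1/sqrt(J_k)``.
    """

    center: bool = True
    scale_mode: Literal["norm_one", "unit_variance", "none"] = "norm_one"
    block_weight: bool = False
    impute_method: Literal["column_mean", "iterative_svd"] = "column_mean"
    impute_seed: int = 0


def read_blocks(
    paths: Sequence[str],
    delimiter: str = ",",
    block_names: Sequence[str] | None = None,
) -> MultiblockData:
    """Read one delimited file per block and align rows by sample ID.

    Every file must have a header row of variable names and a leading
    sample-ID column.  All files must carry the same ID *set*; rows are
    re-ordered to the first file's ID order.  Empty cells become NaN.
    """
    if block_names is None:
        import os

        block_names = [
            os.path.splitext(os.path.basename(str(p)))[0] for p in paths
        ]
    frames: list[pd.DataFrame] = []
    for path in paths:
        try:
            df = pd.read_csv(
                path, sep=delimiter, index_col=0, float_precision="round_trip"
            )
        except Exception as exc:  # pragma: no cover - passthrough context
            raise BlockParseError(f"{path}: {exc}") from exc
        df.index = df.index.astype(str)
        if df.index.duplicated().any():
            dups = df.index[df.index.duplicated()].tolist()
            raise BlockParseError(f"{path}: duplicate sample IDs {dups}")
        for col in df.columns:
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                row = df.index[bad.to_numpy().nonzero()[0][0]]
                raise BlockParseError(
                    f"{path}: non-numeric value in column {col!r}, row {row!r}"
                )
            df[col] = coerced
        frames.append(df)

    ref_ids = list(frames[0].index)
    ref_set = set(ref_ids)
    for path, df in zip(paths[1:], frames[1:]):
        ids = set(df.index)
        if ids != ref_set:
            missing = sorted(ref_set - ids)
            extra = sorted(ids - ref_set)
            raise AlignmentError(
                f"{path}: sample IDs do not match the first block "
                f"(absent here: {missing}; unknown here: {extra})"
            )
    aligned = [df.loc[ref_ids] for df in frames]
    return MultiblockData(
        blocks=[df.to_numpy(dtype=float) for df in aligned],
        row_ids=ref_ids,
        block_names=list(block_names),
        var_names=[list(df.columns) for df in aligned],
    )


def read_wide_table(
    path: str,
    block_spec: dict[str, Sequence[str]],
    delimiter: str = ",",
) -> MultiblockData:
    """Read one wide table and split its columns into blocks.

    ``block_spec`` maps block names to lists of column names (a parsed JSON
    object works directly).  Column order within a block follows the spec,
    not the file.
    """
    try:
        df = pd.read_csv(
            path, sep=delimiter, index_col=0, float_precision="round_trip"
        )
    except Exception as exc:  # pragma: no cover
        raise BlockParseError(f"{path}: {exc}") from exc
    df.index = df.index.astype(str)
    blocks = []
    var_names = []
    for name, cols in block_spec.items():
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise BlockParseError(f"{path}: unknown column(s) {missing} for block {name!r}")
        sub = df[list(cols)].apply(pd.to_numeric, errors="coerce")
        bad = sub.isna() & df[list(cols)].notna()
        if bad.to_numpy().any():
            raise BlockParseError(f"{path}: non-numeric value in block {name!r}")
        blocks.append(sub.to_numpy(dtype=float))
        var_names.append(list(cols))
    return MultiblockData(
        blocks=blocks,
        row_ids=list(df.index),
        block_names=list(block_spec),
        var_names=var_names,
    )


def _impute_column_mean(X: np.ndarray) -> np.ndarray:
    X = X.copy()
    mask = np.isnan(X)
    if not mask.any():
        return X
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        means = np.nanmean(X, axis=0)
    X[mask] = np.take(means, np.nonzero(mask)[1])
    return X


def _impute_iterative_svd(
    X: np.ndarray, rank: int, tol: float = 1e-8, max_iter: int = 500
) -> np.ndarray:
    """EM-style low-rank completion: fill, truncated SVD, refill, repeat."""
    mask = np.isnan(X)
    if not mask.any():
        return X.copy()
    filled = _impute_column_mean(X)
    for _ in range(max_iter):
        U, s, Vt = np.linalg.svd(filled, full_matrices=False)
        recon = (U[:, :rank] * s[:rank]) @ Vt[:rank]
        change = np.max(np.abs(recon[mask] - filled[mask]))
        filled[mask] = recon[mask]
        if change < tol:
            break
    return filled


def impute_missing(
    data: MultiblockData,
    method: Literal["column_mean", "iterative_svd"] = "column_mean",
    seed: int = 0,
    rank: int = 2,
) -> MultiblockData:
    """Replace NaN entries block by block; observed cells are never touched.

    ``column_mean`` uses the mean of the observed entries of the column.
    ``iterative_svd`` alternates a rank-``rank`` truncated SVD with
    re-imputation of the missing cells until the imputed values stabilise
    (tolerance 1e-8, at most 500 sweeps).  Both are deterministic; ``seed``
    is accepted for interface stability only.
    """
    del seed
    out = data.copy()
    for idx, (name, X) in enumerate(zip(out.block_names, out.blocks)):
        fully_missing = np.isnan(X).all(axis=0)
        if fully_missing.any():
            cols = [out.var_names[idx][j] for j in np.nonzero(fully_missing)[0]]
            raise ValueError(f"block {name!r}: fully-missing column(s) {cols}")
        if method == "column_mean":
            out.blocks[idx] = _impute_column_mean(X)
        elif method == "iterative_svd":
            r = min(rank, min(X.shape))
            out.blocks[idx] = _impute_iterative_svd(X, r)
        else:
            raise ValueError(f"unknown imputation method {method!r}")
    return out


def pre_process(
    data: MultiblockData, config: PreprocessConfig | None = None
) -> MultiblockData:
    """Center and scale every column; optionally weight blocks by 1/sqrt(J_k).

    Requires complete data (see :func:`impute_missing`).  Constant columns
    scale to all-zero with a warning instead of raising.
    """
    config = config or PreprocessConfig()
    if data.has_missing():
        raise ValueError("data contain missing entries; run impute_missing first")
    out = data.copy()
    for idx, (name, X) in enumerate(zip(out.block_names, out.blocks)):
        X = X.copy()
        if config.center:
            X -= X.mean(axis=0)
        if config.scale_mode != "none":
            centered = X - X.mean(axis=0)
            if config.scale_mode == "norm_one":
                denom = np.sqrt((centered**2).sum(axis=0))
            else:  # unit_variance
                denom = np.sqrt((centered**2).sum(axis=0) / (X.shape[0] - 1))
            constant = denom < 1e-12
            if constant.any():
                cols = [out.var_names[idx][j] for j in np.nonzero(constant)[0]]
                warnings.warn(
                    f"block {name!r}: constant column(s) {cols} scaled to zero",
                    stacklevel=2,
                )
            safe = np.where(constant, 1.0, denom)
            X = X / safe
            X[:, constant] = 0.0
        if config.block_weight:
            X = X / np.sqrt(X.shape[1])
        out.blocks[idx] = X
    return out


def concatenate(data: MultiblockData) -> tuple[np.ndarray, dict[str, tuple[int, int]]]:
    """Column-concatenate the blocks; returns ``(X_C, partition)``."""
    return np.hstack(data.blocks), data.partition


def split(
    X_C: np.ndarray, partition: dict[str, tuple[int, int]]
) -> list[np.ndarray]:
    """Inverse of :func:`concatenate` (block order = partition order)."""
    return [X_C[:, start:stop] for start, stop in partition.values()]


def write_blocks(data: MultiblockData, paths: Sequence[str], delimiter: str = ",") -> None:
    """Write each block back to a delimited file with full float precision."""
    for path, name, X, names in zip(
        paths, data.block_names, data.blocks, data.var_names
    ):
        df = pd.DataFrame(X, index=pd.Index(data.row_ids, name="sample_id"), columns=names)
        df.to_csv(path, sep=delimiter, float_format="%.17g")
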