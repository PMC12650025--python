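"""Multi-source feature fusion: z-scored concatenation of the microstate
block and the statistical block.

The fused vector is ``[x_micro, x_stat]`` (microstate block first), each
dimension standardised with mean/SD fitted on the *training* vectors only
— test-fold transforms reuse training statistics, so no information leaks
across folds.  Dimensions that are constant on the training data carry no
information and would divide by zero; they are flagged and dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["NormalizationStats", "FusedVector", "fit_normalizer", "fuse", "fuse_matrix"]


@dataclass
class NormalizationStats:
    mean: np.ndarray
    sd: np.ndarray                 # population SD (ddof=0)
    constant_mask: np.ndarray      # True where the training dimension was constant

    @property
    def n_dims(self) -> int:
        return len(self.mean)


@dataclass
class FusedVector:
    values: np.ndarray             # (n_kept,) or (n_rows, n_kept)
    names: list[str]
    block_index: dict[str, tuple[int, int]]   # block -> [start, stop) in the kept vector


def fit_normalizer(training_vectors: np.ndarray, tol: float = 1e-12) -> NormalizationStats:
    """Per-dimension mean/SD from training rows; constant dims flagged."""
    X = np.atleast_2d(np.asarray(training_vectors, dtype=float))
    if X.shape[0] < 2:
        raise ValueError("need at least 2 training vectors to fit a normalizer")
    if not np.isfinite(X).all():
        raise ValueError("non-finite training vectors")
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    constant = sd <= tol
    return NormalizationStats(mean=mean, sd=np.where(constant, 1.0, sd), constant_mask=constant)


def fuse(
    micro_values: np.ndarray,
    stat_values: np.ndarray,
    stats: NormalizationStats,
    micro_names: list[str] | None = None,
    stat_names: list[str] | None = None,
) -> FusedVector:
    """Concatenate (micro first), z-score with fitted stats, drop constant dims."""
    micro_values = np.atleast_2d(np.asarray(micro_values, dtype=float))
    stat_values = np.atleast_2d(np.asarray(stat_values, dtype=float))
    n_micro = micro_values.shape[1]
    n_stat = stat_values.shape[1]
    X = np.concatenate([micro_values, stat_values], axis=1)
    if X.shape[1] != stats.n_dims:
        raise ValueError(
            f"dimension mismatch: {X.shape[1]} vs fitted {stats.n_dims}"
        )
    if not np.isfinite(X).all():
        raise ValueError("non-finite feature values")
    Z = (X - stats.mean) / stats.sd
    keep = ~stats.constant_mask
    names = (micro_names or [f"micro_{i}" for i in range(n_micro)]) + (
        stat_names or [f"stat_{i}" for i in range(n_stat)]
    )
    kept_names = [n for n, k in zip(names, keep) if k]
    n_micro_kept = int(keep[:n_micro].sum())
    n_kept = int(keep.sum())
    block_index = {"micro": (0, n_micro_kept), "stat": (n_micro_kept, n_kept)}
    values = Z[:, keep]
    if values.shape[0] == 1:
        values = values[0]
    return FusedVector(values=values, names=kept_names, block_index=block_index)


def fuse_matrix(
    micro_matrix: np.ndarray,
    stat_matrix: np.ndarray,
    stats: NormalizationStats,
    **kw,
) -> FusedVector:
    """Row-wise :func:`fuse` over matched (micro, stat) matrices."""
    return fuse(micro_matrix, stat_matrix, stats, **kw)
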