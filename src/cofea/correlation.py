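"""Streaming per-peak summaries of inter-peak correlation coefficients.

The p x p correlation matrix is never materialized: peaks are processed in
row blocks, each block contributing one block-by-all slab computed as a
matrix product of pre-standardized rows. For every peak j the self term
(c_jj = 1 for well-defined rows) is removed analytically, yielding

    mean_j        = (1 / (p - 1)) * sum_{k != j} c_jk
    mean_square_j = (1 / (p - 1)) * sum_{k != j} c_jk^2

Because each block computes full rows of the coefficient matrix, the result
is independent of the chunk size and worker count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from joblib import Parallel, delayed
from scipy.stats import rankdata

from .preprocessing import PeakEmbedding
from .types import ValidationError

CORR_METHODS = ("pcc", "spcc", "csc")


@dataclass
class CorrelationSummary:
    """Per-peak mean and mean-square of the p-1 inter-peak coefficients."""

    mean: np.ndarray
    mean_square: np.ndarray
    method: str
    n_peaks: int
    degenerate: np.ndarray  # rows with zero variance (pcc/spcc) or zero norm (csc)

    def validate(self) -> None:
        if self.mean.min() < -1 - 1e-9 or self.mean.max() > 1 + 1e-9:
            raise ValidationError("mean correlation outside [-1, 1]")
        if self.mean_square.min() < -1e-9 or self.mean_square.max() > 1 + 1e-9:
            raise ValidationError("mean-square correlation outside [0, 1]")


def _standardize_rows(P: np.ndarray, method: str) -> tuple[np.ndarray, np.ndarray]:
    """Map rows to unit vectors whose dot products are the chosen coefficients.

    Degenerate rows (zero variance for pcc/spcc, zero norm for csc) become
    zero vectors, so they contribute coefficient 0 to every pair.
    """
    V = np.array(P, dtype=np.float64)
    if method == "spcc":
        V = np.apply_along_axis(rankdata, 1, V)  # average ranks for ties
    if method in ("pcc", "spcc"):
        V = V - V.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(V, axis=1)
    degenerate = norms == 0
    safe = np.where(degenerate, 1.0, norms)
    V /= safe[:, np.newaxis]
    V[degenerate] = 0.0
    return V, degenerate


def _block_sums(V: np.ndarray, start: int, stop: int) -> tuple[np.ndarray, np.ndarray]:
    slab = V[start:stop] @ V.T  # (block, p) coefficient slab
    self_term = np.einsum("ij,ij->i", V[start:stop], V[start:stop])  # 1 or 0
    sums = slab.sum(axis=1) - self_term
    sums_sq = np.einsum("ij,ij->i", slab, slab) - self_term  # self^2 == self
    return sums, sums_sq


def correlation_summary(
    pe: PeakEmbedding,
    method: str = "pcc",
    chunk_size: int = 1000,
    n_workers: int = 1,
) -> CorrelationSummary:
    """Compute mean/mean-square inter-peak correlation vectors blockwise."""
    if method not in CORR_METHODS:
        raise ValidationError(f"unknown correlation method {method!r}; use {CORR_METHODS}")
    P = np.asarray(pe.values, dtype=np.float64)
    p, q = P.shape
    if p < 2:
        raise ValidationError("need at least 2 peaks")
    if q < 2:
        raise ValidationError(
            f"embedding has q={q} components; correlation over a single "
            "component is degenerate (need q >= 2)"
        )
    if chunk_size < 1:
        raise ValidationError("chunk_size must be >= 1")
    V, degenerate = _standardize_rows(P, method)
    starts = list(range(0, p, chunk_size))
    blocks = [(s, min(s + chunk_size, p)) for s in starts]
    if n_workers > 1 and len(blocks) > 1:
        results = Parallel(n_jobs=n_workers, backend="threading")(
            delayed(_block_sums)(V, s, e) for s, e in blocks
        )
    else:
        results = [_block_sums(V, s, e) for s, e in blocks]
    sums = np.concatenate([r[0] for r in results])
    sums_sq = np.concatenate([r[1] for r in results])
    mean = sums / (p - 1)
    mean_square = sums_sq / (p - 1)
    cs = CorrelationSummary(
        mean=np.clip(mean, -1.0, 1.0),
        mean_square=np.clip(mean_square, 0.0, 1.0),
        method=method,
        n_peaks=p,
        degenerate=degenerate,
    )
    cs.validate()
    return cs


def pairwise_correlation(row_a: np.ndarray, row_b: np.ndarray, method: str = "pcc") -> float:
    """Coefficient between two embedding rows; 0 for degenerate inputs."""
    a = np.asarray(row_a, dtype=np.float64)
    b = np.asarray(row_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError(f"length mismatch: {a.shape} vs {b.shape}")
    if a.size < 2:
        raise ValidationError("vectors must have length >= 2")
    if method not in CORR_METHODS:
        raise ValidationError(f"unknown correlation method {method!r}")
    if method == "spcc":
        a, b = rankdata(a), rankdata(b)
    if method in ("pcc", "spcc"):
        a = a - a.mean()
        b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(a @ b / (na * nb))
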