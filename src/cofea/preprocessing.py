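"""Stepwise preprocessing: prevalence filter, TF-IDF variants, cell-wise PCA.

The default transform is the Signac-style variant

    x'_ij = log(1 + (x_ij / colsum_j) * (n / rowsum_i) * scale_factor)

with natural logarithm. ``origin`` multiplies the per-cell term frequency by
``log(1 + n / rownnz_i)`` without the final log; ``scopen`` is the Signac form
with the inverse document frequency computed on binarized counts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from sklearn.decomposition import PCA

from .types import CountMatrix, ValidationError

logger = logging.getLogger(__name__)

TFIDF_VARIANTS = ("signac", "origin", "scopen")

# above this many matrix entries exact SVD becomes too slow / memory hungry
_EXACT_SVD_MAX_ENTRIES = 10_000_000


@dataclass
class TransformedMatrix:
    """Real-valued peak-by-cell matrix produced by a TF-IDF variant."""

    values: sp.csr_matrix
    variant: str

    @property
    def p(self) -> int:
        return self.values.shape[0]

    @property
    def n(self) -> int:
        return self.values.shape[1]


@dataclass
class PeakEmbedding:
    """Peak-by-component coordinates from cell-wise PCA (peaks are observations)."""

    values: np.ndarray
    n_components: int
    explained_variance: np.ndarray

    @property
    def p(self) -> int:
        return self.values.shape[0]

    @property
    def q(self) -> int:
        return self.values.shape[1]


def filter_by_prevalence(
    cm: CountMatrix, min_cell_fraction: float = 0.01
) -> tuple[CountMatrix, np.ndarray]:
    """Keep peaks detected (count >= 1) in at least ``min_cell_fraction`` of cells.

    The threshold is inclusive: a peak whose detected fraction equals the
    threshold is kept. Returns the filtered matrix and the original row
    indices of the kept peaks, in original order.
    """
    if not 0 <= min_cell_fraction <= 1:
        raise ValidationError(f"min_cell_fraction={min_cell_fraction} outside [0, 1]")
    nnz_per_peak = cm.values.getnnz(axis=1)
    frac = nnz_per_peak / cm.n
    kept = np.flatnonzero(frac >= min_cell_fraction)
    if kept.size < 2:
        raise ValidationError(
            f"prevalence filter at {min_cell_fraction} leaves {kept.size} peaks; "
            "lower the threshold"
        )
    filtered = CountMatrix(
        values=cm.values[kept],
        peaks=[cm.peaks[i] for i in kept],
        barcodes=list(cm.barcodes),
        labels=cm.labels,
    )
    return filtered, kept


def tfidf_transform(
    cm: CountMatrix,
    variant: str = "signac",
    scale_factor: float = 1e4,
    strict: bool = True,
) -> TransformedMatrix:
    """Apply one of the three TF-IDF variants to the count matrix.

    With ``strict=True`` an all-zero cell (column) or all-zero peak (row) is an
    error; with ``strict=False`` such columns/rows map to zeros (used when a
    peak subset leaves some cells empty during evaluation).
    """
    if variant not in TFIDF_VARIANTS:
        raise ValidationError(f"unknown TF-IDF variant {variant!r}; use {TFIDF_VARIANTS}")
    X = cm.values.tocsr().astype(np.float64)
    colsum = np.asarray(X.sum(axis=0)).ravel()
    rowsum = np.asarray(X.sum(axis=1)).ravel()
    rownnz = X.getnnz(axis=1).astype(np.float64)
    if strict:
        zero_cols = np.flatnonzero(colsum == 0)
        if zero_cols.size:
            raise ValidationError(
                f"cell column {zero_cols[0]} has zero total count; "
                "run filter_by_prevalence / remove empty cells first"
            )
        zero_rows = np.flatnonzero(rowsum == 0)
        if zero_rows.size:
            raise ValidationError(
                f"peak row {zero_rows[0]} has zero total count; "
                "run filter_by_prevalence first"
            )
    n = cm.n
    with np.errstate(divide="ignore", invalid="ignore"):
        inv_colsum = np.where(colsum > 0, 1.0 / colsum, 0.0)
        if variant == "signac":
            idf = np.where(rowsum > 0, n / rowsum, 0.0)
        elif variant == "scopen":
            idf = np.where(rownnz > 0, n / rownnz, 0.0)
        else:  # origin
            idf = np.log1p(np.where(rownnz > 0, n / rownnz, 0.0))
    tf = X.multiply(inv_colsum[np.newaxis, :])  # x_ij / colsum_j
    out = sp.csr_matrix(tf.multiply(idf[:, np.newaxis]))
    if variant in ("signac", "scopen"):
        out = out * scale_factor
        out.data = np.log1p(out.data)
    return TransformedMatrix(values=out, variant=variant)


def pca_peak_embedding(
    tm: TransformedMatrix, n_components: int = 100, seed: int = 0
) -> PeakEmbedding:
    """Cell-wise PCA: peaks are observations, cells are (centered) variables.

    Components are sign-fixed so each loading vector's largest-magnitude entry
    is positive, making the embedding reproducible up to floating point under
    cell permutation.
    """
    if n_components < 2:
        raise ValidationError("n_components must be >= 2")
    p, n = tm.values.shape
    max_q = min(p, n) - 1
    q = n_components
    if q > max_q:
        logger.warning("n_components=%d clamped to %d (= min(p, n) - 1)", q, max_q)
        q = max_q
    X = np.asarray(tm.values.todense(), dtype=np.float64)
    if np.allclose(X, X[0:1, :]):
        raise ValidationError("transformed matrix is constant; PCA undefined")
    solver = "full" if p * n <= _EXACT_SVD_MAX_ENTRIES else "randomized"
    pca = PCA(n_components=q, svd_solver=solver, random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        coords = pca.fit_transform(X)
    # deterministic sign: largest-|.| loading entry of each component positive
    for j in range(q):
        load = pca.components_[j]
        i = int(np.argmax(np.abs(load)))
        if load[i] < 0:
            coords[:, j] *= -1.0
    return PeakEmbedding(
        values=coords,
        n_components=q,
        explained_variance=pca.explained_variance_.copy(),
    )
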