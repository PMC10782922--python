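"""Iterative LOWESS scoring of mean-square vs mean correlation, and the
end-to-end selection pipeline.

The background trend of (mean, mean-square) pairs is fitted with LOWESS
three times; after each fit, residuals are modelled with a normal
distribution and points in the extreme quantile tails are dropped from the
next fit. Every peak is finally scored by its absolute residual from the
last-fitted curve.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm
from statsmodels.nonparametric.smoothers_lowess import lowess

from .correlation import CorrelationSummary, correlation_summary
from .preprocessing import (
    filter_by_prevalence,
    pca_peak_embedding,
    tfidf_transform,
)
from .types import CountMatrix, ScoreTable, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class LowessFit:
    fitted_x: np.ndarray  # sorted unique m values of the final fit
    fitted_y: np.ndarray  # smoothed mean-square at fitted_x
    frac: float
    n_iterations_run: int
    n_points_per_fit: list[int] | None = None  # points entering each fit

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Linear interpolation; constant extrapolation outside the fitted range."""
        return np.interp(np.asarray(x, dtype=float), self.fitted_x, self.fitted_y)


@dataclass
class ResidualScores:
    residual: np.ndarray  # signed s_j - s~(m_j)
    score: np.ndarray  # |residual|
    quantile: np.ndarray  # normal-CDF quantile under the last fit's residual model


def _fit_curve(x: np.ndarray, y: np.ndarray, frac: float) -> tuple[np.ndarray, np.ndarray]:
    """LOWESS fit returning a strictly increasing curve (duplicate x averaged)."""
    fitted = lowess(y, x, frac=frac, it=3, return_sorted=True)
    fx, fy = fitted[:, 0], fitted[:, 1]
    ux, inverse = np.unique(fx, return_inverse=True)
    if ux.size < fx.size:
        uy = np.bincount(inverse, weights=fy) / np.bincount(inverse)
    else:
        uy = fy
    return ux, uy


def iterative_lowess_scores(
    cs: CorrelationSummary,
    n_fits: int = 3,
    trim_quantiles: tuple[float, float] = (0.05, 0.95),
    frac: float = 0.3,
) -> tuple[ResidualScores, LowessFit]:
    """Score every peak by absolute residual from the last of ``n_fits`` fits."""
    m = np.asarray(cs.mean, dtype=float)
    s = np.asarray(cs.mean_square, dtype=float)
    p = m.size
    if p < 20:
        raise ValidationError(f"need at least 20 peaks to smooth, got {p}")
    lo, hi = trim_quantiles
    if not 0 < lo < hi < 1:
        raise ValidationError(f"invalid trim quantiles {trim_quantiles}")
    active = np.arange(p)
    fx = fy = None
    fits_run = 0
    n_points_per_fit: list[int] = []
    for fit_no in range(1, n_fits + 1):
        if active.size < 10:
            raise ValidationError(
                f"only {active.size} points survive trimming before fit {fit_no}; "
                "widen trim_quantiles"
            )
        n_points_per_fit.append(active.size)
        fx, fy = _fit_curve(m[active], s[active], frac)
        res = s[active] - np.interp(m[active], fx, fy)
        fits_run = fit_no
        if fit_no == n_fits:
            break
        mu, sd = res.mean(), res.std(ddof=1)
        if sd <= 1e-12 * max(1.0, float(np.abs(s).max())):
            break  # residuals are numerically zero; nothing to trim
        q = norm.cdf(res, loc=mu, scale=sd)
        active = active[(q >= lo) & (q <= hi)]
    final = LowessFit(
        fitted_x=fx,
        fitted_y=fy,
        frac=frac,
        n_iterations_run=fits_run,
        n_points_per_fit=n_points_per_fit,
    )
    shat = final.predict(m)
    residual = s - shat
    mu, sd = res.mean(), res.std(ddof=1)
    if sd == 0:
        quantile = np.full(p, 0.5)
    else:
        # keep quantiles strictly inside (0, 1) even for extreme outliers
        quantile = np.clip(norm.cdf(residual, loc=mu, scale=sd), 1e-12, 1 - 1e-12)
    return (
        ResidualScores(residual=residual, score=np.abs(residual), quantile=quantile),
        final,
    )


def select_features(rs: ResidualScores, k: int, peak_ids: list[str] | None = None) -> ScoreTable:
    """Top-k peaks by score, ties broken by ascending original index."""
    p = rs.score.size
    if not 1 <= k <= p:
        raise ValidationError(f"k={k} outside 1..{p}")
    if peak_ids is None:
        peak_ids = [f"peak_{i}" for i in range(p)]
    return ScoreTable.from_scores(rs.score, peak_ids, k=k)


def run_cofea(
    cm: CountMatrix,
    k: int,
    min_cell_fraction: float = 0.01,
    tfidf_variant: str = "signac",
    scale_factor: float = 1e4,
    n_pcs: int = 100,
    corr_method: str = "pcc",
    chunk_size: int = 1000,
    n_workers: int = 1,
    n_fits: int = 3,
    trim_quantiles: tuple[float, float] = (0.05, 0.95),
    frac: float = 0.3,
    seed: int = 0,
) -> ScoreTable:
    """Full pipeline: filter -> TF-IDF -> cell-wise PCA -> correlation summary
    -> iterative LOWESS -> top-k selection.

    The returned table covers all original peaks: filtered-out peaks get score
    0 and ranks after every scored peak (in original index order).
    """
    stage = "filter_by_prevalence"
    try:
        filtered, kept = filter_by_prevalence(cm, min_cell_fraction)
        if k > filtered.p:
            raise ValidationError(
                f"k={k} exceeds {filtered.p} peaks remaining after filtering"
            )
        stage = "tfidf_transform"
        tm = tfidf_transform(filtered, variant=tfidf_variant, scale_factor=scale_factor)
        stage = "pca_peak_embedding"
        pe = pca_peak_embedding(tm, n_components=n_pcs, seed=seed)
        stage = "correlation_summary"
        cs = correlation_summary(
            pe, method=corr_method, chunk_size=chunk_size, n_workers=n_workers
        )
        stage = "iterative_lowess_scores"
        rs, _ = iterative_lowess_scores(
            cs, n_fits=n_fits, trim_quantiles=trim_quantiles, frac=frac
        )
    except ValidationError as exc:
        raise ValidationError(f"[{stage}] {exc}") from exc

    p_orig = cm.p
    scores = np.zeros(p_orig)
    scores[kept] = rs.score
    # ranks: scored peaks first (score desc, index asc), then dropped peaks by index
    dropped = np.setdiff1d(np.arange(p_orig), kept, assume_unique=True)
    order_kept = kept[np.lexsort((np.arange(kept.size), -rs.score))]
    full_order = np.concatenate([order_kept, dropped])
    rank = np.empty(p_orig, dtype=int)
    rank[full_order] = np.arange(1, p_orig + 1)
    return ScoreTable(
        peak_index=np.arange(p_orig),
        peak_id=cm.peak_ids,
        score=scores,
        rank=rank,
        selected=rank <= k,
        k=k,
    )
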