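"""Evaluation of feature selections: ground-truth overlap, baseline
selectors, and clustering/embedding quality metrics on a standard
downstream pipeline (TF-IDF -> PCA -> kNN -> Leiden)."""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import igraph as ig
import leidenalg
import numpy as np
import scipy.sparse as sp
from scipy.stats import rankdata
from sklearn.decomposition import PCA
from sklearn.metrics import (
    adjusted_mutual_info_score,
    adjusted_rand_score,
    homogeneity_score,
    normalized_mutual_info_score,
    silhouette_score,
)
from sklearn.neighbors import NearestNeighbors

from .preprocessing import tfidf_transform
from .types import CountMatrix, ScoreTable, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class ClusteringReport:
    nmi: float
    ami: float
    ari: float
    homo: float
    asw: float
    clisi: float
    n_clusters_found: int
    n_features_used: int

    def as_dict(self) -> dict[str, float]:
        return {
            "nmi": self.nmi,
            "ami": self.ami,
            "ari": self.ari,
            "homo": self.homo,
            "asw": self.asw,
            "clisi": self.clisi,
            "n_clusters_found": self.n_clusters_found,
            "n_features_used": self.n_features_used,
        }


def overlap_proportion(selected: set[int], truth: set[int]) -> float:
    """|selected & truth| / min(|selected|, |truth|).

    The min denominator makes a perfect score of 1 attainable whether fewer
    or more features than ground-truth peaks are selected.
    """
    if not truth:
        raise ValidationError("truth set is empty")
    if not selected:
        warnings.warn("empty selection; overlap proportion is 0", stacklevel=2)
        return 0.0
    return len(set(selected) & set(truth)) / min(len(selected), len(truth))


def baseline_hda(cm: CountMatrix, k: int) -> ScoreTable:
    """Highest degree of accessibility: number of cells with count >= 1."""
    score = cm.values.getnnz(axis=1).astype(float)
    return ScoreTable.from_scores(score, cm.peak_ids, k=k)


def baseline_signac(cm: CountMatrix, k: int) -> ScoreTable:
    """TF-IDF row sums mapped to empirical quantiles; top quantiles selected."""
    tm = tfidf_transform(cm, variant="signac")
    rowsum = np.asarray(tm.values.sum(axis=1)).ravel()
    quantile = rankdata(rowsum, method="average") / rowsum.size
    return ScoreTable.from_scores(quantile, cm.peak_ids, k=k)


def baseline_episcanpy(cm: CountMatrix, k: int) -> ScoreTable:
    """Tent-shaped variability of the open fraction: 1 - |2f - 1|.

    Maximal for peaks open in half the cells, zero for peaks open in none or
    all — an approximation of the quoted behavior of the reference tool.
    """
    f = cm.values.getnnz(axis=1) / cm.n
    score = 1.0 - np.abs(2.0 * f - 1.0)
    return ScoreTable.from_scores(score, cm.peak_ids, k=k)


def _leiden_partition(graph: ig.Graph, resolution: float, seed: int) -> np.ndarray:
    part = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=2,
    )
    return np.asarray(part.membership)


def _leiden_match_k(
    graph: ig.Graph, target: int, seed: int, max_iter: int = 20
) -> np.ndarray:
    """Binary-search the resolution until the cluster count matches ``target``
    (or is nearest after ``max_iter`` iterations)."""
    lo, hi = 1e-4, 5.0
    best, best_gap = None, np.inf
    # expand upper bound until enough clusters appear
    for _ in range(6):
        memb = _leiden_partition(graph, hi, seed)
        if memb.max() + 1 >= target:
            break
        hi *= 4
    for _ in range(max_iter):
        mid = (lo + hi) / 2
        memb = _leiden_partition(graph, mid, seed)
        ncl = memb.max() + 1
        gap = abs(ncl - target)
        if gap < best_gap:
            best, best_gap = memb, gap
        if ncl == target:
            return memb
        if ncl < target:
            lo = mid
        else:
            hi = mid
    return best


def _knn_graph(embedding: np.ndarray, n_neighbors: int) -> ig.Graph:
    nn = NearestNeighbors(n_neighbors=n_neighbors + 1, metric="cosine")
    nn.fit(embedding)
    _, idx = nn.kneighbors(embedding)
    edges = {(min(i, j), max(i, j)) for i, row in enumerate(idx) for j in row[1:]}
    g = ig.Graph(n=embedding.shape[0], edges=sorted(edges))
    return g


def _clisi(embedding: np.ndarray, labels: np.ndarray, n_neighbors: int = 30) -> float:
    """Median rescaled inverse-Simpson of true labels over each cell's
    neighborhood; 1 = perfect separation, 0 = full mixing."""
    codes = np.unique(labels, return_inverse=True)[1]
    n_types = codes.max() + 1
    if n_types < 2:
        return 1.0
    k = min(n_neighbors + 1, embedding.shape[0])
    nn = NearestNeighbors(n_neighbors=k)
    nn.fit(embedding)
    _, idx = nn.kneighbors(embedding)
    per_cell = np.empty(embedding.shape[0])
    for i, row in enumerate(idx):
        freq = np.bincount(codes[row[1:]], minlength=n_types) / (k - 1)
        simpson = float((freq**2).sum())
        lisi = 1.0 / simpson if simpson > 0 else n_types
        per_cell[i] = (n_types - lisi) / (n_types - 1)
    return float(np.median(per_cell))


def cluster_and_score(
    cm: CountMatrix,
    selected: set[int],
    labels: dict[str, str] | None = None,
    seed: int = 0,
    n_pcs: int = 50,
    knn: int = 15,
    clisi_neighbors: int = 30,
) -> ClusteringReport:
    """Cluster cells using only the selected peaks and score against labels.

    Pipeline: peak subset -> TF-IDF (signac) -> PCA over cells -> kNN graph
    (cosine) -> Leiden with resolution tuned to the true type count.
    """
    if labels is None:
        if cm.labels is None:
            raise ValidationError("labels required (on the matrix or as an argument)")
        labels = cm.labels
    sel = np.sort(np.fromiter(selected, dtype=int))
    if sel.size < 10:
        raise ValidationError(f"need at least 10 selected peaks, got {sel.size}")
    true = np.asarray([labels[b] for b in cm.barcodes])
    uniq, counts = np.unique(true, return_counts=True)
    if counts.min() < 3:
        warnings.warn(
            f"cell type {uniq[counts.argmin()]!r} has fewer than 3 cells", stacklevel=2
        )
    sub = CountMatrix(
        values=cm.values[sel],
        peaks=[cm.peaks[i] for i in sel],
        barcodes=list(cm.barcodes),
        labels=cm.labels,
    )
    tm = tfidf_transform(sub, variant="signac", strict=False)
    X = np.asarray(tm.values.T.todense())  # cells x selected peaks
    q = min(n_pcs, min(X.shape) - 1)
    emb = PCA(n_components=q, svd_solver="full", random_state=seed).fit_transform(X)
    graph = _knn_graph(emb, knn)
    pred = _leiden_match_k(graph, target=len(uniq), seed=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        asw_raw = silhouette_score(emb, true) if len(uniq) > 1 else 0.0
    return ClusteringReport(
        nmi=float(normalized_mutual_info_score(true, pred)),
        ami=float(adjusted_mutual_info_score(true, pred)),
        ari=float(adjusted_rand_score(true, pred)),
        homo=float(homogeneity_score(true, pred)),
        asw=float((asw_raw + 1.0) / 2.0),
        clisi=_clisi(emb, true, clisi_neighbors),
        n_clusters_found=int(pred.max() + 1),
        n_features_used=int(sel.size),
    )


BASELINES = {
    "hda": baseline_hda,
    "signac": baseline_signac,
    "episcanpy": baseline_episcanpy,
}


def select_with_method(cm: CountMatrix, method: str, k: int, seed: int = 0, **cofea_params) -> ScoreTable:
    """Dispatch a selection method name ('cofea' or a baseline) to a ScoreTable."""
    if method == "cofea":
        from .scoring import run_cofea

        return run_cofea(cm, k=k, seed=seed, **cofea_params)
    if method in BASELINES:
        return BASELINES[method](cm, k)
    raise ValidationError(f"unknown method {method!r}; use cofea|hda|signac|episcanpy")
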