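"""Shared domain types: the peak-by-cell count matrix and per-peak score tables."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import scipy.sparse as sp


class ValidationError(ValueError):
    """A domain object violates one of its invariants."""


class FormatError(ValueError):
    """An on-disk file does not match the expected dialect or dimensions."""


class Peak(NamedTuple):
    """A genomic interval in 0-based half-open BED convention."""

    chrom: str
    start: int
    end: int

    @property
    def peak_id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"

    @classmethod
    def from_id(cls, peak_id: str) -> "Peak":
        chrom, rest = peak_id.rsplit(":", 1)
        start, end = rest.split("-")
        return cls(chrom, int(start), int(end))


@dataclass
class CountMatrix:
    """Sparse peak-by-cell non-negative integer matrix with coordinates and barcodes.

    Rows are peaks (``p``), columns are cells (``n``). ``labels`` optionally maps
    each barcode to a cell-type string and is used only for evaluation.
    """

    values: sp.csr_matrix
    peaks: list[Peak]
    barcodes: list[str]
    labels: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if not sp.issparse(self.values):
            self.values = sp.csr_matrix(np.asarray(self.values))
        self.values = self.values.tocsr()
        self.peaks = [Peak(*pk) for pk in self.peaks]
        self.validate()

    @property
    def p(self) -> int:
        return self.values.shape[0]

    @property
    def n(self) -> int:
        return self.values.shape[1]

    @property
    def peak_ids(self) -> list[str]:
        return [pk.peak_id for pk in self.peaks]

    def validate(self) -> None:
        p, n = self.values.shape
        if len(self.peaks) != p:
            raise ValidationError(
                f"peak list length {len(self.peaks)} != matrix rows {p}"
            )
        if len(self.barcodes) != n:
            raise ValidationError(
                f"barcode list length {len(self.barcodes)} != matrix columns {n}"
            )
        if len(set(self.barcodes)) != n:
            raise ValidationError("barcodes are not unique")
        data = self.values.data
        if data.size:
            if data.min() < 0:
                raise ValidationError("count matrix contains negative entries")
            if not np.allclose(data, np.round(data)):
                raise ValidationError("count matrix contains non-integer entries")
        for i, pk in enumerate(self.peaks):
            if pk.start < 0 or pk.start >= pk.end:
                raise ValidationError(
                    f"peak {i} has invalid interval {pk.chrom}:{pk.start}-{pk.end}"
                )
        if self.labels is not None:
            missing = [b for b in self.barcodes if b not in self.labels]
            if missing:
                raise ValidationError(
                    f"labels missing for {len(missing)} barcodes (e.g. {missing[0]!r})"
                )

    def label_array(self) -> np.ndarray:
        if self.labels is None:
            raise ValidationError("count matrix carries no labels")
        return np.asarray([self.labels[b] for b in self.barcodes])


@dataclass
class ScoreTable:
    """Per-peak significance scores, ranks (1 = most significant) and selection flags."""

    peak_index: np.ndarray  # original 0-based row indices
    peak_id: list[str]
    score: np.ndarray
    rank: np.ndarray
    selected: np.ndarray
    k: int | None = field(default=None)

    def __post_init__(self) -> None:
        self.peak_index = np.asarray(self.peak_index, dtype=int)
        self.score = np.asarray(self.score, dtype=float)
        self.rank = np.asarray(self.rank, dtype=int)
        self.selected = np.asarray(self.selected, dtype=bool)
        self.validate()

    def __len__(self) -> int:
        return len(self.peak_index)

    def validate(self) -> None:
        p = len(self.peak_index)
        if not (
            len(self.peak_id) == len(self.score) == len(self.rank) == len(self.selected) == p
        ):
            raise ValidationError("score table columns have inconsistent lengths")
        if p and sorted(self.rank) != list(range(1, p + 1)):
            raise ValidationError("ranks are not a permutation of 1..p")
        if p:
            order = np.argsort(self.rank)
            diffs = np.diff(self.score[order])
            if diffs.size and diffs.max() > 1e-12:
                raise ValidationError("score is not non-increasing along rank")
        if self.k is not None and p:
            expect = self.rank <= self.k
            if not np.array_equal(expect, self.selected):
                raise ValidationError("selected flags do not match the k smallest ranks")

    @classmethod
    def from_scores(
        cls,
        scores: np.ndarray,
        peak_ids: list[str],
        k: int | None = None,
        peak_index: np.ndarray | None = None,
    ) -> "ScoreTable":
        """Rank scores descending, ties broken by ascending original index (stable)."""
        scores = np.asarray(scores, dtype=float)
        p = scores.size
        if k is not None and not (1 <= k <= p):
            raise ValidationError(f"k={k} outside 1..{p}")
        if peak_index is None:
            peak_index = np.arange(p)
        order = np.lexsort((np.arange(p), -scores))
        rank = np.empty(p, dtype=int)
        rank[order] = np.arange(1, p + 1)
        selected = rank <= k if k is not None else np.zeros(p, dtype=bool)
        return cls(
            peak_index=np.asarray(peak_index),
            peak_id=list(peak_ids),
            score=scores,
            rank=rank,
            selected=selected,
            k=k,
        )

    def selected_set(self) -> set[int]:
        return set(self.peak_index[self.selected].tolist())

    def top_k(self, k: int) -> set[int]:
        return set(self.peak_index[self.rank <= k].tolist())
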