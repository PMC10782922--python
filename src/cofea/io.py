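"""Readers and writers for the on-disk quartet: MTX counts, BED3 peaks,
barcode TSV, optional barcode->label TSV, and the score TSV."""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io as spio
import scipy.sparse as sp

from .types import CountMatrix, FormatError, Peak, ScoreTable, ValidationError

SCORE_COLUMNS = ["peak_index", "peak_id", "score", "rank", "selected"]


def _require(path: str | Path) -> Path:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    return path


def read_bed(path: str | Path) -> list[Peak]:
    """Read a 3+-column BED file (0-based half-open) into peak intervals."""
    path = _require(path)
    peaks: list[Peak] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{ln}: expected >=3 BED columns")
            try:
                peaks.append(Peak(parts[0], int(parts[1]), int(parts[2])))
            except ValueError as exc:
                raise FormatError(f"{path}:{ln}: non-integer BED coordinate") from exc
    return peaks


def write_bed(peaks: list[Peak], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for pk in peaks:
            fh.write(f"{pk.chrom}\t{pk.start}\t{pk.end}\n")
    return path


def read_barcodes(path: str | Path) -> list[str]:
    path = _require(path)
    with open(path) as fh:
        barcodes = [line.strip() for line in fh if line.strip()]
    return barcodes


def write_barcodes(barcodes: list[str], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for bc in barcodes:
            fh.write(bc + "\n")
    return path


def read_labels(path: str | Path) -> dict[str, str]:
    """Two-column barcode<TAB>label TSV (no header)."""
    path = _require(path)
    labels: dict[str, str] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}:{ln}: expected 2 tab-separated columns")
            labels[parts[0]] = parts[1]
    return labels


def write_labels(labels: dict[str, str], barcodes: list[str], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for bc in barcodes:
            fh.write(f"{bc}\t{labels[bc]}\n")
    return path


def read_count_matrix(
    mtx_path: str | Path,
    bed_path: str | Path,
    barcodes_path: str | Path,
    labels_path: str | Path | None = None,
) -> CountMatrix:
    """Assemble a validated CountMatrix from an MTX/BED/barcodes triplet.

    Row order follows the BED file, column order follows the barcode file.
    Entry order inside the MTX body is irrelevant.
    """
    mtx_path = _require(mtx_path)
    try:
        values = spio.mmread(str(mtx_path))
    except Exception as exc:  # noqa: BLE001 - surface with path context
        raise FormatError(f"could not parse Matrix Market file {mtx_path}: {exc}") from exc
    values = sp.coo_matrix(values)
    peaks = read_bed(bed_path)
    barcodes = read_barcodes(barcodes_path)
    p, n = values.shape
    if p != len(peaks):
        raise FormatError(
            f"{mtx_path} declares {p} rows but {bed_path} has {len(peaks)} peaks"
        )
    if n != len(barcodes):
        raise FormatError(
            f"{mtx_path} declares {n} columns but {barcodes_path} has "
            f"{len(barcodes)} barcodes"
        )
    if p < 2 or n < 2:
        raise FormatError(
            f"{mtx_path}: matrices with fewer than 2 peaks or 2 cells are rejected"
        )
    if values.data.size and not np.allclose(values.data, np.round(values.data)):
        raise ValidationError(f"{mtx_path} contains non-integer entries")
    labels = read_labels(labels_path) if labels_path is not None else None
    return CountMatrix(
        values=sp.csr_matrix(values, dtype=np.int64),
        peaks=peaks,
        barcodes=barcodes,
        labels=labels,
    )


def write_count_matrix(cm: CountMatrix, out_dir: str | Path) -> tuple[Path, Path, Path]:
    """Write the MTX/BED/barcodes triplet (plus labels.tsv when present)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    mtx_path = out_dir / "matrix.mtx"
    bed_path = out_dir / "peaks.bed"
    barcodes_path = out_dir / "barcodes.tsv"
    try:
        spio.mmwrite(str(mtx_path), cm.values.tocoo().astype(np.int64), field="integer")
    except OSError as exc:
        raise OSError(f"failed writing {mtx_path}: {exc}") from exc
    write_bed(cm.peaks, bed_path)
    write_barcodes(cm.barcodes, barcodes_path)
    if cm.labels is not None:
        write_labels(cm.labels, cm.barcodes, out_dir / "labels.tsv")
    return mtx_path, bed_path, barcodes_path


def read_dense_matrix(path: str | Path, labels_path: str | Path | None = None) -> CountMatrix:
    """Convenience reader for toy CSV/TSV tables.

    Row names are "chrom:start-end" peak ids, column names are barcodes.
    """
    path = _require(path)
    sep = "\t" if path.suffix in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.shape[0] < 2 or df.shape[1] < 2:
        raise FormatError(f"{path}: matrices with fewer than 2 peaks or 2 cells are rejected")
    try:
        peaks = [Peak.from_id(str(pid)) for pid in df.index]
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"{path}: row names must be 'chrom:start-end' ids") from exc
    labels = read_labels(labels_path) if labels_path is not None else None
    return CountMatrix(
        values=sp.csr_matrix(df.to_numpy()),
        peaks=peaks,
        barcodes=[str(c) for c in df.columns],
        labels=labels,
    )


def write_scores(st: ScoreTable, path: str | Path) -> Path:
    """Write a score table as TSV, rows ordered by rank."""
    path = Path(path)
    order = np.argsort(st.rank) if len(st) else np.array([], dtype=int)
    df = pd.DataFrame(
        {
            "peak_index": st.peak_index[order],
            "peak_id": [st.peak_id[i] for i in order],
            "score": st.score[order],
            "rank": st.rank[order],
            "selected": st.selected[order],
        },
        columns=SCORE_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)
    return path


def read_scores(path: str | Path) -> ScoreTable:
    path = _require(path)
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SCORE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing score columns {missing}")
    if len(df) == 0:
        return ScoreTable(
            peak_index=np.array([], dtype=int),
            peak_id=[],
            score=np.array([]),
            rank=np.array([], dtype=int),
            selected=np.array([], dtype=bool),
        )
    selected = df["selected"]
    if selected.dtype == object:
        selected = selected.astype(str).str.lower().isin({"true", "1"})
    k = int(df["rank"][selected].max()) if selected.any() else None
    return ScoreTable(
        peak_index=df["peak_index"].to_numpy(),
        peak_id=[str(x) for x in df["peak_id"]],
        score=df["score"].to_numpy(float),
        rank=df["rank"].to_numpy(int),
        selected=selected.to_numpy(bool),
        k=k,
    )


def file_digest(path: str | Path) -> str:
    import hashlib

    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def dataset_paths(directory: str | Path) -> dict[str, Path]:
    """Locate the standard quartet files inside a dataset directory."""
    directory = Path(directory)
    out = {
        "mtx": directory / "matrix.mtx",
        "bed": directory / "peaks.bed",
        "barcodes": directory / "barcodes.tsv",
    }
    labels = directory / "labels.tsv"
    if labels.exists():
        out["labels"] = labels
    return out


def is_dir_writable(path: str | Path) -> bool:
    return os.access(str(path), os.W_OK)
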