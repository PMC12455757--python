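"""Count matrices, transcript annotation, and gene-level aggregation.

The universal I/O currency is :class:`CountMatrix`: a sparse features x cells
matrix of non-negative values (raw counts or normalized expression) with
unique, ordered feature and cell identifiers.  Isoform (transcript) matrices
are mapped to genes through :class:`TranscriptInfo`, parsed from a GTF or a
plain 2-3 column table.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "CountMatrix",
    "TranscriptInfo",
    "CellMetadata",
    "read_count_matrix",
    "write_count_matrix",
    "parse_gtf_transcript_info",
    "read_transcript_info_table",
    "aggregate_gene_counts",
]

VALID_LAYERS = ("raw_counts", "normalised", "lognorm")


class MatrixFormatError(ValueError):
    """Raised when an input file cannot be parsed or violates the contract."""


@dataclass
class CountMatrix:
    """Sparse features x cells expression matrix.

    Parameters
    ----------
    values
        ``scipy.sparse`` matrix (stored as CSR) of shape
        ``(len(features), len(cells))`` with non-negative entries.
    features
        Ordered unique feature identifiers (gene or transcript IDs).
    cells
        Ordered unique cell barcodes.
    layer_tag
        One of ``raw_counts``, ``normalised`` (pre-normalized input, e.g.
        TPM/FPKM), or ``lognorm`` (produced by :func:`isoplex.scht.normalize`).
    """

    values: sp.csr_matrix
    features: np.ndarray
    cells: np.ndarray
    layer_tag: str = "raw_counts"

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)
        self.features = np.asarray(self.features, dtype=object)
        self.cells = np.asarray(self.cells, dtype=object)
        if self.layer_tag not in VALID_LAYERS:
            raise ValueError(f"layer_tag must be one of {VALID_LAYERS}, got {self.layer_tag!r}")
        if self.values.shape != (self.features.size, self.cells.size):
            raise MatrixFormatError(
                f"matrix shape {self.values.shape} does not match "
                f"{self.features.size} features x {self.cells.size} cells"
            )
        for name, ids in (("feature", self.features), ("cell", self.cells)):
            if len(set(ids)) != len(ids):
                dupes = pd.Index(ids)[pd.Index(ids).duplicated()].unique().tolist()
                raise MatrixFormatError(f"duplicate {name} IDs: {dupes[:5]}")
        if self.values.nnz and self.values.data.min() < 0:
            raise MatrixFormatError("count matrix contains negative entries")

    # -- convenience -------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def nnz(self) -> int:
        self.values.eliminate_zeros()
        return self.values.nnz

    def to_dense(self) -> np.ndarray:
        return np.asarray(self.values.todense())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.to_dense(), index=self.features, columns=self.cells)

    def feature_index(self) -> dict:
        return {f: i for i, f in enumerate(self.features)}

    def subset(self, feature_mask=None, cell_mask=None) -> "CountMatrix":
        vals = self.values
        feats, cells = self.features, self.cells
        if feature_mask is not None:
            vals = vals[feature_mask, :]
            feats = feats[feature_mask]
        if cell_mask is not None:
            vals = vals[:, cell_mask]
            cells = cells[cell_mask]
        return CountMatrix(vals, feats, cells, self.layer_tag)

    @classmethod
    def from_dense(cls, array, features, cells, layer_tag="raw_counts") -> "CountMatrix":
        return cls(sp.csr_matrix(np.asarray(array, dtype=float)), features, cells, layer_tag)


@dataclass
class TranscriptInfo:
    """transcript_id -> (gene_id, gene_name) mapping with unique transcripts."""

    table: pd.DataFrame  # columns: transcript_id, gene_id, gene_name

    def __post_init__(self) -> None:
        required = ["transcript_id", "gene_id", "gene_name"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise ValueError(f"TranscriptInfo table missing columns {missing}")
        self.table = self.table[required].reset_index(drop=True)
        if self.table["transcript_id"].duplicated().any():
            dup = self.table.loc[self.table["transcript_id"].duplicated(), "transcript_id"]
            raise MatrixFormatError(f"duplicate transcript_ids: {dup.unique()[:5].tolist()}")

    @property
    def transcript_to_gene(self) -> pd.Series:
        return self.table.set_index("transcript_id")["gene_id"]

    def genes(self) -> np.ndarray:
        return self.table["gene_id"].unique()

    def isoforms_of(self, gene_id: str) -> list:
        return self.table.loc[self.table["gene_id"] == gene_id, "transcript_id"].tolist()


@dataclass
class CellMetadata:
    """Cell barcode -> cell-type label; cell types partition the cell set."""

    cell_types: pd.Series  # index: cell_id, values: cell-type label

    def __post_init__(self) -> None:
        self.cell_types = pd.Series(self.cell_types)
        if self.cell_types.index.duplicated().any():
            raise MatrixFormatError("duplicate cell_ids in metadata")

    @property
    def types(self) -> list:
        # stable first-appearance order
        return list(dict.fromkeys(self.cell_types.tolist()))

    def cells_of(self, cell_type) -> np.ndarray:
        return np.asarray(self.cell_types.index[self.cell_types == cell_type])

    @classmethod
    def from_table(cls, path, cell_col="cell_id", type_col="cell_type") -> "CellMetadata":
        df = pd.read_csv(path, sep=None, engine="python")
        if cell_col not in df.columns or type_col not in df.columns:
            raise MatrixFormatError(
                f"metadata must have columns {cell_col!r} and {type_col!r}; found {list(df.columns)}"
            )
        return cls(pd.Series(df[type_col].values, index=df[cell_col].values))


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _read_id_list(path: Path) -> np.ndarray:
    df = pd.read_csv(path, sep="\t", header=None)
    return df.iloc[:, 0].astype(str).values


def read_count_matrix(path, format: str, layer_tag: str = "raw_counts") -> CountMatrix:
    """Read a features x cells matrix from ``mtx_dir``, ``csv`` or ``tsv``.

    ``mtx_dir`` expects ``matrix.mtx`` + ``features.tsv`` + ``barcodes.tsv``
    (MatrixMarket coordinate, 1-based, features x cells).  If the stored
    orientation is transposed relative to the companion files, it is
    auto-detected by dimension matching; square mismatches fail loudly.
    Dense CSV/TSV must carry a header row of cell IDs and feature IDs in the
    first column.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "mtx_dir":
        mtx = path / "matrix.mtx"
        feat = path / "features.tsv"
        barc = path / "barcodes.tsv"
        for p in (mtx, feat, barc):
            if not p.exists():
                raise FileNotFoundError(f"mtx_dir missing companion file {p.name}")
        try:
            values = sp.csr_matrix(scipy.io.mmread(mtx))
        except Exception as exc:  # noqa: BLE001 - surface parse location
            raise MatrixFormatError(f"malformed MatrixMarket file {mtx}: {exc}") from exc
        features = _read_id_list(feat)
        cells = _read_id_list(barc)
        if values.shape == (features.size, cells.size):
            pass
        elif values.shape == (cells.size, features.size) and features.size != cells.size:
            values = sp.csr_matrix(values.T)
        else:
            raise MatrixFormatError(
                f"matrix shape {values.shape} matches neither "
                f"({features.size}, {cells.size}) nor its transpose unambiguously"
            )
    elif format in ("csv", "tsv"):
        sep = "," if format == "csv" else "\t"
        try:
            df = pd.read_csv(path, sep=sep, index_col=0)
        except Exception as exc:  # noqa: BLE001
            raise MatrixFormatError(f"malformed {format} file {path}: {exc}") from exc
        values = sp.csr_matrix(df.values.astype(float))
        features = df.index.astype(str).values
        cells = df.columns.astype(str).values
    else:
        raise ValueError(f"unknown format {format!r}; use mtx_dir, csv or tsv")
    return CountMatrix(values, features, cells, layer_tag)


def write_count_matrix(matrix: CountMatrix, path, format: str = "mtx_dir") -> None:
    """Write a CountMatrix; integer counts round-trip exactly."""
    path = Path(path)
    if format == "mtx_dir":
        path.mkdir(parents=True, exist_ok=True)
        scipy.io.mmwrite(path / "matrix.mtx", sp.coo_matrix(matrix.values))
        pd.Series(matrix.features).to_csv(path / "features.tsv", sep="\t", index=False, header=False)
        pd.Series(matrix.cells).to_csv(path / "barcodes.tsv", sep="\t", index=False, header=False)
    elif format in ("csv", "tsv"):
        sep = "," if format == "csv" else "\t"
        matrix.to_frame().to_csv(path, sep=sep)
    else:
        raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# GTF transcript annotation
# ---------------------------------------------------------------------------

# matches both `key "value";` and `key value;` attribute dialects
_ATTR_RE = re.compile(r'(\w+)\s+"?([^";]+)"?\s*;')


def _parse_attributes(attr_field: str) -> dict:
    return {m.group(1): m.group(2).strip() for m in _ATTR_RE.finditer(attr_field)}


def parse_gtf_transcript_info(path) -> TranscriptInfo:
    """Extract (transcript_id, gene_id, gene_name) records from a GTF.

    Any feature line carrying a ``transcript_id`` attribute contributes (so a
    GTF with only exon lines still yields the transcript set).  ``gene_name``
    falls back to ``gene_id`` when absent.  A transcript mapped to two
    distinct gene_ids is an error.
    """
    path = Path(path)
    records: dict[str, tuple[str, str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise MatrixFormatError(f"{path}:{lineno}: expected 9 tab-separated GTF fields")
            attrs = _parse_attributes(fields[8])
            tid = attrs.get("transcript_id")
            gid = attrs.get("gene_id")
            if tid is None or gid is None:
                continue
            name = attrs.get("gene_name", gid)
            if tid in records:
                if records[tid][0] != gid:
                    raise MatrixFormatError(
                        f"{path}:{lineno}: transcript {tid} maps to both "
                        f"{records[tid][0]} and {gid}"
                    )
            else:
                records[tid] = (gid, name)
    table = pd.DataFrame(
        [(t, g, n) for t, (g, n) in records.items()],
        columns=["transcript_id", "gene_id", "gene_name"],
    )
    return TranscriptInfo(table)


def read_transcript_info_table(path) -> TranscriptInfo:
    """Read a 2-3 column TSV (transcript_id, gene_id[, gene_name])."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] == 2:
        df.columns = ["transcript_id", "gene_id"]
        df["gene_name"] = df["gene_id"]
    else:
        df = df.iloc[:, :3]
        df.columns = ["transcript_id", "gene_id", "gene_name"]
    return TranscriptInfo(df)


# ---------------------------------------------------------------------------
# Gene-level aggregation
# ---------------------------------------------------------------------------

def aggregate_gene_counts(iso: CountMatrix, info: TranscriptInfo) -> CountMatrix:
    """Sum isoform rows into gene rows (raw counts, before normalization).

    Gene order follows first appearance in the annotation restricted to the
    matrix's isoforms.  Unmapped transcripts are an error.
    """
    t2g = info.transcript_to_gene
    unmapped = [t for t in iso.features if t not in t2g.index]
    if unmapped:
        raise MatrixFormatError(f"transcripts missing from annotation: {unmapped[:10]}")
    gene_of = t2g.loc[iso.features].values
    genes = list(dict.fromkeys(gene_of))
    gene_idx = {g: i for i, g in enumerate(genes)}
    rows = np.array([gene_idx[g] for g in gene_of])
    # indicator matrix (genes x isoforms) @ iso values
    indicator = sp.csr_matrix(
        (np.ones(rows.size), (rows, np.arange(rows.size))), shape=(len(genes), rows.size)
    )
    return CountMatrix(indicator @ iso.values, np.asarray(genes, dtype=object), iso.cells, iso.layer_tag)
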