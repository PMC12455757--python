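"""Quality control, normalization, HVG selection, and hierarchical tensor build.

The single-cell hierarchical tensor (SCHT) replaces a zero-padded
cell x gene x isoform array with a gene-keyed collection of small
isoform x cell sub-matrices sharing one cell ordering.  With cell-type
labels it is extended to per-(gene, cell type) sub-matrices restricted to
the type's gene-expressing cells and the isoforms expressed in that type.

Pipeline order is fixed: feature filter -> cell filter -> normalize ->
HVG selection -> SCHT build -> cell-type integration; each stage logs its
statistics for the QC report.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .matrix import CellMetadata, CountMatrix, TranscriptInfo

__all__ = [
    "QCParams",
    "SCHT",
    "IntegratedSCHT",
    "RunLog",
    "recommend_qc_parameters",
    "filter_features",
    "filter_cells",
    "normalize",
    "select_hvgs",
    "build_scht",
    "integrate_cell_types",
    "create_scht",
    "save_scht",
    "load_scht",
]


class PipelineError(RuntimeError):
    """Raised when a QC step leaves nothing to analyze."""


@dataclass
class QCParams:
    """Quality-control and selection parameters.

    p_min: minimum detection proportion for a gene (default 0.02).
    epsilon: minimum mean raw count for a gene (default 1e-4).
    n_min/n_max: inclusive bounds on detected genes per cell (200 / 20000).
    n_hvg: number of highly variable genes kept (default 3000, capped at
        the number of genes available).
    input_type: 'raw_counts' (CPM + log2) or 'normalised' (log2 only).
    """

    p_min: float = 0.02
    epsilon: float = 1e-4
    n_min: int = 200
    n_max: int = 20000
    n_hvg: int = 3000
    input_type: str = "raw_counts"

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_min <= 1.0:
            raise ValueError("p_min must be in [0, 1]")
        if self.n_min >= self.n_max:
            raise ValueError("n_min must be < n_max")
        if self.n_hvg < 1:
            raise ValueError("n_hvg must be >= 1")
        if self.input_type not in ("raw_counts", "normalised"):
            raise ValueError("input_type must be 'raw_counts' or 'normalised'")


class RunLog(dict):
    """Stage statistics collected during SCHT construction (for QC report)."""

    def record(self, section: str, **stats) -> None:
        self.setdefault(section, {}).update(stats)


@dataclass
class SCHT:
    """Gene-keyed collection of isoform x cell sub-matrices.

    ``matrices[g]`` is a dense (I_g x n) array of normalized expression;
    every sub-matrix has >= 2 isoform rows and shares ``cells`` ordering.
    """

    matrices: dict  # gene_id -> np.ndarray (I_g x n)
    isoforms: dict  # gene_id -> list of isoform ids (row order)
    cells: np.ndarray
    run_log: RunLog = field(default_factory=RunLog)

    def __post_init__(self) -> None:
        n = len(self.cells)
        for g, X in self.matrices.items():
            if X.shape[0] < 2:
                raise ValueError(f"gene {g}: SCHT sub-matrix must have >= 2 isoform rows")
            if X.shape != (len(self.isoforms[g]), n):
                raise ValueError(f"gene {g}: sub-matrix shape mismatch")
            if X.min() < 0:
                raise ValueError(f"gene {g}: negative expression values")

    @property
    def genes(self) -> list:
        return list(self.matrices)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def total_nonzero(self) -> int:
        return int(sum(np.count_nonzero(X) for X in self.matrices.values()))


@dataclass
class IntegratedSCHT(SCHT):
    """SCHT plus per-(gene, cell type) sub-matrices.

    ``by_type[g][k]`` is a dict with keys ``isoforms`` (row ids), ``cells``
    (barcodes of type-k cells expressing g) and ``X`` (dense sub-matrix).
    A (gene, type) entry exists only if the gene is expressed in that type.
    """

    by_type: dict = field(default_factory=dict)  # gene -> {cell_type -> {...}}
    cell_types: pd.Series = None  # cell -> type, aligned to self.cells

    def types_of(self, gene: str) -> list:
        return list(self.by_type.get(gene, {}))


# ---------------------------------------------------------------------------
# QC operations
# ---------------------------------------------------------------------------

def _detected_per_cell(matrix: CountMatrix) -> np.ndarray:
    return np.asarray((matrix.values > 0).sum(axis=0)).ravel()


def recommend_qc_parameters(gene_matrix: CountMatrix, params: QCParams | None = None) -> QCParams:
    """Suggest n_min/n_max from the genes-per-cell distribution.

    Uses the 1st/99th percentiles rounded outward; a degenerate distribution
    (or < 10 cells) falls back to the defaults (200, 20000), widened outward
    if the observed range lies outside the default window.
    """
    base = params or QCParams()
    gpc = _detected_per_cell(gene_matrix)
    if gene_matrix.cells.size < 10:
        warnings.warn("fewer than 10 cells; returning default QC parameters", stacklevel=2)
        return base
    p1, p99 = np.percentile(gpc, [1, 99])
    if p99 - p1 < 1:  # degenerate distribution
        n_min = min(200, max(1, int(gpc.min()) - 1))
        n_max = max(20000, int(gpc.max()) + 1)
    else:
        n_min = max(1, int(np.floor(p1)))
        n_max = max(int(np.ceil(p99)), n_min + 1)
    return QCParams(base.p_min, base.epsilon, n_min, n_max, base.n_hvg, base.input_type)


def filter_features(
    gene_matrix: CountMatrix,
    iso_matrix: CountMatrix,
    params: QCParams,
    info: TranscriptInfo,
    run_log: RunLog | None = None,
):
    """Remove genes detected in < p_min of cells OR with mean count < epsilon.

    Either criterion alone removes the gene.  All transcripts belonging to
    retained genes are kept, preserving complete isoform diversity.
    """
    n_cells = gene_matrix.cells.size
    detect_prop = np.asarray((gene_matrix.values > 0).sum(axis=1)).ravel() / max(n_cells, 1)
    mean_count = np.asarray(gene_matrix.values.mean(axis=1)).ravel()
    low_detection = detect_prop < params.p_min
    low_mean = mean_count < params.epsilon
    keep = ~(low_detection | low_mean)
    if not keep.any():
        raise PipelineError(
            "no genes survive feature filtering; lower p_min/epsilon or check input"
        )
    kept_genes = set(gene_matrix.features[keep])
    t2g = info.transcript_to_gene
    iso_keep = np.array([t2g.get(t) in kept_genes for t in iso_matrix.features])
    if run_log is not None:
        run_log.record(
            "feature_filter",
            genes_in=int(gene_matrix.features.size),
            genes_removed_low_detection=int(low_detection.sum()),
            genes_removed_low_mean=int((low_mean & ~low_detection).sum()),
            genes_removed_total=int((~keep).sum()),
            genes_out=int(keep.sum()),
            isoforms_removed=int((~iso_keep).sum()),
        )
    return gene_matrix.subset(feature_mask=keep), iso_matrix.subset(feature_mask=iso_keep)


def filter_cells(
    gene_matrix: CountMatrix,
    iso_matrix: CountMatrix,
    params: QCParams,
    run_log: RunLog | None = None,
):
    """Keep cells with n_min <= detected genes <= n_max (inclusive bounds)."""
    gpc = _detected_per_cell(gene_matrix)
    keep = (gpc >= params.n_min) & (gpc <= params.n_max)
    if not keep.any():
        raise PipelineError("no cells survive cell filtering; adjust n_min/n_max")
    if run_log is not None:
        run_log.record(
            "cell_filter",
            cells_in=int(gene_matrix.cells.size),
            cells_removed_low=int((gpc < params.n_min).sum()),
            cells_removed_high=int((gpc > params.n_max).sum()),
            cells_out=int(keep.sum()),
        )
    return gene_matrix.subset(cell_mask=keep), iso_matrix.subset(cell_mask=keep)


def normalize(matrix: CountMatrix, input_type: str = "raw_counts") -> CountMatrix:
    """CPM + log2 for raw counts, log2(c + 1) for pre-normalized input.

    raw_counts: x = log2(c / colsum * 1e6 + 1), per-cell library scaling
    makes the result invariant to rescaling any cell's column.  All-zero
    columns map to zero.
    """
    if matrix.layer_tag != input_type:
        raise ValueError(f"matrix layer {matrix.layer_tag!r} does not match input_type {input_type!r}")
    vals = sp.csc_matrix(matrix.values, copy=True).astype(float)
    if vals.nnz and vals.data.min() < 0:
        raise ValueError("negative values cannot be normalized")
    if input_type == "raw_counts":
        colsum = np.asarray(vals.sum(axis=0)).ravel()
        scale = np.divide(1e6, colsum, out=np.zeros_like(colsum, dtype=float), where=colsum > 0)
        vals = vals @ sp.diags(scale)
    vals.data = np.log2(vals.data + 1.0)
    return CountMatrix(sp.csr_matrix(vals), matrix.features, matrix.cells, "lognorm")


def select_hvgs(norm_gene_matrix: CountMatrix, n_hvg: int, run_log: RunLog | None = None) -> list:
    """Rank genes by dispersion (variance / mean of lognorm expression).

    Zero-mean genes are excluded; ties break by higher mean, then lexical
    gene ID, making the selection deterministic.  Returns the top
    min(n_hvg, available) gene IDs in rank order.
    """
    if norm_gene_matrix.layer_tag != "lognorm":
        raise ValueError("HVG selection expects a lognorm matrix")
    X = norm_gene_matrix.values
    n = X.shape[1]
    mean = np.asarray(X.mean(axis=1)).ravel()
    sq = np.asarray(X.multiply(X).mean(axis=1)).ravel()
    var = (sq - mean**2) * (n / max(n - 1, 1))  # sample variance
    with np.errstate(divide="ignore", invalid="ignore"):
        dispersion = np.where(mean > 0, var / mean, -np.inf)
    order = sorted(
        range(len(mean)),
        key=lambda i: (-dispersion[i], -mean[i], str(norm_gene_matrix.features[i])),
    )
    keep = [i for i in order if mean[i] > 0][: min(n_hvg, len(mean))]
    hvgs = [norm_gene_matrix.features[i] for i in keep]
    if run_log is not None:
        run_log.record(
            "hvg",
            n_hvg_requested=int(n_hvg),
            n_hvg_selected=len(hvgs),
            genes_zero_mean=int((mean <= 0).sum()),
        )
    return hvgs


def build_scht(
    norm_iso_matrix: CountMatrix,
    info: TranscriptInfo,
    hvgs: list,
    run_log: RunLog | None = None,
) -> SCHT:
    """Assemble the SCHT: one isoform x cell sub-matrix per multi-isoform HVG.

    All-zero isoform rows are dropped; genes left with a single detected
    isoform are excluded and counted for the QC report.  The total non-zero
    count across sub-matrices equals that of the filtered isoform matrix
    restricted to retained genes (lossless over retained genes).
    """
    if norm_iso_matrix.layer_tag != "lognorm":
        raise ValueError("SCHT build expects a lognorm isoform matrix")
    run_log = run_log if run_log is not None else RunLog()
    t2g = info.transcript_to_gene
    iso_of_gene: dict[str, list[int]] = {}
    fidx = {f: i for i, f in enumerate(norm_iso_matrix.features)}
    for t, i in fidx.items():
        g = t2g.get(t)
        if g is not None:
            iso_of_gene.setdefault(g, []).append(i)
    matrices, isoforms = {}, {}
    single_iso = 0
    not_detected = 0
    dense = None  # materialize lazily per gene from sparse rows
    for g in hvgs:
        rows = iso_of_gene.get(g, [])
        if not rows:
            not_detected += 1
            continue
        X = np.asarray(norm_iso_matrix.values[rows, :].todense())
        detected = np.count_nonzero(X, axis=1) > 0
        X = X[detected]
        if X.shape[0] < 2:
            single_iso += 1
            continue
        matrices[g] = X
        isoforms[g] = [norm_iso_matrix.features[rows[j]] for j in np.where(detected)[0]]
    run_log.record(
        "scht",
        hvgs_in=len(hvgs),
        genes_single_isoform_removed=single_iso,
        genes_no_isoform_data=not_detected,
        genes_in_scht=len(matrices),
    )
    if not matrices:
        raise PipelineError("no multi-isoform genes available for SCHT construction")
    return SCHT(matrices, isoforms, norm_iso_matrix.cells, run_log)


def integrate_cell_types(scht: SCHT, meta: CellMetadata) -> IntegratedSCHT:
    """Partition each gene's sub-matrix by cell type.

    A cell expresses gene g iff its summed isoform expression is > 0; an
    isoform is expressed in a type iff its sum over the type's cells is > 0.
    A (gene, type) entry exists only when at least one of the type's cells
    expresses the gene.
    """
    labels = meta.cell_types
    missing = [c for c in scht.cells if c not in labels.index]
    if missing:
        raise ValueError(f"cells without cell-type annotation: {missing[:10]}")
    aligned = labels.loc[scht.cells]
    types = list(dict.fromkeys(aligned.tolist()))
    type_cols = {k: np.where(aligned.values == k)[0] for k in types}
    by_type: dict = {}
    for g, X in scht.matrices.items():
        per_gene = {}
        for k, cols in type_cols.items():
            Xk = X[:, cols]
            expressing = Xk.sum(axis=0) > 0
            if not expressing.any():
                continue  # gene not expressed in this type
            Xk = Xk[:, expressing]
            iso_mask = Xk.sum(axis=1) > 0
            per_gene[k] = {
                "isoforms": [scht.isoforms[g][j] for j in np.where(iso_mask)[0]],
                "cells": scht.cells[cols][expressing],
                "X": Xk[iso_mask],
            }
        by_type[g] = per_gene
    return IntegratedSCHT(
        matrices=scht.matrices,
        isoforms=scht.isoforms,
        cells=scht.cells,
        run_log=scht.run_log,
        by_type=by_type,
        cell_types=aligned,
    )


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

def create_scht(
    gene_matrix: CountMatrix,
    iso_matrix: CountMatrix,
    info: TranscriptInfo,
    meta: CellMetadata | None = None,
    params: QCParams | None = None,
):
    """Run the full construction pipeline and return (SCHT, RunLog).

    With ``meta`` an :class:`IntegratedSCHT` is returned.  When ``params`` is
    None, data-adaptive n_min/n_max are taken from
    :func:`recommend_qc_parameters`.
    """
    run_log = RunLog()
    run_log.record(
        "initial",
        n_cells=int(gene_matrix.cells.size),
        n_genes=int(gene_matrix.features.size),
        n_isoforms=int(iso_matrix.features.size),
        n_cell_types=len(meta.types) if meta is not None else 0,
    )
    if params is None:
        params = recommend_qc_parameters(gene_matrix)
    gm, im = filter_features(gene_matrix, iso_matrix, params, info, run_log)
    gm, im = filter_cells(gm, im, params, run_log)
    gm_n = normalize(gm, params.input_type)
    im_n = normalize(im, params.input_type)
    hvgs = select_hvgs(gm_n, params.n_hvg, run_log)
    scht = build_scht(im_n, info, hvgs, run_log)
    if meta is not None:
        scht = integrate_cell_types(scht, meta)
    # sparsity accounting feeds the QC report
    from .report import sparsity_accounting

    run_log.record("sparsity", **sparsity_accounting(scht, im_n, info))
    return scht, run_log


# ---------------------------------------------------------------------------
# Serialization: directory of per-gene MTX sub-matrices + index table
# ---------------------------------------------------------------------------

def save_scht(scht: SCHT, path) -> None:
    import scipy.io
    from pathlib import Path

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    pd.Series(scht.cells).to_csv(path / "cells.tsv", sep="\t", index=False, header=False)
    index_rows = []
    for i, g in enumerate(scht.genes):
        stem = f"gene_{i:05d}"
        scipy.io.mmwrite(path / f"{stem}.mtx", sp.coo_matrix(scht.matrices[g]))
        index_rows.append((g, stem, len(scht.isoforms[g])))
        pd.Series(scht.isoforms[g]).to_csv(
            path / f"{stem}.isoforms.tsv", sep="\t", index=False, header=False
        )
    pd.DataFrame(index_rows, columns=["gene_id", "stem", "n_isoforms"]).to_csv(
        path / "index.tsv", sep="\t", index=False
    )
    if isinstance(scht, IntegratedSCHT) and scht.cell_types is not None:
        pd.DataFrame(
            {"cell_id": scht.cells, "cell_type": scht.cell_types.values}
        ).to_csv(path / "cell_types.tsv", sep="\t", index=False)


def load_scht(path) -> SCHT:
    import scipy.io
    from pathlib import Path

    path = Path(path)
    cells = pd.read_csv(path / "cells.tsv", sep="\t", header=None).iloc[:, 0].astype(str).values
    index = pd.read_csv(path / "index.tsv", sep="\t")
    matrices, isoforms = {}, {}
    for _, row in index.iterrows():
        X = np.asarray(sp.csr_matrix(scipy.io.mmread(path / f"{row.stem}.mtx")).todense())
        matrices[row.gene_id] = X
        isoforms[row.gene_id] = (
            pd.read_csv(path / f"{row.stem}.isoforms.tsv", sep="\t", header=None)
            .iloc[:, 0]
            .astype(str)
            .tolist()
        )
    scht = SCHT(matrices, isoforms, np.asarray(cells, dtype=object))
    ct_path = path / "cell_types.tsv"
    if ct_path.exists():
        ct = pd.read_csv(ct_path, sep="\t")
        meta = CellMetadata(pd.Series(ct["cell_type"].values, index=ct["cell_id"].values))
        return integrate_cell_types(scht, meta)
    return scht
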