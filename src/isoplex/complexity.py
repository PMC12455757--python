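"""The seven core isoform-complexity metrics.

Per gene, on its isoform x cell sub-matrix of normalized expression:

- ``idi_intra``: expression-weighted mean over cells of the normalized
  Shannon entropy of each cell's isoform proportions (do individual cells
  co-express multiple isoforms?).
- ``idi_inter``: normalized entropy of the mean isoform-expression
  proportions across all cells (how diverse is isoform usage across the
  population?).
- ``het``: mean over cell types of the average Jensen-Shannon distance
  between the isoform proportion vectors of cell pairs within a type
  (cell-to-cell variation in isoform usage).
- ``spec``: average Jensen-Shannon distance between cell-type mean isoform
  profiles (cell-type-specific isoform usage).
- ``het_var`` / ``diff_var`` / ``coexp_var``: coefficients of variation of,
  respectively, the per-type heterogeneity values, the pairwise type-type
  JS distances, and the per-type intra-cellular diversity values.

Entropies and JS distances use base-2 logarithms, so all four first-order
metrics live in [0, 1].  NA semantics: metrics that need >= 2 cell types
(or >= 2 pair values for a CV) are NA for genes expressed in a single type;
a cell detecting a single isoform has entropy 0; CVs are NA when the mean
is 0 or fewer than 2 finite inputs remain.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .scht import SCHT, IntegratedSCHT

__all__ = [
    "cell_entropy",
    "idi_intra",
    "idi_inter",
    "js_distance",
    "het_per_type",
    "spec_metric",
    "cv_metric",
    "compute_all_metrics",
    "METRICS",
]

METRICS = ["idi_intra", "idi_inter", "het", "spec", "het_var", "diff_var", "coexp_var"]

_EPS = 1e-300


def _entropy_bits(p: np.ndarray, axis=None) -> np.ndarray:
    """Shannon entropy in bits with the 0*log(0) = 0 convention."""
    p = np.asarray(p, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, -p * np.log2(np.maximum(p, _EPS)), 0.0)
    return terms.sum(axis=axis)


def cell_entropy(proportions, n_detected: int) -> float:
    """Normalized Shannon entropy of one cell's isoform proportions.

    ``n_detected`` is the number of isoforms with non-zero expression in the
    cell; the entropy is divided by log2(n_detected).  A cell detecting a
    single isoform is defined to have entropy 0 (no within-cell diversity).
    """
    p = np.asarray(proportions, dtype=float)
    if p.size == 0:
        raise ValueError("empty proportion vector")
    if n_detected <= 1:
        return 0.0
    return float(_entropy_bits(p) / np.log2(n_detected))


def idi_intra(X: np.ndarray) -> float:
    """Expression-weighted mean of per-cell normalized entropies.

    Weights are each cell's total gene expression w_j; cells with w_j = 0
    do not contribute.  NA for an all-zero matrix.
    """
    X = np.asarray(X, dtype=float)
    w = X.sum(axis=0)
    expressing = w > 0
    if not expressing.any():
        return np.nan
    Xe = X[:, expressing]
    we = w[expressing]
    P = Xe / we
    n_det = np.count_nonzero(Xe, axis=0)
    H = _entropy_bits(P, axis=0)
    denom = np.where(n_det > 1, np.log2(np.maximum(n_det, 2)), 1.0)
    H = np.where(n_det > 1, H / denom, 0.0)
    return float((we * H).sum() / we.sum())


def idi_inter(X: np.ndarray) -> float:
    """Normalized entropy of mean isoform proportions across all cells."""
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        return np.nan
    xbar = X.mean(axis=1)
    total = xbar.sum()
    if total <= 0:
        return np.nan
    pbar = xbar / total
    return float(_entropy_bits(pbar) / np.log2(X.shape[0]))


def js_distance(p, q) -> float:
    """Jensen-Shannon distance (base 2): sqrt(JS divergence), bounded by 1.

    Inputs must be probability vectors on a common support (zero-pad the
    union of isoform sets); KL terms with p_i = 0 contribute 0.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    for v in (p, q):
        if abs(v.sum() - 1.0) > 1e-8:
            raise ValueError(f"input not normalized (sum={v.sum()!r})")
    m = 0.5 * (p + q)
    with np.errstate(divide="ignore", invalid="ignore"):
        kl_pm = np.where(p > 0, p * (np.log2(np.maximum(p, _EPS)) - np.log2(np.maximum(m, _EPS))), 0.0).sum()
        kl_qm = np.where(q > 0, q * (np.log2(np.maximum(q, _EPS)) - np.log2(np.maximum(m, _EPS))), 0.0).sum()
    div = 0.5 * kl_pm + 0.5 * kl_qm
    return float(np.sqrt(max(div, 0.0)))


def _pairwise_js_mean(P: np.ndarray, return_values: bool = False):
    """Mean JS distance over all unordered column pairs of proportion matrix P.

    P is (I x n) with columns summing to 1.  Vectorized through the entropy
    identity JSD(p, q) = H((p+q)/2) - (H(p) + H(q)) / 2.
    """
    I, n = P.shape
    h = _entropy_bits(P, axis=0)  # (n,)
    iu, ju = np.triu_indices(n, k=1)
    M = 0.5 * (P[:, iu] + P[:, ju])
    h_mix = _entropy_bits(M, axis=0)
    div = h_mix - 0.5 * (h[iu] + h[ju])
    d = np.sqrt(np.maximum(div, 0.0))
    if return_values:
        return float(d.mean()), d
    return float(d.mean())


def _proportions(X: np.ndarray) -> np.ndarray:
    """Column-normalize, keeping only expressing columns."""
    X = np.asarray(X, dtype=float)
    w = X.sum(axis=0)
    Xe = X[:, w > 0]
    return Xe / Xe.sum(axis=0)


def het_per_type(Xk: np.ndarray) -> float:
    """Average JS distance between cells of one type (NA if < 2 expressing cells)."""
    P = _proportions(Xk)
    if P.shape[1] < 2:
        return np.nan
    return _pairwise_js_mean(P)


def _type_profile(Xk: np.ndarray) -> np.ndarray:
    """Mean isoform-expression proportions of one cell type's sub-matrix."""
    Xk = np.asarray(Xk, dtype=float)
    xbar = Xk.mean(axis=1)
    return xbar / xbar.sum()


def spec_metric(profiles: list, return_pairs: bool = False):
    """Average JS distance between cell-type profiles on the union isoform set.

    ``profiles`` is a list of equal-length probability vectors (zero-padded
    to the union isoform set).  NA when fewer than 2 types.
    """
    if len(profiles) < 2:
        return (np.nan, np.array([])) if return_pairs else np.nan
    P = np.column_stack(profiles)
    mean, values = _pairwise_js_mean(P, return_values=True)
    if return_pairs:
        return mean, values
    return mean


def cv_metric(values) -> float:
    """Coefficient of variation (sample SD / mean) with NA-dropping.

    NA inputs are removed first; NA if fewer than 2 finite values remain or
    the mean is 0.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 2:
        return np.nan
    mu = v.mean()
    if mu == 0:
        return np.nan
    return float(v.std(ddof=1) / mu)


def compute_all_metrics(ischt: SCHT) -> "ComplexityTable":
    """Compute all seven metrics per gene, plus per-(gene, cell type) values.

    On a plain (non-integrated) SCHT only idi_intra and idi_inter are
    defined; cell-type metrics are NA with reason 'no_cell_types'.
    """
    rows = []
    type_rows = []
    integrated = isinstance(ischt, IntegratedSCHT) and ischt.by_type
    for g in ischt.genes:
        X = ischt.matrices[g]
        rec = {
            "gene_id": g,
            "idi_intra": idi_intra(X),
            "idi_inter": idi_inter(X),
            "het": np.nan,
            "spec": np.nan,
            "het_var": np.nan,
            "diff_var": np.nan,
            "coexp_var": np.nan,
            "n_cell_types": 0,
            "na_reason": "",
        }
        if integrated:
            per_type = ischt.by_type.get(g, {})
            union = ischt.isoforms[g]
            pos = {t: i for i, t in enumerate(union)}
            profiles = []
            het_vals, intra_vals = [], []
            for k, entry in per_type.items():
                Xk = entry["X"]
                het_k = het_per_type(Xk)
                intra_k = idi_intra(Xk)
                het_vals.append(het_k)
                intra_vals.append(intra_k)
                prof = np.zeros(len(union))
                prof[[pos[t] for t in entry["isoforms"]]] = _type_profile(Xk)
                profiles.append(prof)
                type_rows.append(
                    {
                        "gene_id": g,
                        "cell_type": k,
                        "idi_intra_k": intra_k,
                        "het_k": het_k,
                        "n_cells": Xk.shape[1],
                        "n_isoforms": Xk.shape[0],
                    }
                )
            S = len(per_type)
            rec["n_cell_types"] = S
            finite_het = [h for h in het_vals if np.isfinite(h)]
            rec["het"] = float(np.mean(finite_het)) if finite_het else np.nan
            if S >= 2:
                rec["spec"], js_pairs = spec_metric(profiles, return_pairs=True)
                rec["diff_var"] = cv_metric(js_pairs)
                rec["het_var"] = cv_metric(het_vals)
                rec["coexp_var"] = cv_metric(intra_vals)
            else:
                rec["na_reason"] = "single_cell_type"
        else:
            rec["na_reason"] = "no_cell_types"
        rows.append(rec)
    metrics = pd.DataFrame(rows).set_index("gene_id")
    cell_type_metrics = pd.DataFrame(
        type_rows,
        columns=["gene_id", "cell_type", "idi_intra_k", "het_k", "n_cells", "n_isoforms"],
    )
    return ComplexityTable(metrics, cell_type_metrics)


class ComplexityTable:
    """Per-gene metric table plus long-format per-cell-type breakdown."""

    def __init__(self, metrics: pd.DataFrame, cell_type_metrics: pd.DataFrame):
        self.metrics = metrics
        self.cell_type_metrics = cell_type_metrics

    def to_tsv(self, path, per_type_path=None) -> None:
        self.metrics.to_csv(path, sep="\t", na_rep="NA")
        if per_type_path is not None:
            self.cell_type_metrics.to_csv(per_type_path, sep="\t", index=False, na_rep="NA")

    @classmethod
    def from_tsv(cls, path, per_type_path=None) -> "ComplexityTable":
        metrics = pd.read_csv(path, sep="\t", index_col=0, na_values="NA")
        per_type = (
            pd.read_csv(per_type_path, sep="\t", na_values="NA")
            if per_type_path is not None
            else pd.DataFrame()
        )
        return cls(metrics, per_type)
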