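"""Isoform co-expression: correlation structure, conservation, switching.

Correlations are computed on per-cell isoform PROPORTIONS by default:
whether isoforms of one gene are co-expressed is a compositional question,
and proportions remove the shared library/expression-level signal that
inflates expression-scale correlations.  (Compositional closure makes
proportion correlations of few-isoform genes negatively biased; see the
methods documentation.)  ``use_proportions=False`` switches to the
normalized-expression scale.

Per cell type, the same correlations are evaluated on the type's
gene-expressing cells; Benjamini-Hochberg FDR runs over all tested
pair x type combinations.  Conservation labels per isoform pair:
``conserved`` (significant, same sign in >= 80% of evaluable types),
``mixed`` (significant with opposing signs in >= 2 types),
``cell_type_specific`` (significant in exactly one type), else ``none``.
Switching flags pairs with a strong negative correlation (r <= -r_cut,
inclusive) that is FDR-significant in at least one type.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .scht import IntegratedSCHT, SCHT

__all__ = [
    "CoexpressionResult",
    "isoform_correlation",
    "coexpression_all_celltypes",
    "conservation_analysis",
    "detect_switching",
    "bootstrap_pair_stability",
    "coexpression_stats",
    "analyze_gene",
]

METHODS = ("pearson", "spearman", "kendall")


def _corr(x: np.ndarray, y: np.ndarray, method: str):
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    elif method == "kendall":
        r, p = stats.kendalltau(x, y)  # tie-corrected tau-b
    else:
        raise ValueError(f"method must be one of {METHODS}")
    return float(r), float(p)


def _proportion_matrix(X: np.ndarray, use_proportions: bool) -> np.ndarray:
    """Columns restricted to gene-expressing cells; optionally closed to 1."""
    X = np.asarray(X, dtype=float)
    w = X.sum(axis=0)
    Xe = X[:, w > 0]
    if use_proportions:
        return Xe / Xe.sum(axis=0)
    return Xe


def isoform_correlation(
    X: np.ndarray,
    isoforms: list,
    method: str = "pearson",
    min_cells: int = 10,
    use_proportions: bool = True,
):
    """Pairwise isoform correlations on gene-expressing cells.

    Returns (r DataFrame, p DataFrame, n_cells).  All pairs are NA when
    fewer than ``min_cells`` cells express the gene; zero-variance isoforms
    are NA for their pairs.  Matrices are symmetric with unit diagonal.
    """
    P = _proportion_matrix(X, use_proportions)
    k = len(isoforms)
    R = np.full((k, k), np.nan)
    Pv = np.full((k, k), np.nan)
    np.fill_diagonal(R, 1.0)
    np.fill_diagonal(Pv, 0.0)
    n = P.shape[1]
    if n >= min_cells:
        for i in range(k):
            for j in range(i + 1, k):
                xi, xj = P[i], P[j]
                if np.ptp(xi) == 0 or np.ptp(xj) == 0:
                    continue
                r, p = _corr(xi, xj, method)
                R[i, j] = R[j, i] = r
                Pv[i, j] = Pv[j, i] = p
    rdf = pd.DataFrame(R, index=isoforms, columns=isoforms)
    pdf = pd.DataFrame(Pv, index=isoforms, columns=isoforms)
    return rdf, pdf, n


def coexpression_all_celltypes(
    ischt: IntegratedSCHT,
    gene: str,
    method: str = "pearson",
    min_cells: int = 10,
    use_proportions: bool = True,
):
    """Per-cell-type correlation matrices for one gene.

    Types with fewer than ``min_cells`` expressing cells or fewer than 2
    expressed isoforms are skipped with a reason.  Matrices are indexed on
    the gene's global isoform set (NA where an isoform is absent from the
    type).  Returns (per_type: dict, skipped: dict).
    """
    if gene not in ischt.matrices:
        raise KeyError(f"gene {gene!r} not in SCHT")
    union = ischt.isoforms[gene]
    per_type, skipped = {}, {}
    for k, entry in ischt.by_type.get(gene, {}).items():
        if entry["X"].shape[1] < min_cells:
            skipped[k] = f"only {entry['X'].shape[1]} expressing cells (min_cells={min_cells})"
            continue
        if entry["X"].shape[0] < 2:
            skipped[k] = "fewer than 2 expressed isoforms"
            continue
        r, p, n = isoform_correlation(
            entry["X"], entry["isoforms"], method, min_cells, use_proportions
        )
        per_type[k] = {
            "r": r.reindex(index=union, columns=union),
            "p": p.reindex(index=union, columns=union),
            "n_cells": n,
        }
    return per_type, skipped


def _pair_table(per_type: dict, union: list) -> pd.DataFrame:
    rows = []
    for k, mats in per_type.items():
        R, P = mats["r"], mats["p"]
        for i in range(len(union)):
            for j in range(i + 1, len(union)):
                a, b = union[i], union[j]
                r, p = R.loc[a, b], P.loc[a, b]
                if np.isfinite(r) and np.isfinite(p):
                    rows.append({"iso_a": a, "iso_b": b, "cell_type": k, "r": r, "p": p})
    return pd.DataFrame(rows, columns=["iso_a", "iso_b", "cell_type", "r", "p"])


def conservation_analysis(per_type: dict, union: list, q_threshold: float = 0.05,
                          consistency: float = 0.8) -> pd.DataFrame:
    """Label each isoform pair by cross-type conservation of its correlation.

    FDR (Benjamini-Hochberg) is applied over all tested pair x type entries.
    Labels are defined only for pairs evaluable in >= 2 types.
    """
    tab = _pair_table(per_type, union)
    if tab.empty:
        return tab.assign(q=[], label=[])
    tab = tab.copy()
    tab["q"] = multipletests(tab["p"].values, method="fdr_bh")[1]
    labels = []
    for (a, b), grp in tab.groupby(["iso_a", "iso_b"], sort=False):
        n_eval = len(grp)
        sig = grp[grp["q"] < q_threshold]
        pos = (sig["r"] > 0).sum()
        neg = (sig["r"] < 0).sum()
        if n_eval < 2:
            label = "not_evaluable"
        elif pos >= 1 and neg >= 1:
            label = "mixed"
        elif len(sig) / n_eval >= consistency and len(sig) >= 1:
            label = "conserved"
        elif len(sig) == 1:
            label = "cell_type_specific"
        else:
            label = "none"
        labels.append(((a, b), label))
    label_map = dict(labels)
    tab["label"] = [label_map[(a, b)] for a, b in zip(tab["iso_a"], tab["iso_b"])]
    return tab


def detect_switching(conservation_table: pd.DataFrame, r_cut: float = 0.3,
                     q_threshold: float = 0.05) -> pd.DataFrame:
    """Flag antagonistic pairs: r <= -r_cut (inclusive) with q < q_threshold in some type."""
    tab = conservation_table
    if tab.empty:
        return pd.DataFrame(columns=["iso_a", "iso_b"])
    hit = tab[(tab["r"] <= -r_cut) & (tab["q"] < q_threshold)]
    return hit[["iso_a", "iso_b"]].drop_duplicates().reset_index(drop=True)


def bootstrap_pair_stability(Xk: np.ndarray, isoforms: list, pair: tuple,
                             method: str = "pearson", n_iter: int = 100, seed: int = 0,
                             r_cut: float = 0.3, use_proportions: bool = True) -> float:
    """Fraction of resamples keeping the full-sample sign with |r| >= r_cut / 2."""
    P = _proportion_matrix(Xk, use_proportions)
    ia, ib = isoforms.index(pair[0]), isoforms.index(pair[1])
    x, y = P[ia], P[ib]
    r_full, _ = _corr(x, y, method)
    sign = np.sign(r_full)
    rng = np.random.default_rng(seed)
    n = x.size
    stable = 0
    for _ in range(n_iter):
        idx = rng.integers(0, n, n)
        xi, yi = x[idx], y[idx]
        if np.ptp(xi) == 0 or np.ptp(yi) == 0:
            continue
        r, _ = _corr(xi, yi, method)
        if np.sign(r) == sign and abs(r) >= r_cut / 2:
            stable += 1
    return stable / n_iter


def coexpression_stats(conservation_table: pd.DataFrame, switching: pd.DataFrame | None = None) -> dict:
    """Tallies over the analysis: pairs per label, significance fractions."""
    if conservation_table.empty:
        return {
            "n_pairs": 0,
            "n_tests": 0,
            "label_counts": {},
            "label_fractions": {},
            "fraction_significant": 0.0,
            "n_switching_pairs": 0,
        }
    pairs = conservation_table.drop_duplicates(["iso_a", "iso_b"])
    counts = pairs["label"].value_counts().to_dict()
    evaluable = pairs[pairs["label"] != "not_evaluable"]
    fractions = (
        (evaluable["label"].value_counts() / len(evaluable)).to_dict() if len(evaluable) else {}
    )
    return {
        "n_pairs": int(len(pairs)),
        "n_tests": int(len(conservation_table)),
        "label_counts": counts,
        "label_fractions": fractions,
        "fraction_significant": float((conservation_table["q"] < 0.05).mean()),
        "n_switching_pairs": 0 if switching is None else int(len(switching)),
    }


@dataclass
class CoexpressionResult:
    """Bundle of the per-gene analysis for export."""

    gene: str
    method: str
    global_r: pd.DataFrame
    global_p: pd.DataFrame
    n_cells: int
    per_type: dict
    skipped: dict
    conservation: pd.DataFrame
    switching: pd.DataFrame
    stats: dict = field(default_factory=dict)

    def to_long(self) -> pd.DataFrame:
        """Long-format (gene, iso_a, iso_b, cell_type, r, p, q, label, switching)."""
        tab = self.conservation.copy()
        if tab.empty:
            return pd.DataFrame(
                columns=["gene", "iso_a", "iso_b", "cell_type", "r", "p", "q", "label", "switching"]
            )
        sw = {tuple(t) for t in self.switching[["iso_a", "iso_b"]].itertuples(index=False)}
        tab.insert(0, "gene", self.gene)
        tab["switching"] = [((a, b) in sw) for a, b in zip(tab["iso_a"], tab["iso_b"])]
        return tab


def analyze_gene(
    ischt: IntegratedSCHT,
    gene: str,
    method: str = "pearson",
    min_cells: int = 10,
    r_cut: float = 0.3,
    q_threshold: float = 0.05,
    use_proportions: bool = True,
) -> CoexpressionResult:
    """Run the full co-expression suite for one gene."""
    R, P, n = isoform_correlation(
        ischt.matrices[gene], ischt.isoforms[gene], method, min_cells, use_proportions
    )
    per_type, skipped = coexpression_all_celltypes(ischt, gene, method, min_cells, use_proportions)
    cons = conservation_analysis(per_type, ischt.isoforms[gene], q_threshold)
    sw = detect_switching(cons, r_cut, q_threshold)
    res = CoexpressionResult(gene, method, R, P, n, per_type, skipped, cons, sw)
    res.stats = coexpression_stats(cons, sw)
    return res
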