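"""Dropout-perturbation study: metric stability under added sparsity.

Additional random dropouts (Bernoulli thinning of non-zero counts) are
introduced into the RAW isoform matrix at increasing rates, the full
pipeline (QC -> normalization -> HVG -> hierarchical tensor -> metrics) is
re-run, and each metric's per-gene distribution is compared against the
unperturbed baseline via the overlap coefficient (integral of the pointwise
minimum of the two KDE densities) and Cliff's delta effect size.
Distributions are compared over the intersection of genes surviving both
pipelines, preventing composition artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

from .complexity import METRICS, compute_all_metrics
from .matrix import CellMetadata, CountMatrix, TranscriptInfo, aggregate_gene_counts
from .scht import QCParams, create_scht

__all__ = [
    "perturb_dropout",
    "overlap_coefficient",
    "cliffs_delta",
    "effect_size_band",
    "run_dropout_study",
    "RobustnessResult",
]

DEFAULT_RATES = (0.1, 0.2, 0.3, 0.4, 0.5)


def perturb_dropout(raw: CountMatrix, rate: float, seed: int = 0) -> CountMatrix:
    """Set each non-zero entry to 0 independently with probability ``rate``.

    Zeros are untouched; deterministic for a fixed seed.
    """
    if not 0.0 < rate < 1.0:
        raise ValueError("dropout rate must be in (0, 1)")
    rng = np.random.default_rng(seed)
    vals = sp.csr_matrix(raw.values, copy=True)
    vals.eliminate_zeros()
    keep = rng.random(vals.nnz) >= rate
    vals.data = vals.data * keep
    vals.eliminate_zeros()
    return CountMatrix(vals, raw.features, raw.cells, raw.layer_tag)


def overlap_coefficient(a, b, grid_size: int = 512) -> float:
    """Integral of min(f_a, f_b) for KDE densities on a shared grid.

    Bandwidth is Silverman's rule on the pooled sample, shared by both
    densities; identical samples give 1 (within numerical tolerance) and
    well-separated samples give ~0.  Degenerate (constant) samples fall
    back to a shared-bin histogram overlap.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs >= 2 finite values")
    pooled = np.concatenate([a, b])
    sd = pooled.std(ddof=1)
    iqr = stats.iqr(pooled)
    sigma = min(sd, iqr / 1.349) if iqr > 0 else sd
    bw = 0.9 * sigma * pooled.size ** (-1 / 5)
    if bw <= 0:  # constant sample(s): histogram fallback
        lo, hi = pooled.min(), pooled.max()
        if lo == hi:
            return 1.0 if (a.min() == b.min()) else 0.0
        bins = np.linspace(lo, hi, 32)
        ha, _ = np.histogram(a, bins=bins, density=False)
        hb, _ = np.histogram(b, bins=bins, density=False)
        return float(np.minimum(ha / a.size, hb / b.size).sum())
    lo = pooled.min() - 4 * bw
    hi = pooled.max() + 4 * bw
    grid = np.linspace(lo, hi, grid_size)
    fa = stats.gaussian_kde(a, bw_method=bw / max(a.std(ddof=1), 1e-12))(grid) if a.std(ddof=1) > 0 else None
    fb = stats.gaussian_kde(b, bw_method=bw / max(b.std(ddof=1), 1e-12))(grid) if b.std(ddof=1) > 0 else None
    if fa is None:
        fa = stats.norm.pdf(grid, a[0], bw)
    if fb is None:
        fb = stats.norm.pdf(grid, b[0], bw)
    return float(np.trapezoid(np.minimum(fa, fb), grid))


def cliffs_delta(a, b) -> float:
    """(#{a_i > b_j} - #{a_i < b_j}) / (|a| |b|), in [-1, 1]; antisymmetric."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("samples must be non-empty")
    bs = np.sort(b)
    gt = np.searchsorted(bs, a, side="left").sum()  # b_j < a_i
    ge = np.searchsorted(bs, a, side="right").sum()  # b_j <= a_i
    lt = a.size * b.size - ge
    return float((gt - lt) / (a.size * b.size))


def effect_size_band(delta: float) -> str:
    """Qualitative Cliff's-delta bands: negligible < 0.147 <= small < 0.33 <= medium < 0.474 <= large."""
    d = abs(delta)
    if d < 0.147:
        return "negligible"
    if d < 0.33:
        return "small"
    if d < 0.474:
        return "medium"
    return "large"


@dataclass
class RobustnessResult:
    """Per (metric, rate) stability summary plus per-iteration values."""

    table: pd.DataFrame  # metric, rate, iteration, overlap, delta
    failures: list

    def summary(self) -> pd.DataFrame:
        g = self.table.groupby(["metric", "rate"])
        out = g.agg(
            mean_overlap=("overlap", "mean"),
            sd_overlap=("overlap", "std"),
            mean_delta=("delta", "mean"),
            n_iterations=("overlap", "size"),
        ).reset_index()
        out["effect_band"] = out["mean_delta"].map(effect_size_band)
        return out


def _metric_distributions(gene, iso, info, meta, params):
    scht, _ = create_scht(gene, iso, info, meta, params)
    table = compute_all_metrics(scht).metrics
    return table


def run_dropout_study(
    gene: CountMatrix,
    iso: CountMatrix,
    info: TranscriptInfo,
    meta: CellMetadata,
    params: QCParams | None = None,
    rates=DEFAULT_RATES,
    n_iter: int = 20,
    seed: int = 0,
    metrics=METRICS,
) -> RobustnessResult:
    """For each rate x iteration: perturb raw isoform counts, re-run the
    pipeline, and compare each metric's per-gene distribution to baseline.

    The gene matrix is re-aggregated from the perturbed isoform matrix so
    QC and HVG selection see consistent data.  Iteration failures (e.g. QC
    leaving nothing) are recorded and the study continues.
    """
    baseline = _metric_distributions(gene, iso, info, meta, params)
    rows, failures = [], []
    rng = np.random.default_rng(seed)
    for rate in rates:
        for it in range(n_iter):
            sub_seed = int(rng.integers(0, 2**31 - 1))
            try:
                iso_p = perturb_dropout(iso, rate, seed=sub_seed)
                gene_p = aggregate_gene_counts(iso_p, info)
                perturbed = _metric_distributions(gene_p, iso_p, info, meta, params)
            except Exception as exc:  # noqa: BLE001 - study continues
                failures.append({"rate": rate, "iteration": it, "error": str(exc)})
                continue
            shared = baseline.index.intersection(perturbed.index)
            for metric in metrics:
                b = baseline.loc[shared, metric].dropna()
                p = perturbed.loc[shared, metric].dropna()
                common = b.index.intersection(p.index)
                if len(common) < 20:
                    continue
                rows.append(
                    {
                        "metric": metric,
                        "rate": rate,
                        "iteration": it,
                        "overlap": overlap_coefficient(b.loc[common], p.loc[common]),
                        "delta": cliffs_delta(p.loc[common], b.loc[common]),
                        "n_genes": len(common),
                    }
                )
    return RobustnessResult(pd.DataFrame(rows), failures)
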