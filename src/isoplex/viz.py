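"""Data-faithful visual outputs: landscapes, density contours, isoform profiles.

Every figure has a data-table twin; analyses and tests consume the tables,
the figures are renderings only.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
from scipy import stats  # noqa: E402

from .scht import IntegratedSCHT
from .complexity import _type_profile  # shared mean-proportion definition

__all__ = ["plot_landscape", "plot_density", "isoform_profile", "isoform_transitions"]


def plot_landscape(metrics: pd.DataFrame, dim_x: str, dim_y: str, thresholds: dict):
    """Bivariate complexity landscape with threshold lines + quadrant stats.

    Quadrants (x = e.g. diversity, y = e.g. specificity):
    Q1 = high/high, Q2 = low x / high y, Q3 = low/low, Q4 = high x / low y.
    Percentages are over genes with both dimensions non-NA.
    Returns (figure, quadrant DataFrame).
    """
    for dim in (dim_x, dim_y):
        if dim not in metrics.columns or metrics[dim].dropna().empty:
            raise ValueError(f"dimension {dim!r} missing or all-NA")
    tx = _thr(thresholds, dim_x)
    ty = _thr(thresholds, dim_y)
    sub = metrics[[dim_x, dim_y]].dropna()
    x, y = sub[dim_x].values, sub[dim_y].values
    quads = {
        "Q1": (x >= tx) & (y >= ty),
        "Q2": (x < tx) & (y >= ty),
        "Q3": (x < tx) & (y < ty),
        "Q4": (x >= tx) & (y < ty),
    }
    n = len(sub)
    qdf = pd.DataFrame(
        {
            "quadrant": list(quads),
            "count": [int(m.sum()) for m in quads.values()],
            "percent": [100.0 * m.sum() / n if n else 0.0 for m in quads.values()],
        }
    )
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(x, y, s=12, alpha=0.7)
    ax.axvline(tx, ls="--", c="grey")
    ax.axhline(ty, ls="--", c="grey")
    ax.set_xlabel(dim_x)
    ax.set_ylabel(dim_y)
    ax.set_title(f"{dim_x} vs {dim_y} (n={n})")
    return fig, qdf


def _thr(thresholds, dim):
    t = thresholds[dim]
    return float(getattr(t, "threshold", t))


def plot_density(metrics: pd.DataFrame, dim_x: str, dim_y: str, grid_size: int = 100):
    """2-D KDE contours over the landscape scatter.

    Returns (figure, info dict) with the density grid (normalized to
    integrate to ~1) and the number of local density modes.  Degenerate
    variance falls back to scatter only (density grid None).
    """
    sub = metrics[[dim_x, dim_y]].dropna()
    if len(sub) < 20:
        raise ValueError("need >= 20 genes with both dimensions for density contours")
    x, y = sub[dim_x].values, sub[dim_y].values
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(x, y, s=10, alpha=0.5)
    ax.set_xlabel(dim_x)
    ax.set_ylabel(dim_y)
    if np.std(x) == 0 or np.std(y) == 0:
        return fig, {"density": None, "n_modes": 0, "degenerate": True}
    kde = stats.gaussian_kde(np.vstack([x, y]))
    # pad the grid by ~3 bandwidths so the density mass is captured
    bw_x, bw_y = np.sqrt(np.diag(kde.covariance))
    gx = np.linspace(x.min() - 3 * bw_x, x.max() + 3 * bw_x, grid_size)
    gy = np.linspace(y.min() - 3 * bw_y, y.max() + 3 * bw_y, grid_size)
    GX, GY = np.meshgrid(gx, gy)
    Z = kde(np.vstack([GX.ravel(), GY.ravel()])).reshape(GX.shape)
    ax.contour(GX, GY, Z, levels=8)
    n_modes = _count_2d_modes(Z)
    return fig, {
        "density": Z,
        "grid_x": gx,
        "grid_y": gy,
        "n_modes": n_modes,
        "degenerate": False,
    }


def _count_2d_modes(Z: np.ndarray) -> int:
    """Strict local maxima of the density grid above 10% of the peak."""
    inner = Z[1:-1, 1:-1]
    neighbors = [
        Z[:-2, 1:-1], Z[2:, 1:-1], Z[1:-1, :-2], Z[1:-1, 2:],
        Z[:-2, :-2], Z[:-2, 2:], Z[2:, :-2], Z[2:, 2:],
    ]
    is_max = np.all([inner > nb for nb in neighbors], axis=0)
    return int((is_max & (inner > 0.1 * Z.max())).sum())


def isoform_profile(ischt: IntegratedSCHT, gene: str, order: list | None = None,
                    minor_cutoff: float = 0.05):
    """Mean isoform-usage proportions per cell type (columns sum to 1).

    Isoforms below ``minor_cutoff`` in every type are pooled into a
    "minor" row.  Returns (DataFrame, figure).
    """
    if gene not in ischt.matrices:
        raise KeyError(f"gene {gene!r} not in SCHT")
    union = ischt.isoforms[gene]
    pos = {t: i for i, t in enumerate(union)}
    cols = {}
    for k, entry in ischt.by_type.get(gene, {}).items():
        prof = np.zeros(len(union))
        prof[[pos[t] for t in entry["isoforms"]]] = _type_profile(entry["X"])
        cols[k] = prof
    if not cols:  # no cell-type partition: single global column
        cols["all"] = _type_profile(ischt.matrices[gene])
    df = pd.DataFrame(cols, index=union)
    if order is not None:
        missing = [k for k in order if k not in df.columns]
        if missing:
            raise KeyError(f"unknown cell types/stages {missing}")
        df = df[order]
    minor = (df < minor_cutoff).all(axis=1)
    if minor.any() and (~minor).any():
        pooled = df.loc[minor].sum(axis=0)
        df = df.loc[~minor]
        df.loc["minor"] = pooled
    fig, ax = plt.subplots(figsize=(6, 4))
    bottom = np.zeros(df.shape[1])
    for iso, row in df.iterrows():
        ax.bar(df.columns, row.values, bottom=bottom, label=str(iso))
        bottom += row.values
    ax.set_ylabel("isoform usage proportion")
    ax.set_title(gene)
    ax.legend(fontsize=6)
    return df, fig


def isoform_transitions(ischt: IntegratedSCHT, gene: str, stages: list):
    """Isoform proportion trajectories across ordered stages + switch events.

    A switch event is a change of the dominant isoform between consecutive
    stages.  Returns (trajectory DataFrame, switch list, figure).
    """
    df, _ = isoform_profile(ischt, gene, order=stages, minor_cutoff=0.0)
    switches = []
    dominant = df.idxmax(axis=0)
    for a, b in zip(stages[:-1], stages[1:]):
        if dominant[a] != dominant[b]:
            switches.append({"from_stage": a, "to_stage": b,
                             "from_isoform": dominant[a], "to_isoform": dominant[b]})
    fig, ax = plt.subplots(figsize=(6, 4))
    for iso, row in df.iterrows():
        ax.plot(stages, row.values, marker="o", label=str(iso))
    ax.set_ylabel("isoform usage proportion")
    ax.set_title(gene)
    ax.legend(fontsize=6)
    return df, switches, fig
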