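"""Distribution-aware threshold determination and binary gene classification.

Complexity-metric distributions are heterogeneous (bimodal, zero-inflated,
skewed), so a single global rule fails.  The pipeline is:

1. diagnose the distribution (multimodal / zero_inflated /
   extremely_skewed / moderately_skewed / unimodal) by combining a
   dip-type unimodality test, KDE peak/valley analysis, and BIC-selected
   Gaussian mixtures;
2. apply a class-specific threshold algorithm with a hierarchical
   fallback chain ending in a 75th-percentile terminal fallback;
3. sanity-clamp the threshold into the [P5, P95] band;
4. validate by bootstrap resampling (default 100 iterations) and, when the
   sample is large enough, stratified k-fold stability, combining both into
   a [0, 1] reliability score.

Classification is binary per dimension: metric value >= threshold earns the
dimension's "high" label; NA metric values keep NA labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.mixture import GaussianMixture
from sklearn.model_selection import StratifiedKFold

from .complexity import METRICS

__all__ = [
    "DistributionDiagnosis",
    "ThresholdResult",
    "ThresholdConfig",
    "dip_statistic",
    "dip_test",
    "detect_zero_inflation",
    "diagnose_distribution",
    "determine_threshold",
    "sanity_check",
    "bootstrap_threshold",
    "kfold_threshold_stability",
    "reliability_score",
    "threshold_with_validation",
    "classify_genes",
    "find_complexity_pattern",
    "LABELS",
]

LABELS = {
    "idi_intra": ("Strong Isoform Co-expression", "Weak Isoform Co-expression"),
    "idi_inter": ("High Isoform Diversity", "Low Isoform Diversity"),
    "het": ("High Cellular Heterogeneity", "Low Cellular Heterogeneity"),
    "spec": ("Cell-Type-Specific Isoform Expression", "Cell-Type-Independent Isoform Expression"),
    "het_var": ("Variable Heterogeneity Across Cell Types", "Consistent Heterogeneity Across Cell Types"),
    "diff_var": ("High Cell-Type Distinctions", "Low Cell-Type Distinctions"),
    "coexp_var": ("Cell-Type-Adaptive Co-expression", "Cell-Type-Consistent Co-expression"),
}


@dataclass
class ThresholdConfig:
    """Tunable constants of the diagnosis/threshold pipeline.

    The published description names the methods but leaves these constants
    open; all are exposed here with the package defaults.
    """

    dip_alpha: float = 0.05
    dip_n_boot: int = 200
    valley_depth_frac: float = 0.25  # KDE valley must dip 25% below lower flanking peak
    peak_height_frac: float = 0.05  # peaks below 5% of the tallest are noise
    gmm_separation: float = 2.0  # component means > 2 pooled SD apart
    skew_moderate: float = 1.0
    skew_extreme: float = 2.0
    near_zero_range_frac: float = 0.01
    near_zero_iqr_frac: float = 0.05
    zero_bin_ratio: float = 3.0  # first/second FD-bin ratio (strict >)
    kde_bw_scale: float = 0.9  # Silverman bandwidth x 0.9
    grid_size: int = 512
    gap_frac: float = 0.25  # zero-inflated gap must span 25% of the range
    terminal_percentile: float = 75.0
    sanity_band: tuple = (5.0, 95.0)
    yj_grid: tuple = (-2.0, 2.0, 0.05)


@dataclass
class DistributionDiagnosis:
    dist_class: str  # multimodal | zero_inflated | extremely_skewed | moderately_skewed | unimodal
    dip_p: float
    kde_peaks: int
    gmm_k_by_bic: int
    skewness: float
    zero_inflation: dict
    multimodal_votes: dict
    transform: str = "none"  # 'none' or 'yeo_johnson'
    yj_lambda: float | None = None
    flags: list = field(default_factory=list)  # 'low_data', 'degenerate', ...


@dataclass
class ThresholdResult:
    metric: str
    threshold: float
    method_trace: list  # [(method_name, succeeded: bool), ...]
    method_used: str
    method_rank: str  # primary | secondary | terminal
    diagnosis: DistributionDiagnosis
    bootstrap: dict
    kfold_cv: float
    reliability: float
    sanity_adjusted: bool

    def to_dict(self) -> dict:
        d = {
            "metric": self.metric,
            "threshold": self.threshold,
            "method_trace": [list(t) for t in self.method_trace],
            "method_used": self.method_used,
            "method_rank": self.method_rank,
            "distribution_class": self.diagnosis.dist_class,
            "dip_p": self.diagnosis.dip_p,
            "kde_peaks": self.diagnosis.kde_peaks,
            "gmm_k_by_bic": self.diagnosis.gmm_k_by_bic,
            "skewness": self.diagnosis.skewness,
            "transform": self.diagnosis.transform,
            "bootstrap": self.bootstrap,
            "kfold_cv": self.kfold_cv,
            "reliability": self.reliability,
            "sanity_adjusted": self.sanity_adjusted,
        }
        return d


# ---------------------------------------------------------------------------
# Dip-type unimodality test
# ---------------------------------------------------------------------------

_DIP_NULL_CACHE: dict = {}
_DIP_MAX_N = 200


def _unimodal_envelope_dev(xs: np.ndarray) -> float:
    """Max |ecdf - best unimodal envelope| minimized over mode positions.

    For every candidate mode m the empirical cdf is fitted by its greatest
    convex minorant on [x_0, x_m] and least concave majorant on
    [x_m, x_{n-1}]; the statistic is half the smallest achievable maximal
    deviation (Hartigan-type dip).
    """
    n = xs.size
    F = (np.arange(1, n + 1) - 0.5) / n

    def prefix_devs(x, f):
        # incremental lower convex hull; deviation of ecdf above hull per prefix
        hull = [0]
        devs = np.empty(n)
        devs[0] = 0.0
        for m in range(1, n):
            while len(hull) >= 2:
                i, j = hull[-2], hull[-1]
                # cross product test for lower hull in (x, f)
                if (f[j] - f[i]) * (x[m] - x[i]) >= (f[m] - f[i]) * (x[j] - x[i]):
                    hull.pop()
                else:
                    break
            hull.append(m)
            hx = x[np.array(hull)]
            hf = f[np.array(hull)]
            fit = np.interp(x[: m + 1], hx, hf)
            devs[m] = np.abs(f[: m + 1] - fit).max()
        return devs

    dev_left = prefix_devs(xs, F)
    # suffix concave majorant == prefix convex minorant of reversed, negated data
    dev_right = prefix_devs(-xs[::-1], -F[::-1])[::-1]
    return 0.5 * float(np.maximum(dev_left, dev_right).min())


def dip_statistic(values) -> float:
    """Dip-type departure-from-unimodality statistic (0 = perfectly unimodal)."""
    x = np.sort(np.asarray(values, dtype=float))
    x = x[np.isfinite(x)]
    n = x.size
    if n < 4 or x[0] == x[-1]:
        return 0.0
    if n > _DIP_MAX_N:  # deterministic thinning keeps the test O(n log n)
        x = x[np.linspace(0, n - 1, _DIP_MAX_N).astype(int)]
    return _unimodal_envelope_dev(x)


def dip_test(values, n_boot: int = 200) -> tuple[float, float]:
    """(statistic, p-value) with the null calibrated on uniform samples.

    The null distribution is simulated once per sample size with a fixed
    internal seed and cached, so the test is deterministic.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    stat = dip_statistic(x)
    n = min(x.size, _DIP_MAX_N)
    if n < 4:
        return stat, 1.0
    key = (n, n_boot)
    if key not in _DIP_NULL_CACHE:
        rng = np.random.default_rng(123456789)
        _DIP_NULL_CACHE[key] = np.sort(
            [_unimodal_envelope_dev(np.sort(rng.random(n))) for _ in range(n_boot)]
        )
    null = _DIP_NULL_CACHE[key]
    p = float((np.sum(null >= stat) + 1) / (len(null) + 1))
    return stat, p


# ---------------------------------------------------------------------------
# KDE helpers
# ---------------------------------------------------------------------------

def _kde_density(values: np.ndarray, config: ThresholdConfig, grid=None):
    kde = stats.gaussian_kde(values, bw_method="silverman")
    kde.set_bandwidth(kde.factor * config.kde_bw_scale)
    if grid is None:
        lo, hi = values.min(), values.max()
        pad = 0.05 * (hi - lo) if hi > lo else 1.0
        grid = np.linspace(lo - pad, hi + pad, config.grid_size)
    return grid, kde(grid)


def _peaks_and_valleys(grid: np.ndarray, density: np.ndarray):
    d = np.diff(density)
    sign = np.sign(d)
    peaks = [i + 1 for i in range(len(sign) - 1) if sign[i] > 0 and sign[i + 1] <= 0]
    valleys = [i + 1 for i in range(len(sign) - 1) if sign[i] < 0 and sign[i + 1] >= 0]
    return peaks, valleys


def _significant_peaks(grid, density, config: ThresholdConfig):
    """Peaks filtered by the valley-depth rule (>= 25% dip below the lower flank)."""
    peaks, _ = _peaks_and_valleys(grid, density)
    peaks = [p for p in peaks if density[p] >= config.peak_height_frac * density.max()]
    if len(peaks) <= 1:
        return peaks
    peaks = sorted(peaks)
    kept = [peaks[0]]
    for p in peaks[1:]:
        prev = kept[-1]
        valley_h = density[prev:p + 1].min()
        lower_flank = min(density[prev], density[p])
        if valley_h <= (1.0 - config.valley_depth_frac) * lower_flank:
            kept.append(p)
        elif density[p] > density[prev]:
            kept[-1] = p  # merge: keep the taller of the merged pair
    return kept


# ---------------------------------------------------------------------------
# Zero inflation
# ---------------------------------------------------------------------------

def detect_zero_inflation(values, config: ThresholdConfig | None = None) -> dict:
    """Histogram-based zero-inflation evidence.

    near-zero threshold = min + max(1% of range, 5% of IQR); bin width by
    Freedman-Diaconis (2*IQR*n^-1/3, falling back to range-based bins when
    IQR = 0); inflation declared when first/second bin ratio > 3 (strict).
    """
    config = config or ThresholdConfig()
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    rng_ = x.max() - x.min()
    iqr = stats.iqr(x)
    near_zero = x.min() + max(config.near_zero_range_frac * rng_, config.near_zero_iqr_frac * iqr)
    if iqr > 0:
        bin_width = 2.0 * iqr * x.size ** (-1.0 / 3.0)
    else:
        bin_width = rng_ / 10.0 if rng_ > 0 else 1.0
    n_bins = max(int(np.ceil(rng_ / bin_width)), 2) if rng_ > 0 else 2
    counts, edges = np.histogram(x, bins=min(n_bins, 512))
    ratio = counts[0] / counts[1] if counts[1] > 0 else np.inf
    zero_frac = float((x <= near_zero).mean())
    inflated = bool(ratio > config.zero_bin_ratio and zero_frac >= 0.2)
    return {
        "near_zero_threshold": float(near_zero),
        "fd_bin_width": float(bin_width),
        "first_second_bin_ratio": float(ratio),
        "zero_fraction": zero_frac,
        "inflated": inflated,
    }


# ---------------------------------------------------------------------------
# Diagnosis
# ---------------------------------------------------------------------------

def diagnose_distribution(values, config: ThresholdConfig | None = None) -> DistributionDiagnosis:
    """Classify a metric distribution; all three multimodality votes recorded."""
    config = config or ThresholdConfig()
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    flags = []
    if x.size < 20:
        flags.append("low_data")
    if x.size == 0 or x.max() == x.min():
        flags.append("degenerate")
        return DistributionDiagnosis(
            "unimodal", 1.0, 1 if x.size else 0, 1, 0.0,
            {"inflated": False}, {"dip": False, "kde": False, "gmm": False}, flags=flags,
        )
    if x.size < 50:
        flags.append("n<50")

    dip_stat, dip_p = dip_test(x, config.dip_n_boot)
    grid, density = _kde_density(x, config)
    sig_peaks = _significant_peaks(grid, density, config)
    skewness = float(stats.skew(x))
    zero_ev = detect_zero_inflation(x, config)

    gmm_k, gmm_sep = _gmm_k_by_bic(x, config)
    votes = {
        "dip": dip_p < config.dip_alpha,
        "kde": len(sig_peaks) >= 2,
        "gmm": gmm_k >= 2 and gmm_sep,
    }

    if x.size < 20:
        dist_class = "unimodal"
    elif zero_ev["inflated"]:
        dist_class = "zero_inflated"
        nz = x[x > zero_ev["near_zero_threshold"]]
        if nz.size >= 20:
            nz_peaks = _significant_peaks(*_kde_density(nz, config), config)
            if len(nz_peaks) >= 2:
                flags.append("zero_inflated_multimodal_nonzero")
    elif sum(votes.values()) >= 2:
        dist_class = "multimodal"
    elif abs(skewness) > config.skew_extreme:
        dist_class = "extremely_skewed"
    elif abs(skewness) > config.skew_moderate:
        dist_class = "moderately_skewed"
    else:
        dist_class = "unimodal"

    diag = DistributionDiagnosis(
        dist_class, dip_p, len(sig_peaks), gmm_k, skewness, zero_ev, votes, flags=flags
    )
    if dist_class == "extremely_skewed":
        diag.transform = "yeo_johnson"
        diag.yj_lambda = _yj_lambda_mle(x, config)
    return diag


def _gmm_k_by_bic(x: np.ndarray, config: ThresholdConfig, ks=(1, 2, 3)):
    X = x.reshape(-1, 1)
    best_k, best_bic, best_model = 1, np.inf, None
    for k in ks:
        if x.size < 5 * k:
            continue
        gm = GaussianMixture(n_components=k, covariance_type="full", random_state=0, n_init=2)
        try:
            gm.fit(X)
        except ValueError:
            continue
        bic = gm.bic(X)
        if bic < best_bic:
            best_k, best_bic, best_model = k, bic, gm
    separated = False
    if best_model is not None and best_k >= 2:
        order = np.argsort(best_model.weights_)[::-1][:2]
        mu = best_model.means_.ravel()[order]
        var = best_model.covariances_.ravel()[order]
        pooled = np.sqrt(var.mean())
        separated = abs(mu[0] - mu[1]) > config.gmm_separation * pooled
    return best_k, separated


def _yj_lambda_mle(x: np.ndarray, config: ThresholdConfig) -> float:
    lo, hi, step = config.yj_grid
    grid = np.arange(lo, hi + step / 2, step)
    llf = [stats.yeojohnson_llf(lmb, x) for lmb in grid]
    return float(grid[int(np.argmax(llf))])


def _yj_forward(x, lmb):
    return stats.yeojohnson(x, lmbda=lmb)


def _yj_inverse(y, lmb):
    y = np.asarray(y, dtype=float)
    out = np.empty_like(y)
    pos = y >= 0
    if lmb != 0:
        out[pos] = np.power(np.maximum(y[pos] * lmb + 1, 0.0), 1.0 / lmb) - 1.0
    else:
        out[pos] = np.expm1(y[pos])
    if (2.0 - lmb) != 0:
        out[~pos] = 1.0 - np.power(np.maximum(1 - (2 - lmb) * y[~pos], 0.0), 1.0 / (2 - lmb))
    else:
        out[~pos] = 1.0 - np.exp(-y[~pos])
    return out


# ---------------------------------------------------------------------------
# Threshold algorithms
# ---------------------------------------------------------------------------

def _gmm2_boundary(x: np.ndarray) -> float | None:
    """Decision boundary between the two dominant components of a 2-GMM."""
    if np.unique(x).size < 3:
        return None
    gm = GaussianMixture(n_components=2, covariance_type="full", random_state=0, n_init=2)
    gm.fit(x.reshape(-1, 1))
    mu = gm.means_.ravel()
    sd = np.sqrt(gm.covariances_.ravel())
    w = gm.weights_
    lo, hi = np.sort(mu)
    if hi - lo < 1e-12:
        return None
    grid = np.linspace(lo, hi, 512)
    d0 = w[0] * stats.norm.pdf(grid, mu[0], sd[0])
    d1 = w[1] * stats.norm.pdf(grid, mu[1], sd[1])
    cross = np.where(np.diff(np.sign(d0 - d1)) != 0)[0]
    if cross.size == 0:
        return None
    # density-equality point closest to the midpoint between the means
    mid = 0.5 * (lo + hi)
    return float(grid[cross[np.argmin(np.abs(grid[cross] - mid))]])


def _multimodal_threshold(x, config):
    grid, density = _kde_density(x, config)
    peaks = _significant_peaks(grid, density, config)
    if len(peaks) >= 2:
        top2 = sorted(sorted(peaks, key=lambda i: -density[i])[:2])
        lo_i, hi_i = top2
        if hi_i - lo_i >= 2:
            valley = lo_i + int(np.argmin(density[lo_i:hi_i + 1]))
            return float(grid[valley])
    return None


def _skewed_threshold(x, diag, config):
    lmb = diag.yj_lambda if diag.yj_lambda is not None else _yj_lambda_mle(x, config)
    z = _yj_forward(x, lmb)
    p5, p95 = np.percentile(z, [5, 95])
    core = z[(z >= p5) & (z <= p95)]
    if core.size >= 10 and core.max() > core.min():
        grid, density = _kde_density(core, config)
        mode_i = int(np.argmax(density))
        curv = np.gradient(np.gradient(density, grid), grid)
        after = np.where(np.diff(np.sign(curv[mode_i:])) != 0)[0]
        if after.size:
            thr_z = grid[mode_i + after[0] + 1]
            return float(_yj_inverse(np.array([thr_z]), lmb)[0]), "inflection"
    thr_z = float(np.mean(z) + 0.5 * np.std(z, ddof=1))
    return float(_yj_inverse(np.array([thr_z]), lmb)[0]), "moment"


def _zero_inflated_threshold(x, diag, config):
    nzt = diag.zero_inflation.get("near_zero_threshold", x.min())
    zeros = x[x <= nzt]
    nonzero = x[x > nzt]
    if nonzero.size == 0:
        return None, None
    gap_low = float(zeros.max()) if zeros.size else float(x.min())
    gap_high = float(nonzero.min())
    rng_ = x.max() - x.min()
    if rng_ > 0 and (gap_high - gap_low) >= config.gap_frac * rng_:
        return 0.5 * (gap_low + gap_high), "gap"
    if nonzero.size >= 20:
        nz_peaks = _significant_peaks(*_kde_density(nonzero, config), config)
        if len(nz_peaks) >= 2:
            thr = _multimodal_threshold(nonzero, config)
            if thr is None:
                thr = _gmm2_boundary(nonzero)
            if thr is not None:
                return float(thr), "nonzero_mixture"
    g = stats.skew(nonzero) if nonzero.size >= 3 else 0.0
    pct = float(np.clip(50.0 + 10.0 * g, 25.0, 90.0))
    return float(np.percentile(nonzero, pct)), "adaptive_percentile"


def _unimodal_threshold(x, config):
    grid, density = _kde_density(x, config)
    med, p90 = np.percentile(x, [50, 90])
    _, valleys = _peaks_and_valleys(grid, density)
    inside = [v for v in valleys if med < grid[v] < p90]
    if inside:
        return float(grid[min(inside, key=lambda v: density[v])]), "density_valley"
    return None, None


def determine_threshold(values, diagnosis: DistributionDiagnosis, config: ThresholdConfig | None = None):
    """Class-specific threshold with hierarchical fallback.

    Returns (threshold, method_trace, method_used, method_rank); the
    terminal fallback (75th percentile) always yields a value.
    """
    config = config or ThresholdConfig()
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    trace: list = []

    def attempt(name, fn, rank):
        try:
            thr = fn()
        except Exception:  # noqa: BLE001 - fallback chain absorbs failures
            thr = None
        ok = thr is not None and np.isfinite(thr)
        trace.append((name, bool(ok)))
        return (float(thr), rank) if ok else None

    chain = []
    cls = diagnosis.dist_class
    if cls == "multimodal":
        chain = [
            ("kde_valley", lambda: _multimodal_threshold(x, config), "primary"),
            ("gmm_boundary", lambda: _gmm2_boundary(x), "secondary"),
        ]
    elif cls == "extremely_skewed":
        try:
            thr, how = _skewed_threshold(x, diagnosis, config)
        except Exception:  # noqa: BLE001
            thr, how = None, None
        if thr is not None and np.isfinite(thr):
            name = f"yeo_johnson_{how}"
            trace.append((name, True))
            rank = "primary" if how == "inflection" else "secondary"
            return float(thr), trace, name, rank
        trace.append(("yeo_johnson", False))
        chain = []
    elif cls == "zero_inflated":
        try:
            thr, how = _zero_inflated_threshold(x, diagnosis, config)
        except Exception:  # noqa: BLE001
            thr, how = None, None
        if thr is not None and np.isfinite(thr):
            name = f"zero_inflated_{how}"
            trace.append((name, True))
            rank = "primary" if how in ("gap", "nonzero_mixture") else "secondary"
            return float(thr), trace, name, rank
        trace.append(("zero_inflated", False))
        chain = []
    else:  # moderately_skewed / unimodal
        def _uni():
            thr, how = _unimodal_threshold(x, config)
            return thr
        chain = [
            ("density_valley", _uni, "primary"),
            ("gmm_boundary", lambda: _gmm2_boundary(x) if diagnosis.gmm_k_by_bic >= 2 else None, "secondary"),
            ("moment", lambda: float(np.mean(x) + 0.5 * np.std(x, ddof=1)), "secondary"),
        ]

    for name, fn, rank in chain:
        res = attempt(name, fn, rank)
        if res:
            thr, rank_ = res
            return thr, trace, name, rank_

    thr = float(np.percentile(x, config.terminal_percentile))
    trace.append(("terminal_percentile", True))
    return thr, trace, "terminal_percentile", "terminal"


def sanity_check(threshold: float, values, config: ThresholdConfig | None = None):
    """Clamp the threshold into the [P5, P95] band of the data (idempotent)."""
    config = config or ThresholdConfig()
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    lo, hi = np.percentile(x, config.sanity_band)
    adjusted = float(np.clip(threshold, lo, hi))
    return adjusted, bool(adjusted != threshold)


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def _threshold_once(x, diagnosis, config):
    thr, _, _, _ = determine_threshold(x, diagnosis, config)
    thr, _ = sanity_check(thr, x, config)
    return thr


def bootstrap_threshold(values, diagnosis, n_iter: int = 100, seed: int = 0,
                        config: ThresholdConfig | None = None) -> dict:
    """Resample-with-replacement stability of the threshold.

    The full-sample distribution class is held fixed across resamples so the
    bootstrap measures threshold stability, not classifier churn.  Returns
    percentile CI95, sd (ddof=1) and cv; cv is NA when sd = 0.
    """
    config = config or ThresholdConfig()
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    rng = np.random.default_rng(seed)
    thrs = np.array([
        _threshold_once(x[rng.integers(0, x.size, x.size)], diagnosis, config)
        for _ in range(n_iter)
    ])
    sd = float(thrs.std(ddof=1)) if n_iter > 1 else 0.0
    mean = float(thrs.mean())
    if sd < 1e-12 * max(1.0, abs(mean)):  # numerically constant resamples
        sd = 0.0
    cv = np.nan if (sd == 0.0 or mean == 0.0) else sd / abs(mean)
    lo, hi = np.percentile(thrs, [2.5, 97.5])
    return {"n_iter": int(n_iter), "ci95": (float(lo), float(hi)), "sd": sd, "cv": cv, "mean": mean}


def kfold_threshold_stability(values, diagnosis, k: int = 5, seed: int = 0,
                              config: ThresholdConfig | None = None) -> float:
    """CV of per-fold thresholds under stratified k-fold splitting.

    Folds are stratified by above/below the full-sample threshold; the
    threshold is recomputed on each training split.  NA when n < 10*k.
    """
    config = config or ThresholdConfig()
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 10 * k:
        return np.nan
    full_thr = _threshold_once(x, diagnosis, config)
    labels = (x >= full_thr).astype(int)
    if len(np.unique(labels)) < 2:
        return np.nan
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    thrs = []
    for train_idx, _ in skf.split(x.reshape(-1, 1), labels):
        thrs.append(_threshold_once(x[train_idx], diagnosis, config))
    thrs = np.asarray(thrs)
    mean = thrs.mean()
    if mean == 0:
        return np.nan
    return float(thrs.std(ddof=1) / abs(mean))


def reliability_score(method_rank: str, diagnosis: DistributionDiagnosis,
                      bootstrap: dict, kfold_cv: float) -> float:
    """[0, 1] reliability: method rank penalized by instability and data issues.

    base 1.0 / 0.75 / 0.5 (primary / secondary / terminal), multiplied by
    exp(-2 * bootstrap cv), exp(-1 * kfold cv) when available, and 0.8 per
    problematic-distribution flag (multimodal non-zero component of a
    zero-inflated metric; n < 50).  Monotone non-increasing in both cvs.
    """
    base = {"primary": 1.0, "secondary": 0.75, "terminal": 0.5}[method_rank]
    boot_cv = bootstrap.get("cv", np.nan)
    if np.isfinite(boot_cv):
        base *= float(np.exp(-2.0 * boot_cv))
    if kfold_cv is not None and np.isfinite(kfold_cv):
        base *= float(np.exp(-1.0 * kfold_cv))
    for flag in diagnosis.flags:
        if flag in ("zero_inflated_multimodal_nonzero", "n<50"):
            base *= 0.8
    return float(np.clip(base, 0.0, 1.0))


def threshold_with_validation(values, metric: str = "", n_boot: int = 100, kfold: int = 5,
                              seed: int = 0, config: ThresholdConfig | None = None) -> ThresholdResult:
    """Full pipeline: diagnose -> threshold -> sanity -> bootstrap/k-fold -> score."""
    config = config or ThresholdConfig()
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise ValueError(f"metric {metric!r}: no finite values to threshold")
    diag = diagnose_distribution(x, config)
    thr, trace, used, rank = determine_threshold(x, diag, config)
    thr, adjusted = sanity_check(thr, x, config)
    boot = bootstrap_threshold(x, diag, n_iter=n_boot, seed=seed, config=config)
    kf = kfold_threshold_stability(x, diag, k=kfold, seed=seed, config=config)
    rel = reliability_score(rank, diag, boot, kf)
    return ThresholdResult(metric, thr, trace, used, rank, diag, boot, kf, rel, adjusted)


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def classify_genes(metrics: pd.DataFrame, thresholds: dict) -> pd.DataFrame:
    """Binary labels per (gene, dimension); NA metric values keep NA labels.

    ``thresholds`` maps metric name -> ThresholdResult or plain float.
    value >= threshold earns the dimension's "high" label (inclusive).
    Dimensions without a threshold are skipped with a warning.
    """
    out = {}
    for metric in METRICS:
        if metric not in metrics.columns:
            continue
        if metric not in thresholds:
            warnings.warn(f"no threshold for dimension {metric!r}; skipped", stacklevel=2)
            continue
        thr = thresholds[metric]
        thr = thr.threshold if isinstance(thr, ThresholdResult) else float(thr)
        high, low = LABELS[metric]
        vals = metrics[metric]
        out[metric] = np.where(vals.isna(), None, np.where(vals >= thr, high, low))
    return pd.DataFrame(out, index=metrics.index)


def find_complexity_pattern(classification: pd.DataFrame, pattern: dict) -> list:
    """Genes whose labels match ALL entries of ``pattern``; NA never matches."""
    unknown = [k for k in pattern if k not in classification.columns]
    if unknown:
        raise KeyError(f"unknown dimensions {unknown}; have {list(classification.columns)}")
    mask = pd.Series(True, index=classification.index)
    for dim, label in pattern.items():
        mask &= classification[dim].eq(label).fillna(False)
    return classification.index[mask].tolist()
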