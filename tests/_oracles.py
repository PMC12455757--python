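"""Independent straight-loop reference implementations.

Deliberately naive (explicit Python loops, textbook formulas) so they share
no code path with the package; used to validate the vectorized metrics.
"""

from __future__ import annotations

import math

import numpy as np


def entropy_bits(p):
    return -sum(pi * math.log2(pi) for pi in p if pi > 0)


def oracle_cell_entropy(x_col):
    """Normalized entropy of one cell's isoform expression vector."""
    total = sum(x_col)
    if total == 0:
        return None
    p = [v / total for v in x_col]
    n_det = sum(1 for v in x_col if v > 0)
    if n_det <= 1:
        return 0.0
    return entropy_bits(p) / math.log2(n_det)


def oracle_idi_intra(X):
    """Expression-weighted mean of per-cell normalized entropies."""
    X = np.asarray(X, dtype=float)
    num = den = 0.0
    for j in range(X.shape[1]):
        w = X[:, j].sum()
        if w == 0:
            continue
        num += w * oracle_cell_entropy(X[:, j])
        den += w
    return num / den if den > 0 else float("nan")


def oracle_idi_inter(X):
    X = np.asarray(X, dtype=float)
    xbar = [X[i, :].mean() for i in range(X.shape[0])]
    total = sum(xbar)
    if total == 0 or X.shape[0] < 2:
        return float("nan")
    p = [v / total for v in xbar]
    return entropy_bits(p) / math.log2(X.shape[0])


def oracle_js_distance(p, q):
    m = [(a + b) / 2 for a, b in zip(p, q)]
    kl_pm = sum(a * math.log2(a / mm) for a, mm in zip(p, m) if a > 0)
    kl_qm = sum(b * math.log2(b / mm) for b, mm in zip(q, m) if b > 0)
    return math.sqrt(max(0.5 * kl_pm + 0.5 * kl_qm, 0.0))


def _expressing_proportions(X):
    X = np.asarray(X, dtype=float)
    cols = []
    for j in range(X.shape[1]):
        w = X[:, j].sum()
        if w > 0:
            cols.append([v / w for v in X[:, j]])
    return cols


def oracle_het_per_type(Xk):
    """Mean pairwise JS distance over expressing cells."""
    cols = _expressing_proportions(Xk)
    n = len(cols)
    if n < 2:
        return float("nan")
    dists = []
    for i in range(n - 1):
        for j in range(i + 1, n):
            dists.append(oracle_js_distance(cols[i], cols[j]))
    return sum(dists) / len(dists)


def oracle_type_profile(Xk):
    Xk = np.asarray(Xk, dtype=float)
    xbar = [Xk[i, :].mean() for i in range(Xk.shape[0])]
    total = sum(xbar)
    return [v / total for v in xbar]


def oracle_cv(values):
    vals = [v for v in values if v == v and np.isfinite(v)]
    if len(vals) < 2:
        return float("nan")
    mu = sum(vals) / len(vals)
    if mu == 0:
        return float("nan")
    sd = math.sqrt(sum((v - mu) ** 2 for v in vals) / (len(vals) - 1))
    return sd / mu


def oracle_all_metrics(X, isoforms, cell_types):
    """All seven metrics for one gene, straight-loop.

    X: (I x n) normalized expression; cell_types: length-n labels.
    Mirrors the integration rules: per-type sub-matrix keeps the type's
    gene-expressing cells and the isoforms expressed in those cells.
    """
    X = np.asarray(X, dtype=float)
    out = {"idi_intra": oracle_idi_intra(X), "idi_inter": oracle_idi_inter(X)}
    types = list(dict.fromkeys(cell_types))
    per_type = {}
    for k in types:
        cols = [j for j, t in enumerate(cell_types) if t == k and X[:, j].sum() > 0]
        if not cols:
            continue
        Xk = X[:, cols]
        rows = [i for i in range(X.shape[0]) if Xk[i, :].sum() > 0]
        per_type[k] = (Xk[rows, :], rows)
    het_vals, intra_vals, profiles = [], [], []
    for k, (Xk, rows) in per_type.items():
        het_vals.append(oracle_het_per_type(Xk))
        intra_vals.append(oracle_idi_intra(Xk))
        prof = [0.0] * X.shape[0]
        for v, i in zip(oracle_type_profile(Xk), rows):
            prof[i] = v
        profiles.append(prof)
    finite_het = [h for h in het_vals if h == h]
    out["het"] = sum(finite_het) / len(finite_het) if finite_het else float("nan")
    S = len(per_type)
    if S >= 2:
        js = []
        for i in range(S - 1):
            for j in range(i + 1, S):
                js.append(oracle_js_distance(profiles[i], profiles[j]))
        out["spec"] = sum(js) / len(js)
        out["diff_var"] = oracle_cv(js)
        out["het_var"] = oracle_cv(het_vals)
        out["coexp_var"] = oracle_cv(intra_vals)
    else:
        out["spec"] = out["diff_var"] = out["het_var"] = out["coexp_var"] = float("nan")
    return out


def oracle_pearson(x, y):
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / math.sqrt(sxx * syy)


def oracle_spearman(x, y):
    def ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        r = [0.0] * len(v)
        i = 0
        while i < len(order):
            j = i
            while j + 1 < len(order) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2 + 1
            for k in range(i, j + 1):
                r[order[k]] = avg
            i = j + 1
        return r

    return oracle_pearson(ranks(x), ranks(y))


def oracle_cliffs_delta(a, b):
    gt = lt = 0
    for x in a:
        for y in b:
            if x > y:
                gt += 1
            elif x < y:
                lt += 1
    return (gt - lt) / (len(a) * len(b))


def random_gene_matrix(rng, n_iso=None, n_cells=None, n_types=None):
    """Random small lognorm-like gene sub-matrix + cell-type labels."""
    n_iso = n_iso or rng.integers(2, 7)
    n_cells = n_cells or rng.integers(20, 61)
    n_types = n_types or rng.integers(2, 5)
    X = rng.gamma(1.0, 2.0, size=(n_iso, n_cells))
    X[rng.random(X.shape) < 0.4] = 0.0  # sparsity incl. zero cells/isoforms
    labels = [f"T{t}" for t in rng.integers(0, n_types, n_cells)]
    return X, labels
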