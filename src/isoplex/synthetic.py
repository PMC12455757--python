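"""Synthetic single-cell isoform count data with planted complexity regimes.

The generator emulates the features of real single-cell isoform matrices
that the complexity metrics respond to: overdispersed per-(cell, gene)
totals (negative binomial), compositional isoform usage (multinomial split
of the total across isoforms by a regime-specific proportion vector), and
dropout (Bernoulli thinning of non-zero entries, identical to the
perturbation used in the robustness study).

Regimes and their expected metric signatures:

- ``coexpression``: every cell uses the same multi-isoform proportion
  vector -> high intra-cellular diversity, low cell-type specificity.
- ``type_switch``: each cell type uses its own dominant isoform (or an
  explicit per-type profile) -> cell-type-specific usage; with a single
  dominant isoform per type, intra-cellular diversity is low.
- ``heterogeneous``: per-cell proportions drawn from a Dirichlet (optionally
  over isoform modules) -> high within-type cell-to-cell heterogeneity;
  module structure plants positively co-varying (within-module) and
  antagonistic (cross-module) isoform pairs.
- ``random_partner``: each cell co-expresses a shared primary isoform with
  one randomly chosen partner at 50/50 -> intra-cellular diversity exceeds
  inter-cellular diversity (the below-diagonal signature).
- ``single_isoform``: one isoform only; excluded by SCHT construction.
- ``uniform_low``: low expression with one shared dominant isoform ->
  low diversity, low specificity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import CellMetadata, CountMatrix, TranscriptInfo, aggregate_gene_counts

__all__ = ["GeneSpec", "SyntheticConfig", "generate_dataset", "preset_scenarios", "planted_switch_pairs"]

REGIMES = (
    "coexpression",
    "type_switch",
    "heterogeneous",
    "random_partner",
    "single_isoform",
    "uniform_low",
)


@dataclass
class GeneSpec:
    """Design of one synthetic gene.

    expression: mean total count per cell for the gene (negative binomial).
    dominant_frac: mass on the dominant isoform for type_switch/uniform_low.
    dirichlet_alpha: concentration for the heterogeneous regime (scalar or
        per-component vector; over modules when ``modules`` is given).
    dominant_map: cell type -> dominant isoform index (type_switch).
    type_profiles: explicit cell type -> proportion vector (type_switch).
    modules: partition of isoform indices; Dirichlet weight is drawn per
        module and split evenly inside it (heterogeneous).
    base_profile: shared proportion vector for coexpression/uniform_low
        (default: uniform, or dominant_frac-based for uniform_low).
    """

    name: str
    n_isoforms: int
    regime: str
    expression: float = 10.0
    dominant_frac: float = 0.9
    dirichlet_alpha: float | list | None = None
    dominant_map: dict | None = None
    type_profiles: dict | None = None
    modules: list | None = None
    base_profile: list | None = None

    def __post_init__(self) -> None:
        if self.regime not in REGIMES:
            raise ValueError(f"unknown regime {self.regime!r}; expected one of {REGIMES}")
        if self.regime == "single_isoform" and self.n_isoforms != 1:
            raise ValueError("single_isoform regime requires n_isoforms == 1")
        if self.regime == "heterogeneous" and self.dirichlet_alpha is None:
            raise ValueError("heterogeneous regime requires dirichlet_alpha")
        if self.regime == "random_partner" and self.n_isoforms < 3:
            raise ValueError("random_partner regime requires >= 3 isoforms")


@dataclass
class SyntheticConfig:
    """Full design of a synthetic dataset."""

    n_cells: int
    n_cell_types: int
    genes: list  # of GeneSpec
    type_proportions: list | None = None  # defaults to equal shares
    nb_dispersion: float = 0.5  # NB size parameter r; var = mu + mu^2 / r
    dropout_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.type_proportions is None:
            self.type_proportions = [1.0 / self.n_cell_types] * self.n_cell_types
        if abs(sum(self.type_proportions) - 1.0) > 1e-8:
            raise ValueError("type proportions must sum to 1")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")


def _cell_proportions(spec: GeneSpec, types: np.ndarray, type_names: list, rng) -> np.ndarray:
    """(n_cells x I) matrix of per-cell isoform proportion vectors."""
    n = types.size
    I = spec.n_isoforms
    P = np.zeros((n, I))
    if spec.regime == "coexpression":
        base = np.asarray(spec.base_profile) if spec.base_profile else np.full(I, 1.0 / I)
        P[:] = base / base.sum()
    elif spec.regime in ("uniform_low",):
        if spec.base_profile is not None:
            base = np.asarray(spec.base_profile, dtype=float)
        else:
            base = np.full(I, (1.0 - spec.dominant_frac) / max(I - 1, 1))
            base[0] = spec.dominant_frac
        P[:] = base / base.sum()
    elif spec.regime == "type_switch":
        for k, tname in enumerate(type_names):
            mask = types == k
            if spec.type_profiles is not None:
                prof = np.asarray(spec.type_profiles[tname], dtype=float)
            else:
                dom = (spec.dominant_map or {}).get(tname, k % I)
                prof = np.full(I, (1.0 - spec.dominant_frac) / max(I - 1, 1))
                prof[dom] = spec.dominant_frac
            P[mask] = prof / prof.sum()
    elif spec.regime == "heterogeneous":
        groups = spec.modules if spec.modules is not None else [[i] for i in range(I)]
        alpha = np.asarray(
            spec.dirichlet_alpha
            if np.ndim(spec.dirichlet_alpha) > 0
            else [spec.dirichlet_alpha] * len(groups),
            dtype=float,
        )
        W = rng.dirichlet(alpha, size=n)  # (n x n_modules)
        for gi, members in enumerate(groups):
            for m in members:
                P[:, m] = W[:, gi] / len(members)
    elif spec.regime == "random_partner":
        # geometric partner preference skews the population-mean profile,
        # keeping inter-cellular diversity below the per-cell entropy of 1
        weights = 0.25 ** np.arange(I - 1)
        partners = 1 + rng.choice(I - 1, size=n, p=weights / weights.sum())
        P[:, 0] = 0.5
        P[np.arange(n), partners] = 0.5
    elif spec.regime == "single_isoform":
        P[:, 0] = 1.0
    return P


def _multinomial_rows(rng, totals: np.ndarray, P: np.ndarray) -> np.ndarray:
    """Multinomial draw per row with row-specific proportion vectors.

    Sequential binomial splitting, vectorized over cells.
    """
    n, I = P.shape
    out = np.zeros((n, I), dtype=np.int64)
    remaining = totals.astype(np.int64).copy()
    p_left = np.ones(n)
    for i in range(I - 1):
        with np.errstate(divide="ignore", invalid="ignore"):
            frac = np.where(p_left > 0, np.clip(P[:, i] / p_left, 0.0, 1.0), 0.0)
        draw = rng.binomial(remaining, frac)
        out[:, i] = draw
        remaining -= draw
        p_left = p_left - P[:, i]
    out[:, -1] = remaining
    return out


def generate_dataset(config: SyntheticConfig):
    """Generate (gene matrix, isoform matrix, metadata, annotation, truth).

    The gene matrix is the exact isoform aggregation; the truth table
    records each gene's regime and (when meaningful) the expected landscape
    quadrant.  Bit-reproducible for a fixed config.seed.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_cells
    type_names = [f"T{k}" for k in range(config.n_cell_types)]
    types = rng.choice(config.n_cell_types, size=n, p=config.type_proportions)
    # guarantee every type is populated (tiny n edge case)
    for k in range(config.n_cell_types):
        if not (types == k).any():
            types[rng.integers(n)] = k
    cells = np.array([f"cell_{j:05d}" for j in range(n)], dtype=object)

    iso_blocks, iso_names, info_rows, truth_rows = [], [], [], []
    for spec in config.genes:
        P = _cell_proportions(spec, types, type_names, rng)
        r = config.nb_dispersion
        mu = spec.expression
        totals = rng.negative_binomial(r, r / (r + mu), size=n)
        counts = _multinomial_rows(rng, totals, P)  # (n x I)
        if config.dropout_rate > 0:
            nz = counts > 0
            drop = rng.random(counts.shape) < config.dropout_rate
            counts = np.where(nz & drop, 0, counts)
        iso_blocks.append(counts.T)  # (I x n)
        names = [f"{spec.name}-I{i + 1}" for i in range(spec.n_isoforms)]
        iso_names.extend(names)
        info_rows.extend((t, spec.name, spec.name) for t in names)
        truth_rows.append(
            {
                "gene_id": spec.name,
                "regime": spec.regime,
                "n_isoforms": spec.n_isoforms,
                "expression": spec.expression,
                "expected_quadrant": _expected_quadrant(spec),
            }
        )

    iso = CountMatrix.from_dense(np.vstack(iso_blocks), iso_names, cells)
    info = TranscriptInfo(pd.DataFrame(info_rows, columns=["transcript_id", "gene_id", "gene_name"]))
    gene = aggregate_gene_counts(iso, info)
    meta = CellMetadata(pd.Series([type_names[k] for k in types], index=cells))
    truth = pd.DataFrame(truth_rows).set_index("gene_id")
    return gene, iso, meta, info, truth


def _expected_quadrant(spec: GeneSpec) -> str:
    """Quadrant on the (idi_intra, spec) landscape the regime is designed to hit.

    Q1 = high/high, Q2 = low intra / high spec, Q3 = low/low,
    Q4 = high intra / low spec.
    """
    if spec.regime == "coexpression":
        return "Q4"
    if spec.regime == "type_switch":
        multi = spec.type_profiles is not None and all(
            (np.asarray(v) > 0).sum() >= 2 for v in spec.type_profiles.values()
        )
        return "Q1" if multi else "Q2"
    if spec.regime == "uniform_low":
        return "Q3"
    return ""


def planted_switch_pairs(spec: GeneSpec) -> list:
    """Ground-truth (iso_a, iso_b, is_switch) tuples for a module gene.

    Cross-module pairs are antagonistic (their module weights are
    complementary); within-module pairs co-vary positively.
    """
    if spec.modules is None:
        return []
    names = [f"{spec.name}-I{i + 1}" for i in range(spec.n_isoforms)]
    module_of = {}
    for mi, members in enumerate(spec.modules):
        for m in members:
            module_of[m] = mi
    pairs = []
    for i in range(spec.n_isoforms):
        for j in range(i + 1, spec.n_isoforms):
            pairs.append((names[i], names[j], module_of.get(i) != module_of.get(j)))
    return pairs


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

def preset_scenarios(seed: int = 0) -> dict:
    """Named study designs exercising every analysis module.

    - ``quadrants``: 40 genes, 10 per landscape quadrant of the
      (intra-cellular diversity x cell-type specificity) plane; 400 cells,
      2 types, 30% dropout.
    - ``below_diagonal``: genes whose intra-cellular diversity exceeds
      their inter-cellular diversity.
    - ``switching``: module genes planting antagonistic isoform pairs
      (4 types x 200 cells, as used for co-expression validation).
    - ``sparse``: mixed regimes under heavy (50%) dropout for the
      robustness study.
    """
    presets = {}

    genes = []
    for i in range(10):
        genes.append(GeneSpec(f"GQ4_{i:02d}", 3, "coexpression", expression=12.0))
    for i in range(10):
        genes.append(
            GeneSpec(
                f"GQ2_{i:02d}", 2, "type_switch", expression=12.0,
                dominant_frac=1.0, dominant_map={"T0": 0, "T1": 1},
            )
        )
    for i in range(10):
        genes.append(
            GeneSpec(
                f"GQ1_{i:02d}", 6, "type_switch", expression=18.0,
                type_profiles={
                    "T0": [1 / 3, 1 / 3, 1 / 3, 0.0, 0.0, 0.0],
                    "T1": [0.0, 0.0, 0.0, 1 / 3, 1 / 3, 1 / 3],
                },
            )
        )
    for i in range(10):
        genes.append(GeneSpec(f"GQ3_{i:02d}", 2, "uniform_low", expression=4.0, dominant_frac=0.95))
    presets["quadrants"] = SyntheticConfig(
        n_cells=400, n_cell_types=2, genes=genes, dropout_rate=0.3, seed=seed
    )

    genes = [
        GeneSpec(f"GBD_{i:02d}", 3, "random_partner", expression=15.0) for i in range(10)
    ] + [GeneSpec(f"GAD_{i:02d}", 3, "coexpression", expression=15.0) for i in range(5)]
    presets["below_diagonal"] = SyntheticConfig(
        n_cells=300, n_cell_types=2, genes=genes, dropout_rate=0.0,
        nb_dispersion=2.0, seed=seed
    )

    genes = [
        GeneSpec(
            f"GSW_{i:02d}", 4, "heterogeneous", expression=40.0,
            dirichlet_alpha=[0.3, 0.3], modules=[[0, 1], [2, 3]],
        )
        for i in range(10)
    ]
    presets["switching"] = SyntheticConfig(
        n_cells=800, n_cell_types=4, genes=genes, dropout_rate=0.1, seed=seed
    )

    genes = (
        [GeneSpec(f"GS_co_{i:02d}", 3, "coexpression", expression=10.0) for i in range(20)]
        + [
            GeneSpec(
                f"GS_sw_{i:02d}", 2, "type_switch", expression=10.0,
                dominant_frac=0.9, dominant_map={"T0": 0, "T1": 1},
            )
            for i in range(20)
        ]
        + [
            GeneSpec(f"GS_het_{i:02d}", 3, "heterogeneous", expression=10.0, dirichlet_alpha=0.8)
            for i in range(20)
        ]
    )
    presets["sparse"] = SyntheticConfig(
        n_cells=300, n_cell_types=2, genes=genes, dropout_rate=0.5, seed=seed
    )
    return presets
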