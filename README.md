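# isoplex

Multidimensional isoform-level transcriptomic complexity analysis for
single-cell data.

## The problem

Alternative splicing lets one gene produce several transcript isoforms, and
single-cell long-read sequencing (Nanopore, PacBio) now quantifies them per
cell. Standard gene x cell matrices hide this layer, and a naive
cell x gene x isoform tensor wastes memory on zero padding because isoform
counts differ wildly between genes. Beyond storage, the analytical question
is multidimensional: does a gene co-express several isoforms *within* each
cell, use different isoforms in different *cells*, switch isoforms between
*cell types*, or vary in any of these patterns across types?

`isoplex` is aimed at groups analyzing isoform-resolved single-cell count
matrices who want quantitative, comparable answers to those questions
without downloading reference datasets: every analysis here runs on
synthetic data with planted ground truth.

## Core model

Counts are CPM-normalized and log-transformed per cell,
`x = log2(c / colsum * 1e6 + 1)` (pre-normalized input: `log2(c + 1)`),
then organized into a **single-cell hierarchical tensor (SCHT)**: a
gene-keyed collection of isoform x cell sub-matrices `X_g` (I_g x n), with
an optional second level of per-cell-type sub-matrices `X_g^(k)` restricted
to the type's gene-expressing cells. Only genes with >= 2 detected isoforms
enter; the representation is lossless (non-zero counts match the filtered
isoform matrix exactly).

Seven per-gene complexity metrics are computed, all entropy/divergence
based with base-2 logarithms (so the first four live in [0, 1]):

| metric | definition |
| --- | --- |
| `idi_intra` | expression-weighted mean over cells of the normalized Shannon entropy of each cell's isoform proportions `H_j = -sum_i p_ij log2 p_ij / log2 n_j` |
| `idi_inter` | normalized entropy of the mean isoform proportions across all cells |
| `het` | mean over cell types of the average Jensen-Shannon distance `JSD(p_i, p_j)` between cell pairs within the type |
| `spec` | average Jensen-Shannon distance between cell-type mean isoform profiles |
| `het_var` | coefficient of variation of per-type heterogeneity values |
| `diff_var` | CV of the pairwise type-type JS distances |
| `coexp_var` | CV of per-type intra-cellular diversity |

Genes expressed in one cell type return NA for the cell-type metrics
(preserved through classification). Each metric's distribution is then
diagnosed (multimodal / zero-inflated / skewed / unimodal, via a dip-type
test, KDE peak analysis and BIC-selected Gaussian mixtures), an adaptive
threshold is determined with a hierarchical fallback chain, validated by
bootstrap and stratified k-fold, and genes are binarily classified per
dimension (e.g. "Strong Isoform Co-expression" vs "Weak Isoform
Co-expression"). A co-expression suite tests isoform pairs for conserved,
mixed or cell-type-specific correlation and antagonistic switching
(BH-FDR controlled), and a dropout-perturbation study quantifies metric
stability via the overlap coefficient and Cliff's delta.

## Worked example

```python
from isoplex import (preset_scenarios, generate_dataset, create_scht,
                     compute_all_metrics, threshold_with_validation, plot_landscape)

cfg = preset_scenarios(seed=1)["quadrants"]        # 40 genes, 4 planted regimes
gene, iso, meta, info, truth = generate_dataset(cfg)
scht, run_log = create_scht(gene, iso, info, meta)  # QC -> normalize -> HVG -> SCHT
table = compute_all_metrics(scht)
print(table.metrics.round(3).head(4))
```

```
         idi_intra  idi_inter    het   spec  het_var  diff_var  coexp_var
gene_id
GQ2_01       0.000      0.982  0.000  1.000      NaN       NaN        NaN
GQ3_05       0.254      0.616  0.212  0.078    0.225       NaN      0.428
GQ3_02       0.293      0.695  0.258  0.018    0.110       NaN      0.030
GQ2_05       0.000      1.000  0.000  1.000      NaN       NaN        NaN
```

`GQ2_*` genes were simulated to switch isoforms between the two cell types:
each cell uses one isoform (`idi_intra = 0`) while the types use disjoint
isoforms (`spec = 1`). `diff_var` is NA because two types give a single
type-pair distance (a CV needs >= 2 values); `het_var` is NA when both
per-type heterogeneities are exactly 0.

```python
thr = {d: threshold_with_validation(table.metrics[d].dropna().values, d, seed=1)
       for d in ("idi_intra", "spec")}
for d, t in thr.items():
    print(d, round(t.threshold, 3), t.diagnosis.dist_class, t.method_used, round(t.reliability, 2))
fig, quadrants = plot_landscape(table.metrics, "idi_intra", "spec",
                                {d: t.threshold for d, t in thr.items()})
print(quadrants)
```

```
idi_intra 0.513 zero_inflated zero_inflated_nonzero_mixture 0.49
spec 0.517 multimodal kde_valley 0.74
  quadrant  count  percent
0       Q1     10     25.0
1       Q2     10     25.0
2       Q3     10     25.0
3       Q4     10     25.0
```

The adaptive thresholds recover the planted design exactly: 10 genes per
landscape quadrant (Q1 type-specific co-expression, Q2 isoform switching,
Q3 low complexity, Q4 shared co-expression).

The same workflow is available from a shell:

```bash
isoplex simulate --preset quadrants --seed 1 --out-dir run/sim
isoplex build-scht --genes run/sim/genes --isoforms run/sim/isoforms \
    --gtf run/sim/transcript_info.tsv --meta run/sim/cell_metadata.tsv --out run/scht
isoplex metrics --scht run/scht/scht --out run/metrics
isoplex classify --metrics run/metrics/complexity_metrics.tsv --seed 1 --out run/classify
```

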