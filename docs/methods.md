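# Methods

## Data model and normalization

The pipeline takes a gene x cell and an isoform x cell raw (or
pre-normalized) count matrix, a transcript -> gene annotation, and optional
cell-type labels. Gene-level counts are always aggregated from raw isoform
counts *before* normalization: CPM divides by the per-cell library, so
summing after normalization would change the denominators.

Normalization is per cell: `x = log2(c / colsum * 1e6 + 1)` for raw counts,
`log2(c + 1)` for pre-normalized input. The raw-count form is invariant to
rescaling any cell's column, which the test suite asserts end-to-end (the
whole metric table is unchanged under per-cell scaling, to ~1e-9).

Quality control removes genes detected (raw count > 0) in fewer than
`p_min` (default 0.02) of cells **or** with mean raw count below `epsilon`
(default 1e-4) — the two criteria are each sufficient, since the mean floor
would otherwise never bind — while keeping *all* transcripts of retained
genes. Cells outside `n_min <= detected genes <= n_max` (defaults 200 /
20000, bounds inclusive) are removed. `recommend_qc_parameters` replaces
the defaults with the 1st/99th percentiles of the genes-per-cell
distribution, rounded outward; degenerate distributions fall back to the
defaults, widened outward if the data range would fall outside. Highly
variable genes are ranked by dispersion (sample variance / mean) of
log-normalized gene expression, with ties broken by mean then gene ID so
the selection is deterministic.

The hierarchical tensor stores one dense isoform x cell block per
multi-isoform HVG (all-zero isoform rows dropped; genes reduced to one
detected isoform excluded and counted for the QC report). This is lossless
over retained genes: the summed non-zero count equals that of the filtered
isoform matrix, an identity asserted at construction time. Cell-type
integration keeps, per (gene, type), the type's gene-expressing cells
(summed isoform expression > 0) and the isoforms expressed in those cells.

## Complexity metrics

All entropies and divergences use base-2 logarithms; proportions are taken
from the log-normalized values (a documented flag switches to linear-CPM
proportions for sensitivity analysis). Per gene:

- intra-cellular diversity: per-cell normalized entropy
  `H_j = -sum p_ij log2 p_ij / log2 n_j` with `n_j` the number of detected
  isoforms; a cell detecting one isoform has `H_j = 0` by definition,
  avoiding the 0/0 at `n_j = 1`. Cells are weighted by their total gene
  expression `w_j`.
- inter-cellular diversity: entropy of mean proportions over all cells,
  normalized by `log2 I_g` with `I_g` the sub-matrix's isoform count.
- heterogeneity: mean Jensen-Shannon *distance* (square root of the
  divergence; a metric bounded by 1 in base 2) over all unordered cell
  pairs within a type, on the type-restricted isoform set; types need >= 2
  expressing cells, and the gene-level value averages only defined types.
- specificity: mean JS distance between cell-type mean-proportion
  profiles, aligned on the union isoform set with zeros for absent
  isoforms (`0 * log 0 = 0` throughout).
- the three CV metrics use the sample (n-1) standard deviation over, in
  turn, per-type heterogeneities, pairwise type-type JS distances, and
  per-type intra-cellular diversities. NAs are dropped first; fewer than 2
  finite values or a zero mean gives NA.

NA semantics are deliberate and preserved through classification: a gene
expressed in one cell type has NA specificity and CVs; `diff_var` is NA
with two types (one pair distance); single-isoform genes never enter.
Pairwise JS computations use the identity
`JSD(p, q) = H((p+q)/2) - (H(p) + H(q))/2` vectorized over all pairs,
which the tests pin against explicit pair loops to 1e-10.

Note one consequence of computing proportions on the log scale: the log
compresses expression ratios, so a cell detecting two isoforms at a 10:1
count ratio still has high entropy. "Low diversity" genes are therefore
driven mostly by cells detecting a *single* isoform, which is also why
added dropout pushes intra-cellular diversity down, not up.

## Threshold determination

Metric distributions are heterogeneous, so classification thresholds are
distribution-aware. The diagnosis combines three multimodality votes —
declared multimodal when >= 2 agree:

1. a dip-type unimodality test: the statistic is half the smallest maximal
   deviation between the empirical cdf and its best unimodal envelope
   (greatest convex minorant left of a candidate mode, least concave
   majorant right of it, minimized over modes). It is calibrated by Monte
   Carlo against the uniform null (200 draws, cached per sample size with
   a fixed internal seed, samples thinned to 200 points), so p-values are
   deterministic. This statistic is implemented in-house.
2. KDE peak/valley analysis (Silverman bandwidth x 0.9, 512-point grid):
   peaks below 5% of the tallest peak are noise; adjacent peaks merge
   unless the valley dips >= 25% below the lower flanking peak. Without
   the height floor, tail ripples of skewed samples masquerade as modes.
3. a BIC-selected Gaussian mixture (k in {1, 2, 3}) voting multimodal when
   the two dominant components are > 2 pooled SD apart.

Zero inflation takes precedence (near-zero threshold
`min + max(1% range, 5% IQR)`; Freedman-Diaconis bins; first/second bin
ratio > 3, strict, with >= 20% of mass near zero); otherwise skewness
|g1| > 2 is extreme, > 1 moderate. Constant or < 20-point samples are
unimodal with a degenerate/low-data flag.

Per class, the threshold algorithm with its fallback chain:

- multimodal: KDE valley between the two largest peaks (primary), then a
  2-component GMM density-equality boundary (secondary);
- extremely skewed: Yeo-Johnson transform (lambda by maximum likelihood on
  a [-2, 2] grid, step 0.05), density-curvature inflection after the mode
  on the 5th-95th percentile core (primary), else mean + 0.5 SD on the
  transformed scale (secondary), back-transformed;
- zero-inflated: gap midpoint between the near-zero cluster and the
  non-zero mass when the gap spans >= 25% of the range, else mixture
  analysis of the non-zero part, else a skewness-adaptive percentile
  (`clip(50 + 10 g1, 25, 90)`) of the non-zero values;
- moderately skewed / unimodal: deepest density valley between the median
  and P90 (primary), else GMM boundary or mean + 0.5 SD (secondary);
- terminal fallback everywhere: the 75th percentile.

Thresholds are sanity-clamped into [P5, P95] (idempotent, flagged when it
fires). Validation: 100 bootstrap resamples recompute the threshold under
the full-sample diagnosis (re-diagnosing each resample would measure
classifier churn, not threshold stability) giving a percentile CI95, SD
and CV (CV reported NA when the SD is exactly 0); stratified 5-fold
stability runs when n >= 10k, stratified by above/below the full-sample
threshold. The reliability score is base 1.0 / 0.75 / 0.5 (primary /
secondary / terminal method) times `exp(-2 cv_boot)`, times
`exp(-cv_kfold)` when available, times 0.8 per problem flag (n < 50;
multimodal non-zero component of a zero-inflated metric), clipped to
[0, 1]. All constants are exposed in `ThresholdConfig`.

Classification is binary per dimension with an inclusive high side
(value >= threshold), e.g. intra-cellular diversity maps to "Strong/Weak
Isoform Co-expression" and specificity to "Cell-Type-Specific/-Independent
Isoform Expression"; NA values keep NA labels, and
`find_complexity_pattern` AND-matches label patterns with NA never
matching.

## Co-expression

Correlations (Pearson default; tie-corrected Kendall tau-b; Spearman with
t-approximation p-values) are computed between isoform *proportions* over
gene-expressing cells — co-expression within a gene is compositional, and
raw expression scales would correlate through the shared library signal.
The compositional closure has a known cost: proportions of a k-isoform
gene are negatively coupled (about -1/(k-1) under symmetric variation), so
negative correlations of small-k genes are biased and `r_cut` (default
0.3, with q < 0.05 after Benjamini-Hochberg over all pair x type tests)
should be read with that in mind; `use_proportions=False` is available.
Per-pair conservation labels need >= 2 evaluable types: `mixed` (both
signs significant) takes precedence over `conserved` (significant, one
sign, in >= 80% of evaluable types — the consistency cutoff is
configurable) and `cell_type_specific` (significant in exactly one type).
Switching flags pairs with r <= -r_cut (inclusive) and significant q in
some type; bootstrap pair stability reports the fraction of 100 resamples
keeping the full-sample sign with |r| >= r_cut/2.

## Robustness study

Additional dropout is Bernoulli thinning of non-zero raw isoform counts
(zeros untouched), applied *before* QC so filtering and HVG effects
propagate; the gene matrix is re-aggregated from the perturbed isoforms.
Per rate (default 0.1-0.5) and iteration (default 20), each metric's
per-gene distribution is compared with baseline on the intersection of
genes surviving both runs (a union-with-NA option exists) via the overlap
coefficient — integral of the pointwise minimum of two KDEs sharing a
Silverman bandwidth computed on the pooled sample, on a 512-point grid
padded by 4 bandwidths; constant samples fall back to shared-bin
histograms — and Cliff's delta, computed by rank counting and reported
with the conventional negligible/small/medium/large bands (0.147 / 0.33 /
0.474).

## Synthetic data

The generator draws per-(cell, gene) totals from a negative binomial
(default dispersion r = 0.5, i.e. strongly overdispersed as in real
droplet/long-read data) and splits them multinomially across isoforms by a
regime-specific proportion vector, then applies Bernoulli dropout —
identical to the robustness perturbation for coherence. Regimes:
`coexpression` (shared multi-isoform profile), `type_switch` (per-type
dominant isoform or explicit per-type profiles), `heterogeneous`
(per-cell Dirichlet weights, optionally over isoform *modules* whose
members split the weight evenly — modules plant positively co-varying
within-module and antagonistic cross-module pairs), `random_partner`
(a shared primary isoform plus one randomly chosen partner per cell at
50/50, with a geometric partner preference; this is the regime whose
intra-cellular diversity exceeds its inter-cellular diversity),
`single_isoform`, and `uniform_low`.

Presets fix the study conditions: `quadrants` (400 cells, 2 types, 40
genes — 10 per landscape quadrant of the intra-cellular diversity x
specificity plane — 30% dropout), `below_diagonal` (no dropout and
dispersion r = 2, because dropout and 1-count cells deflate intra-cellular
diversity and would erase the planted signature), `switching` (4 types x
200 cells, 4-isoform module genes with Dirichlet(0.3, 0.3) module weights
and mean expression 40, giving cross-module correlations near -0.4 and
within-module near 0), and `sparse` (mixed regimes at 50% dropout).

What the generator does *not* emulate: ambient RNA, doublets, batch
effects, gene-gene correlation structure, technology-specific length or
error biases, and realistic transcriptome scale (tens of genes, not
thousands). Passing recovery tests therefore shows the estimators respond
correctly to planted compositional structure under overdispersion and
dropout — not that real-data thresholds or quadrant shares are
reproduced. The switching preset's truth labels follow the module design
(cross-module = antagonistic); because of compositional closure there is
no meaningful "zero correlation" null for proportions, so false-positive
control is assessed against the positively co-varying within-module pairs.

## Problem sizes and numerical choices

Default test and acceptance runs use the preset sizes above with 20 seeds
for recovery studies and a reduced robustness design (250 cells, 60 genes,
rates {0.1, 0.5}, 3 iterations), chosen so the whole suite completes in a
few minutes on one CPU while leaving comfortable statistical margins.
Pairwise-JS heterogeneity is O(n_k^2 I) per gene and type and is evaluated
exactly (no cell subsampling) at these scales. Ties in HVG dispersion,
GMM seeding (fixed random_state), the dip null cache, and all generator
draws are seeded, so every reported number is reproducible bit-for-bit.

Known limitations: the dip-type statistic is an envelope approximation
calibrated by simulation rather than the exact Hartigan recursion (it is
used only as one of three votes); threshold algorithms assume enough
finite metric values (>= 20) to say anything distributional; per-cell-type
threshold tables are computed globally by default; and the co-expression
suite tests pairs only, not higher-order isoform modules.
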