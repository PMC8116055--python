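# Methods

## Problem setting

An antigen protein is conjugated to a protected single-stranded DNA
barcode carrying a capture site compatible with droplet single-cell
feature-barcode chemistry. After vaccination, cells from the draining
lymph node are captured; each cell yields mRNA counts plus UMI counts for
the conjugated tag and for unconjugated control tags. The analysis asks,
per cell and per cell type: how much antigen does the cell hold, which
cells hold an unusually large amount ("antigen-high"), and which genes
mark those cells.

## Tag quantification

Reads are (cell barcode, UMI, tag barcode) tuples. Cell barcodes are
matched exactly against the cell whitelist; tag barcodes are corrected at
up to one substitution, which is unambiguous because the tag whitelist is
validated to have pairwise Hamming distance ≥ 3. `N` or any non-ACGT
symbol counts as a mismatch at its position. Within each (cell, tag)
group, UMIs are deduplicated exactly; an optional directional merge
(UMI-tools rule: u is absorbed into v when Hamming(u, v) = 1 and
reads(v) ≥ 2·reads(u) − 1, visiting UMIs in decreasing read count with
ties broken by sequence) is off by default, so the default reproduces
plain deduplication. An audit tally (exact / corrected / ambiguous /
unmatched / duplicate reads) partitions the read set and is emitted next
to the count matrix.

## QC and normalization

Cells are kept when the number of detected genes is strictly greater than
250 and strictly less than 5000 and the mitochondrial read percentage
(genes matching a configurable `mt-` prefix) is strictly below 15%. All
three bounds are read literally as strict inequalities. Expression is
normalized per cell as ln(1 + count · 10⁴ / cell total). Variable genes
are ranked by standardized variance: per-gene raw-count variance divided
by the median variance of the gene's log-mean bin (20 quantile bins);
ties break lexicographically by gene id so selection is deterministic.
The variable-gene block is centered and scaled per gene, clipped at ±10
(a standard guard against single outlier cells dominating PCA), and
decomposed by exact-SVD PCA. Component signs are fixed by making each
loading vector's largest-magnitude entry positive, so scores are fully
reproducible.

## Clustering and annotation

A shared-nearest-neighbor graph is built from the PC scores: k = 20
nearest neighbours (cell included), Jaccard overlap of neighbour sets as
edge weights, weights below 1/15 pruned. Communities are found by Leiden
optimization of the RB-configuration modularity at resolution 1.0 with a
fixed seed; Leiden refines the classic Louvain scheme while optimizing
the same objective, and the installed implementation exposes the seed and
resolution directly, which is why it stands behind `cluster_cells`.
Labels are relabelled by decreasing cluster size.

Annotation is cluster-level correlation against a reference profile
table: each cluster's mean log-expression over the variable genes shared
with the reference is correlated (Spearman by default; Pearson available)
with every reference type, and the cluster takes the arg-max type. Ties
go to the earlier reference type and are flagged; any call whose
top1 − top2 margin is below 0.02 (a reporting device, not an estimate) is
flagged ambiguous. Flat profiles correlate at 0 by convention.

## Relative antigen signal

Per sample: m = median raw tag count over T/B (baseline) cells;
r_c = a_c/m. If m = 0 the median of the positive baseline counts is used,
then 1; either fallback sets a per-sample `baseline_degenerate` flag —
silent division by zero is never acceptable, and the flag makes the
fallback auditable. The pseudocount is half the smallest positive
relative signal, computed per sample, so display values are comparable
across samples only with that caveat. Group comparisons report, per cell
type: n and fraction of cells, median relative signal, the two-sided
Wilcoxon rank-sum statistic, the Hodges–Lehmann estimate of the median
difference with a 95% rank-based confidence interval, and a
Bonferroni-adjusted p over the family of tests within the sample. Both
an all-pairs family and an each-type-vs-pooled-baseline family are
supported; the function defaults to all pairs, while the pipeline's
summary uses the baseline family.

## Mixture classification

The two-component Gaussian mixture is fit on log10(r_c + pseudocount) —
tag counts span roughly four orders of magnitude, so a Gaussian mixture
is only well-specified on the log scale. EM details: initialization at
the 25th/75th percentiles with both standard deviations at half the
overall sd and equal weights (deterministic; optional random restarts
exist for robustness checks); convergence when the log-likelihood changes
by less than 1e-8 or after 1000 iterations; component standard deviations
floored at 1e-3 × overall sd to prevent degenerate point-mass components;
unequal variances allowed. The log-likelihood is asserted non-decreasing
at every iteration. Components are relabelled so the larger mean is
"high"; hard labels use posterior ≥ 0.5. Groups under 10 cells are
skipped with a warning rather than fit unstably. Under the
well-separated conditions the assay produces (≈2 decades between modes),
hard labels agree with the generating class for >99% of cells; at 3σ
separation the ±0.2/±0.05 parameter-recovery tolerance is met in roughly
three quarters of runs — the same rate a multi-restart reference EM
achieves — so recovery guarantees are stated at 4σ.

## Markers

Per gene, a Wilcoxon rank-sum test with midranks compares log-normalized
expression between antigen-high and antigen-low cells; the exact null
distribution (dynamic-programming enumeration over rank assignments) is
used when the two classes total ≤ 12 cells with tie-free data, otherwise
a normal approximation with tie and continuity correction. AUC is
U/(n₁n₂). logFC is the difference of mean log-normalized expression
(the rank-test-toolkit convention; it differs from ratio-of-means
conventions near zero). pct_in/pct_out count raw counts > 0. Genes with
zero expression in both classes are reported untested and excluded from
the BH family. Pass requires padj < 0.05 (strict), logFC > 0.25
(strict), AUC > 0.5 (strict) and pct_in ≥ 50 (inclusive, "at least").

## Statistical kernels

- Exact rank-sum: the null pmf of U is computed by counting j-subsets of
  ranks by rank-sum (DP over the Gaussian-binomial recurrence) —
  enumeration in effect without materialising subsets. Two-sided exact
  p = min(1, 2·min tail). Exact mode refuses ties; auto mode falls back
  to the corrected normal approximation.
- Hodges–Lehmann: median of all pairwise differences; CI bounds are order
  statistics of the sorted differences selected by the exact U
  distribution (achieved coverage reported) for n₁n₂ ≤ 2000, else by the
  normal-approximation index.
- Multiple testing: Bonferroni and BH delegate to statsmodels; the
  BKY two-stage step-up (stage 1 BH at q′ = q/(1+q); if 0 < r₁ < m,
  stage 2 BH at q″ = q′·m/(m−r₁)) is implemented here and returns the
  rejection set with stagewise diagnostics — its natural output. BKY
  rejections contain BH rejections whenever stage 1 finds enough signal
  (r₁ ≥ mq/(1+q)); this containment is empirical, not universal.
- Fraction diluted: (Σ_{i≥1}N_i/2^i)/(Σ_{i≥0}N_i/2^i), generation 0
  undivided; invariant to rescaling all N_i.
- Standard curve: least-squares Cq = slope·log10(Q) + intercept; a
  non-negative slope is rejected as an invalid dilution series;
  efficiency 10^(−1/slope) − 1; unknowns outside the standards' Cq range
  are flagged extrapolated.

## Synthetic generator

The generator emulates a lymph-node capture in which myeloid and stromal
cells were enriched and recombined with lymphocytes at a 4:4:1:1 ratio.
Defaults: 4 types (cDC2, LEC, T, B) at 800/800/200/200 cells; 1000 genes
of which each type owns 20 signature genes (4-fold elevated) and 10 are
mitochondrially prefixed; gene counts negative binomial with mean 0.5
(dispersion θ = 2, variance μ + μ²/θ), giving ~350–440 detected genes
and ~5% mitochondrial reads per cell — library sizes chosen so the QC
thresholds above operate in their intended regime. The conjugated tag is
a two-component log10-normal: class Bernoulli(high fraction of the type;
0.7 for cDC2, 0.1 for LEC, 0 for T/B which are forced low), count =
round(10^z), z ~ N(0.3 or 2.3, 0.35) — a two-decade mode separation
matching a count range up to ~10⁴ molecules. Control tags are
Poisson(0.05), essentially undetectable. Reads, when generated, get
1 + Poisson(mean−1) PCR duplicates per molecule (shifted Poisson keeps
every molecule observed at least once; the exact duplicate law is
irrelevant to collapse correctness) and independent per-base substitution
errors at rate 0.001. Cell barcodes are drawn collision-free by
construction, so barcode-collision handling is tested with deliberately
injected duplicates rather than left to chance.

What the generator does **not** emulate: ambient RNA, doublets, batch
effects, cell-type-specific library-size differences, realistic gene–gene
correlation beyond the block signatures, or read-level mRNA simulation.
Passing tests therefore demonstrate correctness of the algorithms under
the assay's idealized statistical structure, not robustness to every
artefact of real captures.

## Problem sizes and determinism

The default synthetic capture is 2000 cells × 1000 genes; the marker
null-distribution checks use 1000 genes × 120 cells over 200 label
permutations; mixture recovery uses 50 seeded draws of n = 1000. These
sizes give stable Monte-Carlo estimates while keeping the full suite
fast. Every stochastic component takes an explicit seed
(`numpy.random.default_rng`); the pipeline writes a manifest with
per-stage parameter records and output hashes, and identical config +
seed reproduces byte-identical tables.

## Known limitations

- Cell barcodes are never error-corrected (only tag barcodes are); cell
  calling (knee-point detection) is out of scope — the reader takes
  matrices as given.
- Cluster-level annotation only; per-cell annotation is a non-goal.
- The mixture model is strictly two-component; no model selection.
- Exact rank-sum enumeration is refused for tied data rather than
  attempting a tie-aware exact distribution.
- No UMAP or other embedding: visualization never feeds the statistics.
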