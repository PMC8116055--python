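# atrace

Analysis of antigen-DNA "molecular tracking device" experiments: vaccine
antigens conjugated to phosphorothioate-protected DNA barcodes are captured
alongside mRNA in droplet single-cell sequencing, so the amount of antigen
each cell holds can be read out as a per-cell UMI count of the tag. `atrace`
implements the computational side of such an experiment for lymph-node
captures — from raw tag reads to antigen-high marker genes — together with a
synthetic-data generator that reproduces the statistical structure of the
assay, so the whole chain is testable without any sequencing data.

## Who this is for

Groups running feature-barcode (CITE-seq-style) captures where one feature
block is an antigen tag rather than an antibody tag, and who want a
reproducible, scriptable version of the canonical analysis: QC, clustering,
reference-correlation cell typing, tag normalization against a T/B-cell
baseline, two-component mixture classification, and marker detection.

## The model

For cell *c* with raw antigen-tag UMI count *a_c* in sample *s*:

- **Relative signal** r_c = a_c / m_s, where m_s is the median tag count
  over the T and B cells of the sample (these cells acquire essentially no
  antigen and appear in every capture, so they anchor the scale across
  captures).
- **Display value** log10(r_c + p_s) with pseudocount
  p_s = ½ · min{r_c > 0} per sample.
- **Classification**: a two-component Gaussian mixture on the display
  values, fit by EM (deterministic quantile initialization, variance floor,
  monotone log-likelihood), labels each cell antigen-**low** or
  antigen-**high** by posterior ≥ 0.5. Populations can be fit pooled (LEC
  style) or per cell type (DC style).
- **Markers** of antigen-high cells: per gene, a Wilcoxon rank-sum test on
  log-normalized expression, AUC = U/(n₁n₂), logFC = difference of mean
  log-normalized expression, and percent of expressing cells per class.
  A gene passes with BH-adjusted p < 0.05, logFC > 0.25, AUC > 0.5 and
  pct_in ≥ 50%.

Supporting kernels (`atrace.stats`) include the exact small-sample Wilcoxon
rank-sum null distribution (dynamic-programming enumeration),
Hodges–Lehmann shift estimates with rank-based confidence intervals,
Bonferroni/BH/BKY-two-stage multiple-testing procedures, the
proliferation-dye "fraction diluted" statistic
(Σ_{i≥1}N_i/2^i)/(Σ_{i≥0}N_i/2^i), and qPCR standard-curve quantification.

## Worked example

```python
from atrace import simulate, qc, cluster, antigen, mixture, markers

cfg = simulate.SimConfig(seed=1)          # 4 cell types, 2000 cells
bundle, truth = simulate.simulate_counts(cfg)
filt, report = qc.qc_filter(bundle)       # >250/<5000 genes, <15% mito
norm = qc.lognormalize(filt)
hvg = qc.select_hvg(filt, 2000)
norm = qc.run_pca(norm, hvg, n_pcs=40, seed=1)
cl = cluster.cluster_cells(norm.pca_scores, seed=1)
ann = cluster.annotate_clusters(norm, cl, simulate.make_reference(cfg))
cell_types = ann.cell_types(cl.labels)
sig = antigen.relative_signal(filt, "ova-psDNA", cfg.baseline_types, cell_types)
fits, labels = mixture.classify_antigen(
    sig[~sig.cell_type.isin(cfg.baseline_types)], grouping="per_type")
mk = markers.find_markers(norm, labels.reindex(filt.cell_ids), bundle=filt)
```

This prints (via the summaries in the example script):

```
QC: 2000/2000 cells kept
 cluster assigned_type  r_top1  margin
       0           LEC   0.295   0.174
       1          cDC2   0.295   0.183
       2         Tcell   0.295   0.125
       3         Bcell   0.295   0.175
median relative signal per type:
Bcell     1.00
LEC       1.00
Tcell     1.00
cDC2     63.25
LEC: pi_high=0.103 mu=(0.11, 1.97)
cDC2: pi_high=0.682 mu=(0.11, 2.01)
markers passing all four filters: 20
```

Every cluster is annotated to its generating type; T/B cells sit at a
median relative signal of exactly 1 (they define the baseline); the mixture
recovers the simulated antigen-high fractions (0.10 for LECs, 0.68 vs the
configured 0.7 for cDC2s) with component means two decades apart; and the
20 passing markers are exactly the cDC2 signature genes enriched among
antigen-high cells.

The same chain runs from the command line:

```sh
atrace run --config run.yaml --seed 1 --outdir out/
atrace count --reads reads.tsv --tags tags.tsv --cells cells.txt
```

`atrace run` writes every intermediate table as TSV plus a `manifest.json`
with per-stage parameters and output hashes; re-running with the same
config and seed is byte-identical.

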