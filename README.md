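# dc2scape

Computational toolkit for dissecting dendritic-cell (DC) heterogeneity from
single-cell RNA-seq and ATAC-seq data — and, more generally, for any setting
where discrete cell subsets coexist with continuous differentiation states.

Splenic type-2 conventional dendritic cells (cDC2s) split into T-bet⁺ and
T-bet⁻ lineages that differ in transcription factors, surface markers and
chromatin accessibility, yet are connected by a continuum of intermediate
states arising from a common Siglec-H⁺ progenitor. Analyzing such a mixture
needs statistics that work on full expression *distributions* rather than
means, geometry that respects the underlying manifold, and regulatory models
that link motifs to accessibility changes. This package implements that
toolkit as a tested, reusable library with a synthetic-data module that
plants ground truth for every analysis arm.

## What it computes

**Marker discovery (EMD + AUC).** After library-size normalization
(`log2(count/total × median_total + 0.1)`) and graph-diffusion imputation,
each gene in a one-vs-rest contrast gets two statistics:

- the signed earth mover's distance between expression distributions,
  `EMD = ‖CDF₁ − CDF₂‖₁` (the 1-D Wasserstein-1 distance), signed by the
  direction of the median shift;
- the ROC AUC of the gene as a threshold classifier of cluster membership,
  `AUC = U / (n₁·n₂)` (tie-corrected Mann-Whitney).

Markers are genes with `AUC ≥ 0.99` whose EMD lies outside
`μ_EMD ± k·σ_EMD` (k = 3 by default; 4 as a stricter preset).

**Diffusion geometry.** An adaptive Gaussian kernel
`exp(−(d_ij/σ_i)²)` with `σ_i` = distance to the *ka*-th neighbor
(k = 30, ka = 10 defaults) is symmetrized and row-normalized into a diffusion
operator `M`. Powering it (`t = 4`) imputes expression; its spectrum gives
diffusion components, scaled `λ/(1−λ)` into multi-scale coordinates whose
Euclidean metric approximates diffusion distance. A stability sweep reports
the median per-gene R² between imputations across (k, t).

**Trajectory robustness.** Shortest paths on k-NN graphs of multi-scale
diffusion distances (k = 15), with a k-l-NN ensemble (l = 5 edges kept per
cell per sample) yielding per-cell path-proximity probabilities, path
cluster composition, and step-size outlier profiles.

**Clustering stability.** Cluster solutions across PC-count and k sweeps are
consolidated by plurality membership into reference populations and compared
by the adjusted Rand index (all unordered pairs per axis).

**Cross-species correspondence.** Z-scored centroid Pearson correlation
through an ortholog map; one-vs-rest elastic-net cluster signatures
(α = 0.99, 10-fold CV maximizing AUC) correlated with bulk profiles;
core-signature derivation (`FDR`, `|log2FC| > 1.5`, mean count ≥ 50); ANOVA
TF selection at FDR < 1e-5 in both species; cosine-k-NN TF program
clustering with overlap counting; two-sample KS signature-shift tests.

**ATAC motif-association lasso.** 150-bp windows centered on peak summits
(peaks ≤ 76 bp or off chr1–19/X/Y removed) are scanned with PWMs using
log-odds scores and *exact* per-position p-values (dynamic programming over
the discretized score lattice, FIMO-style; hits at p < 5e-4). Motifs present
in 1–40 % of windows and tied to expressed TFs form the feature matrix **X**
of the linear model **y ~ Xw**, where **y** is per-peak accessibility log2
fold change; lasso with 5-fold CV yields coefficients **w** ranking motifs
by association, with held-out Spearman ρ as performance. Per-gene peak-set
Mann-Whitney statistics furnish "diamond plot" data.

## Worked example

```python
import dc2scape as d

counts, truth = d.make_sc_counts(n_cells=600, n_genes=500, seed=42)
counts, qc = d.filter_cells(counts, max_mito_frac=0.20)
counts, _  = d.filter_genes(counts, min_cells=10)
expr    = d.normalize(counts)
pca     = d.compute_pca(expr, n_components=20)
op      = d.markov_normalize(d.adaptive_affinity(pca.scores, k=30, ka=10))
imputed = d.impute(expr, op, t=4)
table    = d.marker_table(imputed, truth.subset)
selected = d.select_markers(table, d.SelectionRule(auc_min=0.99, emd_sd_multiplier=3))
print(selected.head(5).round(3))
```

Output:

```
  gene   contrast  signed_emd  auc  n_target  n_reference
g00000 S0_vs_rest       1.646  1.0       207          393
g00001 S0_vs_rest       1.829  1.0       207          393
g00002 S0_vs_rest       1.708  1.0       207          393
g00003 S0_vs_rest       1.620  1.0       207          393
g00004 S0_vs_rest       1.531  1.0       207          393
```

All 30 planted markers (10 per subset, +2 log2-units, 50 % dropout) are
selected with zero false positives: each has perfect single-gene
classification (AUC = 1.0) and an EMD of ~1.5–1.8 log2 units against a null
spread of σ ≈ 0.1, far outside the 3σ selection band.

A command-line surface mirrors the library:

```bash
dc2scape simulate sc --seed 1 --out-prefix sim
dc2scape preprocess --counts sim_counts.csv --preset mouse_spleen --out expr.tsv
dc2scape markers --expr expr.tsv --labels sim_labels.tsv --out markers.tsv
```

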