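# Methods

This note records the models and procedures the package implements, the
choices made where the design was genuinely open, and what the synthetic
generators do and do not emulate.

## Preprocessing

Cells are filtered in a fixed order — mitochondrial molecule fraction
(removed when strictly above `max_mito_frac`, default 0.20), unique-gene
count (removed when strictly below `min_genes`), total molecules (retained
when strictly above `min_molecules`; 0 disables the filter) — and the QC
report itemizes removals per stage, so reports are reproducible and
comparable across runs. Genes are retained when detected in strictly more
than `min_cells` cells (default 10). Three named presets ship:
`mouse_spleen` (min_genes = 1000), `human_spleen` (min_molecules = 6000),
`melanoma` (min_molecules = 1000); all values are overridable.
Mitochondrial genes are recognized by id prefix (`mt-`, `MT-`) when no
explicit mask is given — a convention, not a biological claim.

Normalization divides each cell by its total, multiplies by the median
total across cells (numerical-stability scaling), and applies
`log2(x + 0.1)`. The transform is invertible per cell given the totals;
`denormalize` round-trips to machine precision.

PCA operates on gene-centered, **unscaled** values (unit-variance scaling is
deliberately not applied; nothing in the workflow assumes it), with a
deterministic sign convention (largest-magnitude loading positive). Small
matrices use a full SVD; larger ones a Lanczos solver with a fixed start
vector, so results are machine-reproducible. Gene-set seeds for factor
models concatenate the top 30 positive and 30 negative loadings per
component (60 genes per set), ties broken by gene id.

Signature scoring averages per-gene z-scores by default (a raw-mean flag
exists). Z-scoring makes genes of different magnitudes commensurable;
zero-variance genes contribute 0 rather than NaN. Factor removal is
ordinary least squares per gene on the factor matrix plus intercept, output
= residual + gene mean; zero-variance factors are dropped and rank
deficiency is an error naming the collinear column.

## Diffusion geometry

The affinity kernel is adaptive Gaussian: `exp(−(d_ij/σ_i)²)` over each
cell's k nearest neighbors with `σ_i` the distance to its ka-th neighbor,
self-affinity 1, symmetrized by averaging. This is the simplest
construction consistent with an adaptive-bandwidth affinity parameterized
by (k, ka); an α-decay exponent variant is not provided because nothing
downstream needs it. Duplicate points (σ = 0) fall back to the smallest
positive neighbor distance with a logged warning.

Imputation powers the row-normalized operator by repeated sparse
matrix-vector products (`M(M(MX))`, never a dense matrix power). It
commutes with gene-wise affine maps and preserves constants — both are
tested invariants.

Diffusion maps come from the symmetric conjugate `D^{-1/2} A D^{-1/2}`
(dense `eigh` below ~400 cells, Lanczos with a fixed start vector above),
mapped back to right eigenvectors of `M`. The Markov-normalized and
conjugate routes agree up to scaling; the symmetric route is used because
its eigenproblem is numerically better behaved. The trivial stationary
eigenpair is dropped; a multiplicity of unit eigenvalues raises a
disconnected-graph error. The number of retained components defaults to
the largest relative eigen gap `(λ_i − λ_{i+1})/λ_i` — a choice, since
eigen-gap inspection by eye is not reproducible — and is always
overridable. Multi-scale coordinates scale component i by `λ_i/(1−λ_i)`.

The stability grid reports, per (k, t), the median across genes of the
squared Pearson correlation between that imputation and a reference
imputation, with `ka` scaled as `k/3` to vary the neighborhood coherently
and zero-variance genes excluded.

## Marker statistics

`emd_signed` computes the exact 1-D Wasserstein-1 distance
(interval-width-weighted L1 norm of the empirical CDF difference — not an
unweighted sum over grid points, a distinction testable against a
transport-LP oracle), signed by the median difference; median ties fall
back to the mean difference, then 0. `auc_score` uses rank statistics with
tie correction (`U/(n₁n₂)`, O(n log n)).

Selection keeps genes with `AUC ≥ auc_min` (default 0.99; two-sided mode
admits `≤ 1 − auc_min`) whose signed EMD lies outside `μ ± k·σ`, where μ
and σ are computed across **all** genes of the contrast. Two multiplier
presets ship, 3 and 4: published descriptions of this rule differ between
the two values, so neither is privileged; 3 is the default. A robust
(median/MAD) variant is a flag. σ = 0 across a contrast is degenerate and
raises. A balanced-subsampling diagnostic (25 seeded repetitions to the
smaller group size) reports how cell-number imbalance affects EMD ranks.

## Clustering robustness

The adjusted Rand index is the Hubert–Arabie form (delegated to
scikit-learn; an independent pair-counting oracle lives in the tests).
Consolidation relabels each cluster by the plurality of its cells'
membership in named reference groups; an exact tie leaves the cluster
unconsolidated with a warning (the plurality rule's tie case is undefined
in the field's usage, so the conservative option was chosen). Sweeps vary
the PC count and k independently, consolidate each solution, and summarize
all unordered pairs per axis as mean ± SD, keeping the full pairwise matrix
so alternative summaries can be recomputed. The clusterer contract is a
pure function (embedding, k, seed) → labels, so Phenograph, Leiden or a
label file can be slotted in; the built-in default (k-NN graph + greedy
modularity) is a convenience, not a Phenograph reimplementation.

## Trajectory paths

k-NN graphs on multi-scale diffusion distances break distance ties at the
k-th rank by cell id, making the graph bit-reproducible. Path computation
treats edges as undirected with symmetric distances — the k-NN relation is
asymmetric, but shortest paths on mutual distances are better behaved; a
hand-written Dijkstra enforces deterministic lexicographic predecessor
tie-breaks. k-l-NN sampling retains l of each cell's k edges uniformly
without replacement, fresh per sample, from one seeded RNG stream; samples
that disconnect the target count as failures and are excluded downstream
with the failure rate reported. The ensemble default is 100 samples.

"Within n neighbors of the path" is interpreted as membership in the union
over path nodes of each node's n-nearest-cell neighborhood; the dual
reading (path nodes among the cell's own n nearest) is available via
`direction="from_cell"`. Step-size outliers are steps exceeding
median + 5×MAD of the path's steps (configurable).

## Correspondence

Centroid z-scoring is per gene across clusters (population SD,
zero-variance → 0); the per-cluster-across-genes alternative is available
by disabling the z-score flag and pre-transforming. Ortholog maps reduce
many-to-many pairs by keeping unique-unique pairs outright and resolving
the rest greedily by total expression (or lexicographically without
expression), with the rule logged.

Cluster signatures use one-vs-rest logistic regression with elastic-net
penalty (mixing weight α = 0.99, i.e. nearly pure lasso), on genes with
total count strictly above 300, library-normalized to the median total and
`log2(x+1)`-transformed — this transform is specific to this procedure and
deliberately distinct from the preprocessing module's `log2(x+0.1)`.
Stratified 10-fold cross-validation selects the penalty maximizing held-out
ROC AUC along a log-spaced path (100 points in production; tests use
shorter paths for speed).

The TF program analysis: one-way ANOVA F-tests per TF across clusters on
normalized log expression, Benjamini–Hochberg adjustment, selection at
FDR < 1e-5 in both species; an expression pre-filter (mean normalized
count > 10) applies when raw means are supplied. Selected TF profiles are
z-scored and clustered per species by cosine-k-NN + greedy modularity
(k = 10 default); the overlap matrix counts ortholog pairs per program
pair and conserves the shared-TF total. The KS signature-shift test is the
two-sided two-sample test of signature-gene log2FCs against the full
background (the signature is a subset of the background, so D is bounded
by the background mass outside the signature's range).

The core-signature rule — FDR below threshold, |log2FC| strictly above
1.5, mean normalized count at least 50, split by sign and intersected
across tissues — takes differential-expression tables as *input*; the
FDR default (0.1) matches the convention of the negative-binomial
frameworks that produce such tables.

## ATAC arm

Coordinates are BED-style 0-based half-open throughout. Windows are
`[summit − w/2, summit + w − w/2)` for width w (the off-by-one convention
for even widths is thereby fixed); clipped windows are flagged. Peaks of
size ≤ 76 bp or outside chr1–19/X/Y are removed before windowing.

Annotation precedence is strict: promoter (summit within 2 kb of any TSS)
→ exonic (window overlaps an exon) → intronic (window inside a gene body)
→ intergenic (within 50 kb of a gene) → unclassified. Distance to gene is
measured peak-edge to gene-span edge (0 when overlapping); TSS distance is
summit to TSS. Both anchors are recorded because the field uses several
conventions.

Internal differential accessibility is a clearly labeled stand-in (size
factors by median-of-ratios, Welch t on log2-normalized counts with a 0.5
pseudocount, BH FDR) — not a negative-binomial model; external per-peak
tables are the recommended input. The significance call is compound:
FDR < 0.01 AND |log2FC| > 0.5 AND reproducibility in the condition the
peak favors.

Motif scanning scores both strands at every offset with
`log2(p_motif/p_background)` (probabilities floored at 1e-3). Per-position
p-values are exact: the null score distribution under the background is
computed by dynamic programming over the score lattice discretized at 1e-3
bins, and a hit requires p < 5e-4. The feature per (window, motif) is the
best significant hit score (count and sum modes exist; the field's usage
does not pin this down, and best-hit is the least lossy for a linear
model). Offsets containing N are skipped. The per-TF best-motif reduction
consumes an externally supplied enrichment ranking.

The lasso ranks peaks by normalized mean count, keeps the top 20 000 (all
if fewer), standardizes features, selects the penalty on a 100-point
log-spaced path by 5-fold CV minimizing held-out squared error, and
reports the mean across folds of Spearman's ρ between held-out predictions
and observed fold changes — fitting and evaluation criteria are kept
separate on purpose. Coefficients are reported on the standardized scale
with a de-standardized variant alongside. Folds come from a seeded
permutation of peaks. Gene-level peak-set statistics use the two-sided
Mann-Whitney U of a gene's peak fold changes against all peaks', exact for
small sets, BH-adjusted across tested genes.

## Synthetic generators

All generators are pure functions of (config, seed) and emit the exact
formats the pipeline consumes.

`make_sc_counts` (defaults: 2 000 cells × 2 000 genes, 3 subsets, 10
markers per subset at +2 log2 units, 50 gene cell-cycle program, lognormal
library sizes around 5 000, 50 % dropout) draws per-cell Poisson counts at
rates `baseline × 2^(subset effect + cycle intensity × loading)`, thinned
per molecule by the dropout probability. Marker-gene baselines are floored
at the median gene's baseline: a subset marker is by definition expressed
in its subset, and planting an effect on a near-silent gene would make the
ground truth unobservable in principle. Five `mt-` genes carry 5 % of each
library so mitochondrial filtering is exercisable. Poisson (not negative
binomial) is the default noise because it is the simplest model that
stresses the statistics; overdispersion would raise variance but not
change any decision logic.

`make_branching_traj` (600 cells × 120 genes, branch point at pseudotime
0.4, noise SD 0.2) drives genes by logistic trends; branch programs switch
on through a quadratic ramp so the manifold is continuous (value and slope
zero) at the split — a discontinuous onset would create a density gap that
no real differentiation continuum has and that disconnects neighbor
graphs.

`make_atac_toy` (2 000 peaks, 120 motifs of length 10 — the midpoint of
the 8–12 bp range typical of curated vertebrate motif sets — 5 active
motifs at |w*| = 0.5, SNR 2, ~5 % motif presence per window with a
per-window site cap for placement feasibility) writes sampled PWM
instances into summit windows, sets the latent fold change
`y = Xw* + ε` with `sd(ε) = sd(Xw*)/SNR`, and realizes two conditions ×
3 replicates as Poisson counts around a lognormal baseline (mean 500 per
window). Gene models are laid out so every annotation class occurs.
`make_bulk_profiles` adds Gaussian noise to log-scale centroids and
exponentiates.

What the generators do **not** emulate: ambient RNA, doublets, batch
effects, UMI saturation, negative-binomial overdispersion (available as an
option only in spirit — the Poisson default is the tested path), realistic
genome composition or peak-width distributions. Passing tests therefore
demonstrate correctness of the statistics and pipelines under controlled
conditions, not robustness to every artifact of real data.

## Problem sizes and numerics

The test suite and the acceptance script run the generators at their
default sizes (2 000 × 2 000 cells×genes; 2 000 peaks × 120 motifs;
600-cell trajectories), which exercise the full pipelines in minutes on a
single core. Sparse eigensolvers use tolerance 1e-10 and deterministic
start vectors; eigenvector and PCA signs are fixed by the
largest-magnitude-entry convention; EMD/AUC/ARI/Mann-Whitney agree with
brute-force oracles to 1e-9 or exactly, as asserted in the tests. Null
rho values in the lasso are reported as computed; a fold whose prediction
or response is constant is excluded from the rho average with a warning.

## Known limitations

- The internal differential-accessibility and differential-expression
  stand-ins are t-test-based and intentionally simple; they are loudly
  labeled and external tables are preferred.
- The default community detector is not Phenograph; stability conclusions
  under the default clusterer need not transfer to another algorithm —
  the clusterer is pluggable for exactly that reason.
- Exact motif p-values depend on the score discretization (1e-3 bins);
  two motifs differing only below bin resolution share a null.
- The k-l-NN ensemble's sample count (100) trades Monte-Carlo error
  against runtime; proximity probabilities carry ~√(p(1−p)/100) noise.
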