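# Methods

This note records the models and procedures the package implements, the
conventions it fixes where more than one reasonable choice existed, what
the synthetic generator does and does not emulate, and known limitations.

## Staging by bootstrap Spearman correlation

Given a query matrix Q (genes × samples, log₂ scale) and a stage reference
R (genes × ordered stages), the usable gene set is the intersection of Q
and R restricted to genes with log₂ expression strictly above `expr_cutoff`
(default 1) in at least one **query** sample; the reference side is not
separately filtered. Per iteration, one subset of `genes_per_iteration`
(default 50) usable genes is drawn and shared across every query × stage
pair, so each iteration yields a coherent correlation profile; Spearman's ρ
is the Pearson correlation of mid-ranks (average ranks on ties), with an
all-constant vector assigned ρ = 0 under a warning. The reported statistic
is the per-pair median over `n_iterations` (default 100) iterations —
median, not mean, for robustness to occasional unrepresentative subsets.
The trace is the per-query argmax stage, ties broken toward the earlier
stage in the reference's developmental order.

Conventions fixed here because the terminology underdetermines them:

* Subsets are drawn **without replacement** by default — "number of genes
  = k" reads as a subsample — but a classical with-replacement bootstrap is
  available (`sampling="with_replacement"`), and an exhaustive mode
  enumerates all C(n, k) subsets (capped at 2×10⁵) for oracle testing.
* One subset per iteration is shared across all pairs rather than re-drawn
  per pair; re-drawing would decouple the columns of each iteration's
  profile and make the traced path less interpretable.

Because ρ is a rank statistic, the median correlation matrix is invariant
to monotone transformations applied to both query and reference — this is
a tested property, and it is why staging is insensitive to the linear-vs-
log averaging question below.

## PCA and gene-loading density

PCA is computed on samples after centering each gene (no unit-variance
scaling: variance structure on log expression is the signal). Scores and
loadings satisfy scores = centered-dataᵀ·loadings, and each component's
sign is fixed by making its largest-magnitude loading positive, so results
are reproducible across linear-algebra backends. Joint embeddings of a
query set and a stage reference concatenate columns on the shared gene
space and decompose de novo — one PCA over all samples — rather than
projecting queries onto a reference-only basis (projection is available
separately through `LoadingPCA.transform`).

A gene's "contribution" to the embedding is its coordinate pair in loading
space. The density overlay is a product-Gaussian KDE over a gene set's
loading coordinates with per-axis normal-reference bandwidth
h_i = σ_i·n^(−1/6); the evaluation grid extends four bandwidths past the
extreme points so the numeric mass integrates to ~1 (checked to 0.05), and
contour levels default to the 0.25/0.5/0.75 quantiles of the density at
the set's own points. At n = 500 the KDE at a distribution's mode is
biased low by roughly h²/(1+h²) ≈ 11%; the 15% test tolerance reflects
this known smoothing bias, not an implementation error.

## Variable genes

Two selectors are provided. The CV² route computes per-gene means on the
stored log₂ scale and CV² = var/mean² on de-logged values, fits
CV² = a₀ + a₁/mean by least squares (the standard technical-noise form, in
which Poisson sampling gives a₁ ≈ 1, a₀ ≈ 0 — verified on simulated
counts), and selects genes above both axis thresholds (x: mean log₂
expression, default 0.5; y: log₁₀ CV², default 0.3) and above the fitted
trend. The axis thresholds are explicit configuration values, since the
procedure that motivated them does not print the values used. A
lowess-based trend (`model="loess_like"`) is the non-parametric
alternative. The top-N route ranks genes by log-scale variance after an
expression floor (≥ `min_expr` in at least one column), with a
deterministic lexicographic tie-break.

## Signatures and module scores

DE tables are consumed in a documented schema (gene_id, log2fc, padj,
base_mean); the built-in `simple_de` (Welch t-test on log values +
Benjamini–Hochberg) is a labelled stand-in so the pipeline runs without an
external negative-binomial tool, not a replacement for one. The rank
product is (−log₁₀ padj) × log₂FC with padj floored at 1e-300; the signed
log₂ fold-change (rather than linear FC) keeps "down-ranked" well defined,
and a linear-FC mode exists behind a flag.

Module scores follow the binned-control scheme: genes are placed into
`n_bins` = 25 equal-frequency bins of average expression; each signature
gene contributes `n_ctrl_per_gene` = 100 control genes drawn with
replacement (seeded) from its bin; the score is mean signature expression
minus the mean over the control multiset. The whole-universe signature
therefore scores ≈ 0 regardless of expression level, and an additive shift
of the signature genes moves the score by slightly less than the shift
(the shifted genes re-enter the control pool through their bins; the
planted +1.0 recovery lands near 0.93–0.96 at the packaged sizes, within
the ±0.1 test band).

## Temporal clustering and lineage attribution

Time-course rows are z-scored with the population (1/N) standard deviation
— a convention that must be fixed somewhere and is tested — dropping
constant rows. Fuzzy c-means uses the standard alternating updates with
random membership initialization; the fuzzifier defaults to 1.25 or to the
published size/dimension heuristic
m = 1 + (1418/N + 22.05)·D⁻² + (12.33/N + 0.243)·D^(−0.0406·ln N − 0.1134),
clipped to [1.05, 3]. Convergence is a center shift below `tol` (1e-6);
the objective Σ u^m d² is recorded per iteration and is non-increasing. A
point coinciding exactly with a center receives full membership there.
Cluster labels being arbitrary, clusters are relabeled by the time of
their center's maximum so reports are stable across runs; hard labels are
argmax memberships with ties to the lower index and no membership floor.
Lineage attribution counts each cluster's hard members inside opposing
marker sets per contrast and normalizes within the contrast; clusters with
no members from a contrast are flagged undefined rather than zero.

No automatic selection of the cluster number is attempted; c is a
parameter (pipeline default 4 on the packaged synthetic course, where the
planted structure is two shapes per branch).

## Droplet QC and normalization

Threshold comparisons follow their defining wording literally: "fewer than
3000 genes" removes < 3000 (a cell with exactly 3000 detected genes is
kept), "more than 10% mitochondrial" removes > 0.10 (exactly 10% is kept),
and embryo-profile QC excludes cells with < 6000 genes above log₂ 1.5. A
detected gene is count > 0. Mitochondrial genes are identified by the
case-insensitive "MT-" symbol prefix, the GRCh38 convention.
Normalization is value = ln(1 + count/total × 10,000) per cell, preserving
sparsity; the conservation identity Σ(e^value − 1) = 10,000 per cell is
tested to 1e-6. Stage averaging is an arithmetic mean on the stored log
scale (the common convention for log-FPKM references); if linear-scale
averaging is ever preferred, de-log before `average_by_group` — staging
itself is rank-based and insensitive to this choice.

## Synthetic data generator

The generator defines the packaged study conditions:

* **Reference**: 2000 genes × 5 stages (ICM → early TE → late TE;
  pre-implantation EPI → post-implantation EPI), baseline log₂ expression
  ~ Gamma(3, 1) (right-skewed, lognormal-like; mean 3), 50 disjoint
  markers per stage elevated by 3 log₂ units, independent N(0, 0.4) noise
  per gene × stage. Marker effect ≈ 7.5× the noise SD puts stage programs
  well clear of noise, as curated embryo references are.
* **Time course**: days 0–5, linear mixing weight w ∈ {0, .25, .5, .75, 1}
  from the naive (pre-EPI) profile toward the branch terminus (late TE or
  post-EPI), biological duplicates, additive log-scale noise. Mixing is
  linear in profile space with no intermediate marker blocks — sufficient
  to test staging directionality, not a model of formative biology.
* **Droplet cells**: cell types drawn from reference stage profiles;
  library size lognormal around 30,000 (σ_log 0.15), Poisson counts on
  de-logged depth-scaled proportions, 5% independent dropout, 13 "MT-"
  genes carrying a 3% mitochondrial share. These values were chosen once
  as realistic 10x-like magnitudes; the 8000-gene universe used for cell
  simulations keeps expected detection (~4500 genes/cell) comfortably
  above the 3000-gene QC threshold. Planted QC failures are constructed
  to fail (low-complexity cells draw from at most 1500 features; high-mito
  cells carry a 35% mitochondrial share), and the rare cell whose realized
  statistics cross its planted label is redrawn, so truth labels match the
  filter exactly; optional boundary cells sit at exactly 3000 detected
  genes and exactly 10% mitochondrial counts and must be kept.

What the generator does **not** emulate: gene–gene correlation structure,
batch effects, ambient RNA, doublets, UMI saturation, and realistic
intermediate states between branch termini. Passing recovery tests on this
generator demonstrates that the statistics behave as designed under their
own assumptions (rank stability, mean–CV² structure, marker-driven
separation); it does not certify performance on real embryo data, where
shared programs, batch structure and annotation mismatches add noise the
generator omits.

## Numerical choices and degenerate inputs

* Spearman of any constant vector is 0 (warned), keeping correlation
  matrices total; padj is floored at 1e-300 before log₁₀.
* All tie-breaks are deterministic: lexicographic gene id in rankings,
  earlier reference stage in traces, lower cluster index in hard labels.
* Every stochastic routine takes an explicit seed; pipelines propagate one
  global seed with fixed per-module offsets, and output tables are written
  with a fixed float format so re-runs are byte-identical (verified by
  hashing in the manifest).
* Readers refuse missing values rather than imputing; duplicate gene rows
  collapse by sum (counts) or mean (other scales) with a warning;
  duplicate sample identifiers are an error.
* Gene identifiers are opaque strings matched exactly and case-sensitively;
  no ortholog or symbol mapping is attempted.

## Problem sizes in tests and the acceptance script

Recovery checks run at deliberately modest sizes — 2000-gene bulk
references, 50-seed staging recovery restricted to the informative samples
(final-day TE branch, day-0 formative branch), 100-cell droplet matrices,
200-gene two-shape clustering over 20 seeds — sizes at which every planted
effect is already decisively detectable, so larger simulations would add
runtime without adding discrimination.

## Limitations

* The built-in DE test is a Welch t-test on log values; count-model
  dispersion estimation is intentionally out of scope, and external DE
  tables are first-class inputs.
* Nonlinear embeddings (UMAP/t-SNE) are delegated to external tools; only
  linear PCA is provided.
* The CV² axis thresholds and the density contour quantiles are honest
  free parameters; no attempt is made to recover unpublished values.
* Fuzzy c-means is locally convergent; different seeds can yield different
  optima on weakly structured data. The packaged defaults are tested only
  on clearly separated temporal shapes.
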