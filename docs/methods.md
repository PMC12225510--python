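# Methods

This note documents the models and procedures implemented in
`cimp_atlas`, the parameters that matter, the synthetic-data design, and
the numerical and design choices made where more than one reasonable
option existed.

## CIMP-CGI calling

The unit of analysis is the CpG island (CGI), summarized as a mean beta
value per sample. A CGI is called CIMP for a candidate tumor subtype
when three criteria hold jointly:

1. **Hypermethylation** relative to the pooled CIMP-negative subtypes:
   Δβ = (candidate group mean) − (pooled negative mean) > `delta_min`
   (default 0.2 beta units). Pooling is at the sample level, not a mean
   of group means, so unequal negative-group sizes are weighted by their
   samples. The signed form encodes the hypermethylation direction; an
   absolute-difference variant is available (`use_abs_delta`).
2. **Low normal methylation**: mean beta over the normal reference
   group < `normal_max` (default 0.75). The mean over normal samples is
   used rather than requiring every normal sample individually to pass.
3. **Subtype specificity**: a Kruskal–Wallis test per CGI across the
   tumor subtype groups on per-sample betas, Benjamini–Hochberg adjusted
   across all tested CGIs, with adjusted p < `adj_p_max` (default
   0.001). The adjustment method is configurable (BH or Bonferroni), as
   is the group set entering the test.

Kruskal–Wallis uses the tie-corrected H statistic with the chi-square
approximation (df = groups − 1). For whole matrices a vectorized
rank-based evaluation is used; rows with missing values fall back to a
per-row path on the available samples, and the vectorized path is
cross-checked against the scipy implementation in the unit tests.
Degenerate all-identical rows report H = 0, p = 1. Missing beta values
are propagated, never imputed; a CGI missing any criterion value is
excluded from calling with a logged count.

A per-sample **CIMP methylation score** is the missing-aware mean beta
over a called CGI set; survival association is estimated by a Cox
proportional-hazards fit of event hazard on that continuous score
(partial likelihood, Efron tie handling via lifelines), reporting the
coefficient, hazard-ratio confidence interval and Wald p.

Array perturbation experiments are summarized by a per-CpG log2 beta
ratio with an `eps = 1e-3` pseudocount (the ratio is undefined at
beta = 0): gain above +0.01, loss below −0.01.

Genomic-context enrichment between two CGI sets uses an exact one-sided
binomial tail with the comparison set's proportion as the null rate.

## CGI–gene annotation

Coordinates are 0-based, half-open everywhere. The promoter window is
strand-aware: [TSS − 2000, TSS + 500) on the plus strand and its exact
mirror on the minus strand (half-open mirroring shifts the window by one
base, which the implementation handles so that reflecting all
coordinates and strands reproduces mirrored annotations exactly).
Context precedence is promoter > intragenic > intergenic; a CGI may
target several genes; TSS distance is measured from the CGI midpoint.
The promoter extent is a convention, not a biological constant, so both
window sizes are parameters. Overlap queries are simple per-chromosome
scans: at the scale this package targets (tens of thousands of CGIs,
thousands of genes) an interval index buys nothing and the plain scan
keeps the window semantics transparent.

## Chromatin-signature factorization

The CGI × (mark, context) matrix V is decomposed as V ≈ W·H with
W (CGI × k) the signature exposures and H (k × features) the signature
definitions. The optimizer is the multiplicative-update scheme for the
squared Frobenius objective (Lee–Seung), which guarantees a
nonincreasing error sequence; the error trace is recorded and asserted.
Each run starts from uniform random nonnegative factors scaled to the
data magnitude; `n_init` (default 20) independent initializations are
run and the lowest final error is kept, with all per-initialization
errors retained for stability inspection. Early stopping triggers when
the relative error improvement between checkpoints (every 10
iterations) falls below `tol` (default 1e-6); the iteration cap defaults
to 10^4. The factorization rank is a user decision (default k = 4);
`rank_survey` reports reconstruction error, explained variance and an
exposure-cluster silhouette per k but never auto-selects.

Exposures are normalized per CGI by the row maximum, so every CGI
reaches 1.0 in some signature and the ≥ 0.8 assignment threshold
guarantees at least one assignment; row-sum normalization cannot
guarantee that totality and was rejected. Comparisons to planted factors
always apply unit-normalization and optimal permutation matching
(Hungarian algorithm on cosine similarity), since NMF is identifiable
only up to permutation and diagonal rescaling. Signature enrichment of a
CGI set uses a 2×2 Fisher exact test with a Haldane–Anscombe 0.5
correction for zero cells in the odds ratio.

## CIMP-class prediction

Nine predictors per CGI: progenitor DNA methylation, six histone marks
(H3K27ac, H3K4me1, H3K4me3, H3K27me3, H3K9me3, H3K36me3), CGI length and
TSS distance. CGIs labelled with both phenotypes are excluded, as are
rows with any missing predictor (logged). Training uses a stratified
70/30 split; repeated stratified cross-validation (default 10 folds × 5
repeats) on the training portion selects the per-split candidate-feature
count, with the majority class downsampled to the minority size inside
every CV resample (re-drawn from the run seed). The final forest
(default 2000 trees) is evaluated once on the untouched test split. AUC
is the rank-based Mann–Whitney form with ties counted half,
cross-checked against scikit-learn. Importances are impurity-decrease
based, normalized to percent (permutation importance is available as an
option); the forest internals are scikit-learn's.

## Epigenetic dynamics

**Structure learning** is greedy hill-climbing over DAGs with the
Gaussian BIC network score: per node, the log-likelihood of a
linear-Gaussian local model given its parents minus (k/2)·log n for its
k free parameters. Moves are single-edge additions, deletions and
reversals; candidates are enumerated in sorted node order and the best
strictly improving move applied, making the search deterministic for a
given dataset. Constant features are excluded with a log message.

**Bootstrapping** learns a structure on each of R nonparametric
resamples of the CGIs (default R = 200; the property benchmarks use
R = 100). Edge strength is the fraction of resamples containing the edge
in either direction; direction confidence is the majority-direction
fraction among those. The consensus keeps edges with strength ≥ 0.5,
oriented by majority; any residual cycle is broken by dropping its
weakest edge, which preserves high-confidence edges deterministically.
Edge signs are the signs of Pearson correlations of the incident
features over the input CGIs.

**Rank differences** rank CGIs per feature with rank 1 = highest value
and ties broken by input order ("first"), then diff = rank_tumor −
rank_reference; a negative difference is a gain in the tumor.
DNA-methylation and H3K27me3 differences define the gain/loss quadrants;
an exact zero difference is labelled neutral and excluded from quadrant
counts rather than being forced onto a side.

## Cell states

The **module score** follows the binned-control construction: genes are
split into 24 equal-size bins by dataset-average expression, and for
each set gene 100 control genes are sampled with replacement from its
bin, excluding the set itself from the pool (so dilution cannot shrink a
planted effect); score = mean(set) − mean(controls) per cell. A random
gene set drawn within a bin therefore scores ~0 by construction, which
the tests assert. The CIMP expression score applies this to the
promoter-target genes of a phenotype's called CGIs; whether intragenic
targets are included is an explicit parameter since analyses differ in
which target definition they need. For log2 fold changes of scores,
negatives are clamped to 0 first and an `eps = 1e-9` pseudocount guards
the log.

**Deconvolution** regresses each bulk sample's expression on the
gene × state reference profile matrix by ordinary least squares,
then clamps negative coefficients at 0 and renormalizes to proportions
summing to 1; raw coefficients are returned alongside, and a direct
nonnegative (NNLS) variant is available. The reference must be full
column rank. NPC1/NPC2 and MES1/MES2 modules are merged by union where
module-level sets are used.

**Coupling tests**: per-gene Spearman correlation of CGI beta versus
expression within sample groups, compared between groups by a paired
two-sided Wilcoxon signed-rank over genes; paired targeted-versus-
untargeted marker expression per sample uses the same signed-rank test
on per-sample differences. Where cell populations are not actually
paired, the rank-sum test is the appropriate alternative and both are
reachable through scipy; the implemented comparisons only use the
signed-rank form where a true pairing (same sample, same gene) exists.

**Sparse single-cell methylation** pools covered CpGs per cell group
within each CGI and reports m/(m + u); the literal m:u ratio is
available behind a flag, but the bounded fraction is the default since
it remains defined when u = 0 is approached and is comparable across
coverage levels.

## Synthetic data

One master seed drives every generator through independently spawned
sub-streams (`numpy.random.SeedSequence`; PCG64), so a fixed seed gives
bitwise-identical outputs.

- **Methylation cohort**: subtype sizes default to 12/18/12/18 tumors
  (IDH/MES/RTK1/RTK2) plus 6 normals, the cohort structure the analysis
  targets. Background CGIs draw a baseline mean from a balanced bimodal
  beta mixture (Beta(2,8) / Beta(8,2)), reflecting the empirical
  low/high bimodality of CGI methylation. Planted CIMP CGIs (default
  1000 per phenotype in a 20,000-CGI genome) get +Δβ = 0.3 in their
  phenotype's samples only, with baselines drawn low enough that normal
  means stay below the 0.75 cap. Per-sample noise is Gaussian
  (sd 0.05) around the group mean, clipped to [0, 1] — a symmetric
  concentration model that preserves boundedness without materially
  shifting means at this sd.
- **Chromatin signals**: H rows load on disjoint feature blocks
  (values U(1, 2) against a 0.05-level floor), W rows are near one-hot
  (U(0.75, 1.25) at the member signature), and additive half-normal
  noise (sd 0.1) keeps V nonnegative. Fourteen features = seven marks ×
  two biological contexts.
- **Expression coupling**: one gene per CGI with
  expr = baseline·exp(−coupling·beta)·exp(noise) — the simplest
  monotone-silencing model; coupling 0 gives no association.
- **Single cells**: four disjoint 30-gene state modules (AC/MES/NPC/OPC)
  over a lognormal background; a cell's own module is upshifted by 2 log
  units. Bulk pseudo-samples are Dirichlet mixtures of the state mean
  profiles with multiplicative lognormal noise.
- **Survival**: exponential event times with hazard
  baseline·exp(coef·score) and independent exponential censoring.
- **Sparse CpG calls**: per cell, each CpG is covered with a fixed
  probability and methylated with the CGI's true fraction.

What the generators deliberately do not emulate: probe-level array
artifacts, spatial correlation along the genome, batch effects,
compositional coupling between marks, realistic gene-length or
GC-content confounders, and doublets or ambient contamination in single
cells. Passing the planted-truth benchmarks therefore demonstrates the
correctness and calibration of the statistical machinery under the
stated noise model, not robustness to every artifact of real data.

## Benchmark problem sizes

The planted-truth benchmarks (also run by `scripts/acceptance.py`) use:
20,000 CGIs with 1,000 planted per phenotype for caller recovery;
10,000 null CGIs for KW calibration and 20 replicates of a
1,000-test mixture (20% non-null) for BH FDR; 5,000 × 14 signals with
k = 4, 20 initializations and a 2,000-iteration cap for NMF recovery;
300 CGIs per class, 300 trees, 5 × 2 CV and 10 permuted-label seeds for
classifier calibration; n = 2,000 and R = 100 for the chain network;
2,000 CGIs with 200 planted for the quadrants; 50 bulk samples at noise
sd 0.1 for deconvolution; and 50 recovery plus 100 null replicates
(n = 500 / 300) for the Cox fit. These sizes give stable Monte-Carlo
estimates while keeping a full run around a minute on one CPU.

## Known limitations

- The Bayesian-network consensus reports linear-Gaussian dependence
  structure; it supports no causal or interventional claims.
- The chi-square approximation to the Kruskal–Wallis null is slightly
  conservative at the cohort's group sizes (observed null rejection
  ~0.045–0.048 at α = 0.05), which is acceptable for a screening
  criterion applied with a much stricter adjusted-p cutoff.
- OLS deconvolution assumes the reference profiles span the bulk
  mixture; unmodelled states bias proportions toward their nearest
  modelled neighbour.
- NMF multiplicative updates converge to local optima; best-of-20
  initializations is a heuristic, and per-initialization errors are
  exposed so users can judge stability.
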