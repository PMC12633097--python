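# Methods

`vascnet` implements a multi-stage inference chain for multiplexed (TMT)
brain proteomes enriched for cerebrovascular tissue: normalisation and
batch correction, covariate cleanup, signed weighted co-expression network
construction with module refinement, trait-association scans, permutation
module enrichment, and cross-network module preservation. A seeded
synthetic-data generator reproduces the statistical structure of such a
cohort so that every stage can be validated against planted ground truth.

## Synthetic cohorts

The generator draws, per protein `g` and subject channel `s`,

    log2 A_gs = base_g + lambda_g * f_{m(g),s} + b_{batch(s)} + d_{g,batch(s)}
                + sum_c beta_gc (c_s - mean c) + eps_gs

with intensities `2**log2 A`. Modules are latent factors `f_m ~ N(0,1)`
(standardised exactly per module); loadings `lambda_g ~ N(1, 0.3^2)`,
resampled away from zero (|lambda| >= 0.25) so planted membership is
recoverable. Defaults emulate the targeted cohort scale: 400 proteins, six
planted modules of 50, 120 subject channels dealt round-robin over 7
batches, base abundances uniform on 10–20 log2 units.

Batch structure has two components: a scalar log2 offset per batch
(`b ~ N(0, 0.5^2)`) and per-protein deviations around it
(`d_gb ~ N(0, (0.8 * 0.5)^2)`). The second component is essential:
sum-scaling (below) cancels any offset common to all proteins, so a purely
scalar batch model would leave the ratio-based batch correction with
nothing observable to remove; protein-specific plex effects (digestion,
labeling and co-isolation differences) are precisely what the pooled
standard is run in every batch to cancel.

Each batch carries one global internal standard (GIS): a single pooled
all-sample mixture, modelled as the global per-protein mean of subject
intensities, measured in each batch with that batch's `b + d` applied and
log2 measurement noise of `noise_sd/4`. A GIS cell is missing only when
the protein was never measured in any subject channel. (A per-batch pool
was considered and rejected: dividing by a within-batch mean subtracts the
batch-mean of each module's latent factor — genuine between-batch biology —
and does not describe a physical pooled standard.)

Residual noise `noise_sd = 0.7` is calibrated jointly with the batch terms
so that planted within-module |bicor| averages at least 0.5 — modest,
realistic co-expression rather than an easy caricature.

Missingness is missing-not-at-random: a cell is dropped with probability
`logistic(steepness * (midpoint - log2 A))` (defaults 1.0 and 9.0, giving
~4–6% overall, concentrated in low-abundance proteins). Zeros are never
emitted; missing is explicit.

Traits derive from the planted factors: an ordinal 0–3 severity score
through a proportional-odds link with equally spaced cutpoints
(-1.1, 0, 1.1), binary lesion flags through logistic links, a continuous
burden through a linear link with unit residual sd on the standardised
factor scale. Default effect sizes: ordinal beta 0.8 (module 1), binary
0.8 / 0.6 (modules 2–3), linear 0.5 (module 4). Covariates (age, PMI,
endothelial cell proportion) act through per-protein coefficients drawn
from zero-mean normals.

What the generator does **not** emulate: peptide-level quantification,
reporter-ion ratio compression, isotopic interference, correlated
missingness between co-eluting proteins, and non-Gaussian abundance
distributions. Passing tests therefore demonstrate correctness of the
statistical machinery under a faithful but idealised abundance model, not
performance on raw instrument output.

## Preprocessing

Zeros are recoded as missing, then each sample is scaled so its
present-intensity sum equals the maximum sample sum; proteins with >= 50%
missing values are removed (strict inequality, parameterised); the matrix
is log2-transformed. Sample outliers are flagged when a score on either of
the first two principal components (per-protein mean imputation for the
decomposition only) exceeds 4 sd of that component — a deliberately
conservative, single-pass rule; removal is a separate explicit step.

## Batch correction (median polish of ratios)

Each sample is expressed as a log2 ratio to its batch's denominator — the
median over the batch's GIS channels (default) or over all non-GIS
channels (`use_all_non_gis`). Then protein rows (medians over the
denominator-defining channels) and sample columns are alternately
median-centered until every such median is below `tol = 1e-8` (cap 250
sweeps). All arithmetic is additive in log2, equivalent to a
multiplicative polish and exactly idempotent at convergence. With one GIS
channel per batch, the GIS ratio columns are identically zero, row medians
vanish and the polish converges in one or two sweeps; with the all-non-GIS
denominator, convergence is linear and slower. Proteins with no usable
denominator in some batch are dropped with a warning rather than imputed.
GIS columns are corrected alongside but excluded from output by default.

## Covariate regression

Per protein, log2 abundance is regressed on the nuisance covariates
(endothelial proportion, age, PMI, batch by default; categorical terms
one-hot with a reference level) over 1000 bootstrap resamples of samples;
the median bootstrap coefficient of each nuisance term, times the centered
covariate, is subtracted. Protected terms (e.g. diagnosis) can be included
in the fit without being subtracted. Centering preserves each protein's
grand mean. The masked normal-equation solver handles per-protein
missingness in a single batched pass. Note that regressing batch after
ratio-based correction also removes each factor's between-batch mean — a
small (~1/(samples per batch)) loss of genuine signal that is inherent to
the published procedure, not an implementation artefact.

Diagnostics use a simplified variance partition: marginal single-factor
R² per protein, reported as quantiles. A mixed-model partition was not
needed because nothing downstream consumes these numbers.

## Network construction

Correlations are biweight midcorrelations (median/MAD Tukey weights,
pairwise-complete, minimum 4 shared observations; zero-MAD vectors fall
back to Pearson and are flagged). Signed adjacency `((1+C)/2)^8`,
topological overlap with the mean-connectivity denominator, average-linkage
clustering of 1 − TOM.

Tree cutting applies the quantile rule `q = 0.99 − 0.02*deepSplit`
(deepSplit 3 by default) first globally and then recursively inside each
candidate branch: a branch at least twice the minimum module size whose
own-subtree quantile cut produces two or more sub-branches of at least 10
proteins is split. The recursion matters because TOM merge heights
compress into a narrow band near 1, where a single global threshold can
land on the wrong side of a between-module merge; over-splits are repaired
by the eigenprotein merge step. Branches below 10 proteins dissolve to
unassigned. A PAM-like stage then attaches each unassigned protein to the
module with the smallest average 1 − TOM dissimilarity, provided that
module appears in the smallest dendrogram clade containing the protein and
at least one assigned protein (the dendrogram-respecting constraint) and
the dissimilarity beats the protein's dissimilarity to the unassigned
pool.

Module eigenproteins are the first right-singular vectors of the
member-z-scored matrices (per-protein mean imputation inside the
decomposition only), scaled to unit variance and oriented so their bicor
with the module's mean z-profile is nonnegative. Modules whose
eigenproteins cluster below dissimilarity 0.07 (1 − Pearson r, average
linkage) are merged iteratively. Membership is then refined by up to 30
sweeps of three kME rules — (1) a member whose kME to its own module falls
more than 0.10 below its best kME moves to the best module, (2) an
unassigned protein with any kME above 0.30 is assigned, (3) a protein with
all kMEs below 0.30 goes grey — recomputing eigenproteins and kMEs after
each sweep until a fixed point. Final modules are renumbered by
nonincreasing size (ties: smaller original label first).

kME/correlation p-values use the Student-t transform
`t = r * sqrt((n-2)/(1-r^2))` with n−2 degrees of freedom.

## Trait associations

Module level: bicor of each eigenprotein with each numeric-coded trait,
with t-based p-values and a two-colour heatmap export. Group differences:
Welch t (the unequal-variance form is the safer default for a two-group
comparison) or one-way ANOVA with Tukey HSD; Tukey p-values below 1e-8.5
are replaced by Bonferroni-corrected pairwise p-values (the studentized
range loses numerical accuracy that deep in the tail). Proteome-wide
scans fit, per protein, outcome ~ protein + covariates with OLS
(continuous), logistic (binary lesions) or proportional-odds logit
(ordinal severity; L-BFGS, gradient tolerance 1e-8, protein standardised
for stability, beta reported on that scale). The protein is the exposure
and the pathology the outcome. Complete-case per scan; separation or
non-convergence flags the protein and removes it from the adjusted
ranking. Multiplicity control is Bonferroni (with the explicit 0.05/m
cutoff reported) or Benjamini-Hochberg.

## Permutation module enrichment

For a set of per-gene p-values (e.g. an ordinal CAA scan), each module's
mean transformed statistic is compared with means over random same-size
gene draws from the background of all genes with statistics (unassigned
genes included in the background, not tested). The default transform is
−log10 p, so larger means more significant and positive Z means
enrichment; a raw-p mode is provided (its Z flips sign) and a signed
−log10 p mode accepts per-gene direction signs. Z = (T − mean T*)/sd T*;
the one-sided exact p is (#{T* ≥ T} + 1)/(m + 1), computed by full subset
enumeration whenever the number of distinct subsets is at most 10x the
requested permutation count (the observed subset then appears once in the
enumeration). The (b+1)/(m+1) estimator is conservative; a
finite-population correction was considered unnecessary at 10,000
permutations. Zero-variance nulls return p = 1 with a degenerate flag.
BH correction runs across modules, with the Z thresholds at 5% and 10%
FDR reported for plotting.

Marker/ontology overlap uses the one-sided Fisher exact test
(hypergeometric upper tail) on GMT sets intersected with the background,
sample odds ratio ad/bc (infinity allowed), BH across the module x set
grid.

## Module preservation

Reference-defined modules are scored in a test dataset on a reduced,
documented battery: density = mean within-module |bicor| and mean |kME| in
the test data; connectivity = correlation of intramodular connectivity
(row sums of within-module |bicor|) and of the within-module correlation
entries between reference and test. Each statistic is standardised against
500 random same-size gene sets; Zdensity and Zconnectivity are the medians
of their pairs, Zsummary their mean (degenerate-null statistics are
dropped from the medians). Classification: Zsummary >= 10 highly
preserved, >= 1.96 preserved, below not preserved (both inclusive). The
full published statistic battery is intentionally not reproduced; the
validated property is the ordering self-test > preserved threshold >
destroyed-structure test on planted modules.

## Orchestration and reproducibility

A single root seed spawns per-stage substreams (`SeedSequence([seed,
stage])`, kept below 2^31) so stages can be rerun in isolation; the whole
run is byte-identical across executions. Configs are YAML with fail-fast
rejection of unknown keys. Every stage writes TSV/JSON artifacts plus a
machine-readable run report of counts, iterations and convergence flags.

## Problem sizes used in validation

The test and acceptance workloads run the full pipeline at the default
cohort scale (400 proteins, 120 channels, 5 seeds), scan calibration on
2,000 null fits per model at n = 300, enrichment with 10,000 permutations,
and preservation with 200 permutations over 3 seeds — sizes chosen so the
whole validation cycle completes in a few minutes on one CPU while keeping
every Monte-Carlo interval tight enough to be meaningful.

## Known limitations

- The tree cut is a quantile-recursive approximation of the reference
  dynamic hybrid algorithm; label-identical agreement with that
  implementation is not a goal (planted-structure recovery is).
- Ordinal/logistic scans rely on asymptotic Wald inference; at very small
  n or quasi-separated proteins the flags matter.
- The preservation battery is reduced (4 statistics); absolute Zsummary
  values are not comparable to the full published battery, though the
  classification thresholds are applied identically.
- Bootstrap regression subtracts point estimates (median over resamples);
  it does not propagate uncertainty downstream.
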