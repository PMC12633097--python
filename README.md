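# vascnet

Co-expression network analysis for cerebrovascular-enriched brain
proteomes.

Cerebral amyloid angiopathy (CAA) — amyloid-β deposition in the walls of
brain vessels — is scored 0–3 at autopsy and accompanies white-matter
hyperintensities, microbleeds and infarcts on imaging. Multiplexed (TMT)
proteomics of vessel-enriched tissue can link protein co-expression
modules to these traits, but only after the technical structure of
multiplexed data (batch effects, pooled-standard channels, abundance-
dependent missingness, nuisance covariates) is removed and the module and
enrichment statistics are computed carefully. `vascnet` implements that
chain as a tested, reusable library with a CLI, and ships a seeded
synthetic-cohort generator so every stage can be validated against
planted ground truth.

## The method

1. **Normalisation** — zeros become explicit missing values; each sample
   is scaled to the maximum present-intensity sum; proteins with ≥ 50%
   missingness are dropped; log2 transform; PCA-based sample outlier
   flags.
2. **Batch correction** — median polish of ratios: log2 ratios of each
   sample to its batch's pooled global-internal-standard (GIS) channel,
   then alternating protein/sample median centering until all medians
   < 1e-8.
3. **Covariate regression** — per protein, the median coefficient over
   1000 bootstrap OLS fits of abundance on cell proportion, age, PMI and
   batch is subtracted (protected terms can be fitted without removal).
4. **Network** — biweight midcorrelation C, signed adjacency
   `A = ((1+C)/2)^8`, topological overlap
   `TOM_ij = (Σ_u A_iu A_uj + A_ij)/(mean(k_i,k_j) − A_ij + 1)`,
   average-linkage clustering of 1 − TOM with a recursive quantile cut
   (deepSplit 3, minimum module size 10), eigenproteins (first principal
   component of each module, ME), merging of modules with cor(ME) > 0.93,
   and iterative kME-rule membership refinement (gap 0.10, floor 0.30).
5. **Associations** — ME–trait bicor heatmaps; Welch t / ANOVA+Tukey
   differential abundance; proteome-wide scans with the protein as
   exposure: OLS (continuous burden), logistic (binary lesions),
   proportional-odds logit (ordinal CAA severity), Bonferroni or BH
   corrected.
6. **Enrichment** — permutation test of each module's mean −log10 p
   against random same-size gene draws:
   `Z = (T − mean T*)/sd T*`, exact p = (b+1)/(m+1), 10,000 permutations
   (full enumeration on small backgrounds); one-sided Fisher/GMT overlap
   for marker sets.
7. **Preservation** — density and connectivity statistics of
   reference-defined modules in a test proteome, standardised against 500
   random gene sets; `Zsummary ≥ 1.96` preserved, `≥ 10` highly preserved.

See `docs/methods.md` for assumptions, parameter defaults and known
limitations.

## Worked example

```python
import vascnet as v

X, manifest, truth = v.generate_dataset(v.SynthConfig(seed=1))
Xl = v.log2_transform(v.filter_missing(v.sum_scale(X)))
Xc, state = v.tampor_correct(Xl, manifest)
Xr = v.bootstrap_regress(Xc, manifest, v.RegressionSpec(n_bootstrap=1000, seed=3))
net = v.build_network(Xr)

scan = v.proteomewide_scan(Xr, manifest, "caa_severity", "ordinal", ["age", "sex"])
enr = v.permutation_module_enrichment(scan.set_index("id")["p"], net.labels,
                                      n_perm=10000, seed=7)
```

Output for this seed:

```
matrix: 400 proteins x 127 channels
tampor: converged in 1 iteration(s)
modules: {1: 57, 2: 50, 3: 50, 4: 50, 5: 50, 6: 50, 7: 49} grey: 44
ordinal CAA scan: 400 proteins, Bonferroni cutoff 1.25e-04, 22 significant
top enriched module: M2  Z=17.3  p_perm=1.00e-04
ARI vs planted modules: 0.867
```

Reading this: the generator planted six 50-protein modules among 400
proteins across 7 TMT batches; after correction the network recovers them
(adjusted Rand index 0.867 against the planted labels — the extra module
is a background-noise cluster). The ordinal severity trait was generated
from the first planted module's latent factor with β = 0.8; the
proteome-wide proportional-odds scan flags its members (22 proteins past
the Bonferroni line 0.05/400), and the permutation enrichment ranks that
module first with Z = 17.3 and the smallest representable exact p at
10,000 permutations (1/10001).

The same chain is available from the shell:

```bash
vascnet --seed 1 --outdir out run-all
```

which writes every stage's TSV/JSON artifact and a machine-readable
`run_report.json`.

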