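# Methods

## The model

`regulasso` explains per-tumor gene expression change from regulatory
genomics. For tumor *k* and gene *g*, the response is the log2 expression
fold change against the normal-tissue reference,

    y_{g,k} = expr_{g,k} − mean_normals(expr_g),

and the model is a linear combination of the gene's regulatory inputs:

    y_g = W_CN·C_g + W_DM·D_g + Σ_TF W_TF·N_{g,TF} + Σ_miR W_miR·N_{g,miR}

with C_g the gene-level copy-number score (GISTIC2-style, −2…2), D_g the
promoter methylation beta value (0…1), and N_{g,TF} / N_{g,miR} the
binding-site counts of each transcription factor in the gene's promoter
and each miRNA in its 3′UTR. One model is fitted **per tumor** with an L1
(lasso) penalty, so each tumor gets its own sparse coefficient vector
W = (W_CN, W_DM, W_TF…, W_miR…). Only genes called differentially
expressed (yin = up, yang = down; |logFC| ≥ 1 and BH FDR < 0.05 from a
per-gene Welch t-test) enter the regression rows, and only miRNAs whose
own expression changes in that tumor (|log2 fold change| strictly above a
threshold, default 0) are admitted as columns.

Two deliberate deviations from common practice in this design:

* **Welch's t-test instead of an empirical-Bayes moderated t.** The
  moderated test shrinks per-gene variances across genes and differs from
  Welch mainly at very small sample sizes; with dozens of samples per
  group the calls are nearly identical, and Welch keeps the package free
  of a specialized external dependency. This is a known, intentional
  difference.
* **An intercept is included** even though the structural equation has
  none: the response is a fold change with a nonzero mean, and forcing
  the fit through the origin would leak that mean into the coefficients.
  `fit_tumor_lasso(..., fit_intercept=False)` disables it.

## Penalty selection and numerics

The penalty λ is chosen per tumor by K-fold (default 10) cross-validation
over genes: a glmnet-style grid of 100 log-spaced values from λ_max (the
smallest penalty that zeroes every coefficient) down four decades, the
CV-minimum mean-squared-error rule, then a refit on all genes at the
chosen λ. Features are standardized to unit variance inside the solver so
the penalty treats count-scaled binding columns and unit-interval
methylation comparably; coefficients are reported back on the original
scale. Fold membership comes from a seeded shuffle of gene indices and is
shared across compared feature subsets, so subset comparisons are paired.
The coordinate-descent solver runs at tolerance 1e-10, which keeps the
Karush–Kuhn–Tucker residuals of the returned solution below 1e-6 (this is
asserted in the test suite). Constant columns get coefficient zero;
models report the mean held-out Spearman rank correlation between
predicted and observed fold changes at the chosen λ.

Model variants are compared by the per-tumor mean CV Spearman correlation
along the ladder miRNA-only → +TF → +CNV → +DM, with a two-sided Wilcoxon
signed-rank test on the paired per-tumor correlations, and against a
baseline in which the response's gene labels are permuted per tumor
before fitting.

## Regulator scoring and the permutation null

A regulator r matters for subtype S to the extent that removing it from
the already-fitted models hurts them. The score is the increase in total
squared training loss when r's coefficient is set to zero in every model
of S, **without refitting**:

    score(r, S) = Σ_g Σ_{k∈S} [(y_{g,k} − W_k^{r→0}·X_{g,k})² − (y_{g,k} − W_k·X_{g,k})²]

Because each model is at its optimum, this quantity is non-negative and
exactly zero for regulators the lasso never selected. It is computed in
closed form from the residuals (2·w_r·x_rᵀe + w_r²‖x_r‖²), which the test
suite checks against a naive double-loop recomputation.

Significance comes from a permutation null: one draw permutes **every**
TF and miRNA binding column independently over genes (destroying
regulator–gene assignments while preserving each column's count
distribution), retrains every tumor's lasso on the permuted design, and
recomputes all scores. The empirical p-value uses the add-one correction
p = (1 + #{null ≥ observed}) / (1 + n_perm), and Benjamini–Hochberg runs
within each subtype across the combined TF+miRNA list; regulators with
FDR < 0.05 are selected. Two implementation choices:

* **Joint column permutation.** Permuting all columns in one draw gives a
  null sample for every regulator from a single retraining pass; a
  per-regulator permutation scheme would multiply the retraining cost by
  the number of regulators for no change in the marginal null of any one
  column.
* **λ reuse by default.** Permutation refits reuse each tumor's fitted λ
  rather than re-running the full CV per draw; the penalty is a property
  of the (unchanged) response scale and dimensionality, and re-tuning
  5000 times multiplies cost by roughly the grid-times-folds factor.
  `null_distribution(..., retune_lambda=True)` re-tunes per draw for
  users who want the fully nested procedure.

Permutation draws use independent child seeds of one root seed, so
results are bit-identical for any worker count. Default draw counts are
200 in tests and examples; production runs should use several thousand
(the add-one p-value floor, and hence the reachable FDR, is set by the
draw count).

Selected sets from the four subtypes are cross-classified into
common / shared / subtype-specific groups by the exact subtype
combination selecting each regulator.

## Enrichment and network export

A regulator's target list is the set of genes with a nonzero binding
entry, intersected with the yin/yang genes. Enrichment against a GMT
collection uses the hypergeometric upper tail P(X ≥ k) with the universe
defaulting to all genes in the collection, gene-set size window 2–500 for
pathway collections (10–500 for GO-style collections), BH adjustment over
tested sets, and default reporting cutoffs FDR < 0.01 (pathways) /
FDR < 0.05 (GO). The network export lists (regulator, target, hits) rows
for selected regulators and pathway-member targets with nonzero binding,
in deterministic (source, target) order, as TSV and SIF.

## Signatures and survival

* **YMR** (yin/yang mean ratio): per patient, mean log2 expression of the
  yin set divided by the mean of the yang set. Patients strictly above
  the cohort mean are high-risk; ties go to low-risk.
* **CRS** (combined risk score): Σ_i x_i·coef_i over chosen regulators,
  where coef_i is the log hazard ratio from a univariate Cox
  proportional-hazards fit (Breslow tie handling, Newton iterations to
  gradient tolerance ~1e-9). CRS groups are cut at the empirical 65th
  percentile (linear-interpolation/type-7 quantile), strictly-above →
  high risk.

Group separation is evaluated with the Kaplan–Meier product-limit
estimator and the two-group log-rank chi-square test. Fixed-horizon
analyses (e.g. five-year survival) are implemented by administrative
censoring at the horizon.

## The synthetic-data generator

`generate_dataset(SimConfig)` produces a complete aligned cohort whose
default shape is the package's study condition: 4 subtypes × 25 tumors,
20 normals, 300 genes, 20 TFs, 30 miRNAs, 5 planted regulators per
subtype with coefficient magnitude 1.0, response noise SD 0.5, binding
density 0.1, binding counts capped at 5.

* Binding counts are Bernoulli(density) × (1 + Poisson(1)), truncated —
  sparse non-negative integers like motif-hit matrices.
* Background methylation is Beta(2,2); background CNV is categorical
  centered on 0 (±1 at 20%, ±2 at 5%).
* Per-tumor CN and DM weights are N(1, 0.1) and N(−1, 0.1): copy number
  acts positively and promoter methylation repressively, with tumor-level
  variability.
* 10% of genes are planted "yin" (amplified: CNV ∈ {1,2}, hypomethylated:
  Beta(2,12)) and 10% "yang" (deleted, hypermethylated: Beta(12,2)), so
  differential expression arises **through the model itself** and the
  zero-noise dataset satisfies the generative identity exactly — refitting
  with a vanishing penalty recovers every planted coefficient.
* Planted regulator coefficients are ±effect_size, constant within
  subtype; planted miRNAs are forced to |fold change| ≥ 0.5 in their
  subtype so a fold-change admission rule cannot silently drop them.
* Tumor expression is the realized normal mean plus the generated fold
  change; baselines are drawn U(9,14) on the log2 scale and floored so no
  planted downshift produces negative expression.
* Survival times are exponential with rate hazard_scale·exp(score) for a
  caller-supplied risk score; the independent exponential censoring rate
  is solved numerically to hit the requested censored fraction.

One root seed fans out into per-component substreams (binding, planted
effects, CNV, methylation, weights, miRNA fold changes, noise, baselines,
pathways), so e.g. changing the normal count does not change the binding
matrices.

What the generator does **not** emulate: copy-number segment structure and
correlation along the genome, probe-level methylation and probe↔gene
ambiguity, count-level sequencing noise (expression is Gaussian around
the linear predictor on the log scale), batch effects, and subtype-level
expression programs beyond the planted regulators. Passing tests
therefore demonstrate correctness of the procedures and their error
control under the stated generative model, not performance on real
cohorts.

## Problem sizes used in the checks

The automated checks run at the default study condition (100 tumors, 300
genes, 50 regulators, 200 permutation draws): regulator recovery averages
5 generator seeds, the type-I (no planted effect) check averages 20
seeds, model-subset ordering uses 40 tumors, the log-rank test is
validated against a 10,000-label-permutation null at n = 40, the Cox
estimator against a simulated hazard ratio of 2 at n = 2000, and the
YMR-linked survival power check uses 40 replicates of 200 patients with a
unit log-hazard per score SD (hazard ratio e ≈ 2.7 per SD, a strong
planted prognostic effect). Pipeline determinism is asserted byte-for-byte
across repeated runs and worker counts.

## Known limitations

* The Welch-based differential test is anti-conservative relative to a
  moderated test below ~5 samples per group; the generator never produces
  such cohorts, but real data users should mind it.
* Empirical p-values are bounded below by 1/(n_perm+1); with few draws and
  many regulators, BH cannot reach low FDR values regardless of signal.
* The leave-regulator-out score is a training-loss quantity; it measures
  the regulator's contribution to the fitted models, not held-out
  predictive value.
* The xtile-style cutoff uses a plain empirical quantile; the original
  outcome-driven cutpoint-search heuristic it stands in for optimizes the
  split against survival and is intentionally not reproduced.
* `intersect_common` sorts ids, so its output is independent of input
  ordering but not of id naming.
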