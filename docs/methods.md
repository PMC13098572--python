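# Methods

`metaboatlas` re-implements, at desk scale, the analysis pattern of a
large case-control NMR-metabolomics atlas: disease-wise metabolic profiles,
a composite inter-disease similarity map with hierarchical clustering,
cross-validated discrimination models with attribution-based consensus
feature selection, and medication-robustness checks. Everything runs on
synthetic cohorts generated by the package itself, so every stage is testable
without restricted data.

## The model of the data

A cohort is a participants × features table: `n_metabolites` (default 325)
NMR-style metabolite measures, `n_clinical` (default 66) clinical covariates,
a set of phenotype codes from a two-level class/subclass hierarchy (empty set
= control), a region label (one discovery region and two geographic
hold-outs, weighted 0.90/0.06/0.04 by default, one large discovery nation
and two smaller hold-out nations), a statin-use flag, and a generic
exclusion flag.

Metabolites are generated as `exp(MVN)`: log-scale means ~N(1, 0.4²),
log-scale SDs σⱼ ~ U(0.3, 0.7), and a block-diagonal correlation structure
(9 blocks by default, constant within-block correlation 0.4) standing in for
the strongly collinear lipoprotein panels of real NMR data; the first 5
blocks are designated "lipid" features. Disease effects are additive on the
log scale and expressed in units of σⱼ, so a planted shift of `s` yields a
log-scale control-standardized mean difference of exactly `s` — the closed
form the generator-recovery tests exploit.

Disease classes fall into three groups:

* **lipid group** — cases receive `shared_shift` (default 1.0 σ) on a shared
  signature of 20 lipid features, spread across the lipid blocks the way real
  cross-disease panels span several biomarker groups;
* **gradient group** — cases receive a per-class graded multiple (0.6–1.4×)
  of the shift on a second, disjoint signature of 15 non-lipid features,
  emulating a hypertensive-renal-style severity arm;
* **null group** — no planted shifts.

Every non-null subclass additionally gets `specific_shift` (default 0.8 σ,
alternating sign) on 4 private features. Statin-flagged participants receive
`statin_effect` additively on the log scale of **all** lipid features
(−1.0 ≈ a 63% reduction; strong therapy). Missingness is
completely-at-random (MCAR) only; informative missingness, batch effects and
longitudinal drift are out of scope. What passing tests show is therefore
that the *machinery* behaves correctly under the distributional shape it
assumes — not that real cohorts satisfy those assumptions.

## Pipeline stages and their parameters

**Assembly.** Exclusions run in study order (all-metabolites-missing first,
then the exclusion flag) into an arithmetic-checked flow ledger. Phenotype
contrasts are built at both hierarchy levels; a class's cases are the union
of its subclass cases plus directly-coded cases; controls are the globally
phenotype-free pool, shared across contrasts. Phenotypes with fewer than
`min_cases` (default 100) cases are dropped — strictly fewer, so exactly 100
is retained.

**Preprocessing.** Features with more than 20% missing values are excluded
(strict >; computed once on the analysis cohort). Median imputation and
z-scoring statistics are fitted on training rows only and applied unchanged
to validation and hold-out rows; constant or all-missing training features
are dropped with a warning. Fold plans are stratified 5×5 nested CV over the
discovery region, with participant ids sorted before the seeded shuffle so
plans are platform-independent.

**Profiling.** For each contrast, meanZ is the mean over cases of
`(x − control mean) / control SD` per metabolite, computed on globally
median-imputed measurement-scale values (a complete-case toggle exists). The
altered set is `|meanZ| > τ` with τ = 0.5, strict inequality. Group
comparisons use the two-sided Mann-Whitney U (tie-corrected normal
approximation, no continuity correction, so identical samples give p = 1
exactly) with Benjamini-Hochberg adjustment over all cells of the requested
table in a single family; the family scope is recorded in the output
metadata.

**Similarity atlas.** S = ωJ + (1−ω)R′ with ω = 0.5: J is the Jaccard
overlap of altered sets (both-empty pairs count as identical, flagged), and
R′ = (ρ+1)/2 is the affinely rescaled Spearman correlation of meanZ profiles
(zero-variance profiles get the uninformative midpoint 0.5, flagged).
Clustering uses complete linkage on D = 1 − S — the minimal monotone
similarity-to-distance conversion, keeping heights in [0, 1] — with a fully
deterministic tie-break (lexicographically smallest pair of cluster-leading
labels) and leaf ordering by smaller-label-subtree-first traversal, so the
dendrogram (exported as Newick with branch lengths = height differences) is
reproducible bit-for-bit. Partition cuts remove the k−1 highest merges; ties
at the cut height are resolved by merge order and flagged. The Adjusted Rand
Index is computed from the contingency-table formula
(Index − Expected)/(Max − Expected); two trivial partitions (where
Max = Expected) compare as 1 when identical and 0 otherwise.

**Discrimination.** Three algorithms (L2 logistic regression, random forest,
gradient-boosted trees) × three feature sets (metabolites only, clinical
only, combined). Class imbalance is handled by inverse-prevalence class
weights (deterministic, unlike resampling). Default grids are small and
config-exposed: C ∈ {0.01, 0.1, 1, 10}; forest depth ∈ {None, 8} at 300
trees; boosted depth ∈ {3, 6} × learning rate ∈ {0.05, 0.1} at 200 trees.
Inner folds select the grid point with the best mean inner AUC (first grid
point wins ties; a singleton grid short-circuits the inner loop); outer folds
are scored by refits on the outer-training set; the headline estimate is the
pooled AUC over concatenated outer-fold scores (per-fold AUCs are also
reported). The final pipeline refits on the full discovery set with the most
frequently selected hyperparameters and is evaluated unchanged on the
geographic hold-out. CIs are percentile bootstrap over 1,000
class-stratified participant resamples. Results carry EPV = cases/features
and an "unstable" flag when EPV < 5 (config-exposed).

**Attributions and consensus.** Attributions are Shapley values against a
background sample, explained on the log-odds margin for linear and boosted
models and on the positive-class probability otherwise. Four routes:
closed-form for linear models (exact); the boosting library's native tree
contributions (exact up to float32); full coalition enumeration for ≤ 16
features (exact); and a permutation-sampling estimator otherwise (flagged
approximate — per-feature values are Monte-Carlo estimates, but the local
accuracy identity `baseline + Σ attributions = output` holds to float64
precision because each permutation's marginal contributions telescope).
Feature direction is the sign of the Pearson correlation between feature
values and per-sample attributions. Consensus selection counts top-k
(k = 30) membership across phenotype models — combined-feature models, best
algorithm per phenotype by mean fold AUC — and selects features recurring in
at least `n_min` (default 10) phenotypes with direction consistency ≥ 0.8.
The consensus panel size is an outcome, never a parameter. Sankey edge
tables use combined-model attributions only, with unrenormalized weights.

**Statin robustness.** Each metabolite is residualized on the statin
indicator by OLS (covariates optional; indicator-only residuals are exactly
mean-balanced across flag groups), residuals standardized, profiles and the
atlas recomputed, and partition cuts compared by ARI over k = 2…10.

## Reference validation studies (`metaboatlas.validation`)

Problem sizes were chosen to exercise every stage in minutes on one CPU:

* **Atlas recovery** — 6 classes × 2 subclasses (2 lipid / 2 gradient / 2
  null), 300 cases per subclass phenotype, 8,000 participants, 325 features.
  The k = 3 cut of the subclass atlas is compared with the planted grouping.
* **Consensus recovery** — the same design at 6,000 participants and 150
  cases per subclass, plus 3 clinical covariates carrying an independent
  0.5-SD case signal; combined logistic models for all 18 contrasts, exact
  linear attributions, `n_min` = the 6 lipid-group contrasts. Reported:
  recall of the 20 planted shared-signature features.
* **Null sanity** — one balanced phenotype, 2,000 participants, all shifts
  zero; pooled nested-CV AUC for all three algorithms must sit near 0.5
  (a leakage detector).
* **Statin null arm** — zero statin effect and a flag *independent of case
  status* (equal 30% prevalence). Independence matters: the null hypothesis
  of the invariance claim is "the flag carries no information", and a flag
  correlated with case status lets the finite-sample residualization
  coefficient remove a case-aligned noise component, legitimately perturbing
  noise-level merge orders even when the true effect is zero. Under the
  independent-flag null the adjusted and unadjusted partitions are identical
  at every k.
* **Statin confounded arm** — statin effect −1.0 on all lipid features with
  prescription tracking the diagnosis (60% of lipid- and null-group cases,
  5% elsewhere). A uniform exposure merely compresses contrasts without
  reordering groups; differential exposure is what biases the clustering —
  here it smears a spurious lipid signature over the heavily-medicated
  phenotypes, and residualization restores the planted grouping.
* **Bootstrap coverage** — two-Gaussian scores with unit separation (true
  AUC = Φ(1/√2) ≈ 0.760) at n = 2,000, 100 replicates, B = 1,000.

## Numerical and degenerate-input conventions

Strict inequalities at both published thresholds (>20% missingness excludes;
|meanZ| > 0.5 alters). Both-empty Jaccard = 1 (flagged); zero-variance
Spearman = 0.5 (flagged); all-tied Mann-Whitney p = 1 (warned). All
randomness flows from explicit seeds through `numpy.random.default_rng`; no
global RNG state. Ledger arithmetic is checked on every run. The
orchestration layer caches each stage's outputs keyed by a configuration
hash, so the expensive discrimination stage is skippable while iterating on
the atlas.

## Known limitations

The generator's planted-shift model is deliberately simple: shifts are
additive on the log scale and independent of the correlation structure, case
phenotypes are mutually exclusive (no comorbidity), and missingness is MCAR.
Consensus recall depends on the planted signature being spread across
correlated blocks; a signature concentrated in one block dilutes per-feature
ridge weights and lowers recall. The permutation attribution estimator's
per-feature values have Monte-Carlo error (only their sum is exact); the
boosting library's native contributions are float32. Real-data phenomena a
biobank-scale analysis must confront — assay drift, informative missingness,
comorbidity, survivor bias, non-statin medications — are explicitly not
modelled, so green tests here validate the machinery, not any biological
claim.
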