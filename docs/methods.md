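# Methods

This note documents the models, parameter choices and numerical conventions
behind `exemplarscore`, and what the synthetic studies can and cannot show.

## 1. The clinical exemplar score

### PESO protocol

For each site *s* with at least two subjects per response class:

* **Own site.** Leave-one-out cross-validation: for each held-out subject,
  the remaining site subjects are completed by marginalization, rebalanced
  with SMOTE–Tomek, and used to fit a random forest (100 trees,
  scikit-learn defaults otherwise, no hyperparameter search). The held-out
  subject's features are completed using the *training* partition's observed
  ranges and the predicted responder probability is averaged over M
  marginalization draws.
* **Other sites.** One model per draw is fitted on the full site and applied
  to all other sites' subjects, completed against the source site's ranges.

Sites with a singleton minority class contribute no model but their subjects
are still predicted by the other sites. Every fit asserts that no target
subject's record is present in its training partition; the violation counter
is part of the returned audit object.

### Score definition

With per-site probabilities `p_is` and label `y_i`:
`a_is = 1 − |y_i − p_is|`, `A_i = mean_s a_is`,
`G_i = 1 − 2 · mean_s |p_is − p̄_i|`, `E_i = (A_i + G_i)/2`.

Design rationale:

* The per-site accuracy is a *bounded* monotone transform of the absolute
  error (an unbounded reciprocal cannot be normalized to [0, 1]); it
  preserves the ordering of subjects.
* `G` rescales the mean absolute deviation of the site probabilities
  (maximum ½ for probabilities) so unanimity gives 1 and a maximal split 0.
* The additive combination makes a unanimously *wrong* subject score 0.5 and
  an accurately-but-discordantly predicted one 0.25 — both intermediate, as
  the score's interpretation requires. A multiplicative combination would
  send wrong-but-unanimous subjects to 0, conflating them with subjects whose
  phenotype carries no consistent signal at all. The score function is a
  pluggable argument of `exemplar_score` for sensitivity analyses.

### Stratification

Within each response class of size `n`, the stratum size is
`k = round_half_up(0.25 · n)` (110 for a class of 439; 207 for 827). The `k`
highest-scoring subjects form the Best stratum; the Poor stratum is drawn
from the complement so heavy ties can never overlap; residual ties are broken
by ascending subject id, making the assignment deterministic. For the
genotyped subsample, strata are re-computed within the subsample by default
(`stratum_scope="within_subsample"`); `"inherited"` reuses full-cohort
labels instead.

## 2. Preprocessing

* **Marginalization, not imputation.** Each missing categorical cell is a
  uniform draw over the dictionary's category list; each missing
  continuous/ordinal cell a uniform draw over the observed training range
  (dictionary bounds as fallback; ordinal draws are integers). M = 10 draws
  by default, averaged at prediction time; M is configurable and replicate
  studies use M = 1 (at the default 5% missingness the between-draw variance
  of an averaged forest probability is far below the fold-level noise).
* **SMOTE–Tomek.** SMOTE interpolates synthetic minority points between
  k = 5 nearest minority neighbours (λ ~ U(0,1)); Tomek links (opposite-class
  mutual nearest neighbours) then drop the member belonging to the
  pre-resampling majority class. Categorical features are one-hot encoded
  before the Euclidean neighbour search and synthetic rows are snapped back
  to valid indicators by block-wise arg-max. Rebalancing only ever sees
  training partitions. When a leave-one-out training partition has a
  singleton minority (a 2-per-class site), rebalancing is skipped rather
  than failing the fold.

## 3. Strata characterization

Continuous/ordinal variables: two-sample permutation test on the absolute
difference of group means; exhaustive enumeration for ≤ 10 observations,
otherwise B = 10,000 Monte-Carlo permutations with the bias-protected
estimator p = (b+1)/(B+1). Categorical/binary: Pearson chi-square with the
null distribution generated by permuting group labels against categories
(fixed margins), same estimator. Tests are two-sided by construction of the
statistics. Missing values are dropped per variable (complete-case, groups
not rebalanced). The Bonferroni threshold divides α = 0.05 by the number of
*testable* variables; variables untestable in a stratum (all missing, or a
degenerate table) are reported as such.

## 4. Genomic classification

Per fold of a class-stratified 10-fold split (or stratified shuffle-splits
for the test-size sensitivity protocol): variant missingness is mean-imputed
and variants standardized with training-fold statistics only, then an
L2-penalized logistic regression (C = 1 fixed a priori — a common prior
scale makes coefficients comparable across conditions and folds; lbfgs,
tol 1e-6, convergence enforced) is fitted and evaluated on the held-out
fold. The decision threshold is 0.5 (the genotyped subsample is near
balanced by design). Metric conventions: MCC = 0 when a marginal factor
vanishes; PPV/NPV are NaN when undefined; AUC is the tie-corrected rank
probability and NaN for single-class folds; Cohen's kappa is 0 when expected
agreement is 1. Conditions (ALL / POOR / BEST) are compared on fold-wise MCC
— the primary metric — with Kruskal–Wallis at α = 0.05, then pairwise
two-sided Mann–Whitney tests at 0.05/3; other metrics are reported
descriptively as median (IQR). When every fold metric is identical (a
saturated simulation), the omnibus is reported as H = 0, p = 1.

## 5. Enrichment

Variants are selected when their coefficient keeps one strict sign in every
fold; an exact zero breaks consistency (it carries no sign). Selected
variants map to the gene whose BED interval contains them, else the gene at
minimal distance `max(0, start − pos, pos − end)` (1-based variant position
against 0-based half-open intervals; ties broken by smaller gene start, then
lexicographic id). A gene's score is the largest |mean fold coefficient|
among its selected variants (`mean` available as an option). Each gene set
with at least one scored member and one scored non-member is tested with a
one-sided Mann–Whitney U (members rank higher); the p-value is exact when
the member × non-member product is ≤ 400 and the scores are tie-free,
otherwise the tie-corrected normal approximation. Benjamini–Hochberg FDR is
applied across the tested sets at q < 0.05. The enrichment engine is
generic — gene sets are user-supplied GMT input, not part of the package.

## 6. Synthetic data generator

The generator emulates the assumed study structure, not any real cohort:

| parameter | default | meaning |
|---|---|---|
| n_sites × site size | 6 × 200 | multi-centre cohort, n = 1200 |
| responder_prevalence | 0.347 | per-site Bernoulli responder rate |
| n_clinical_features | 20 | 50% continuous, rest binary/3-level/ordinal |
| core_fraction | 0.35 | latent "classical phenotype" probability |
| core_alignment | 3.0 | class shift of core subjects along the shared direction |
| site_effect_sd | 3.0 | magnitude of each site's sparse idiosyncratic effect |
| missing_rate | 0.05 | MCAR missingness per feature cell |
| genotyped_fraction | 0.3 | subsample with SNP data (n = 360) |
| n_snps / n_causal | 500 / 40 | independent biallelic SNPs, MAF ~ U(0.1, 0.5) |
| causal_effect | 2.0 | per-allele log-odds tilt in core subjects |
| causal_effect_noncore | 0.0 | tilt in non-core subjects (uniform null: = causal_effect) |

Labels are drawn first (so per-site prevalence is exact in expectation);
features are standard normal with a sparse class shift — along one shared
direction for core subjects, along the site's own direction (shared +
sparse perturbation) otherwise. Sparsity (~d/4 informative features with
unit weights) reflects that clinical prediction is carried by a handful of
variables and is what axis-aligned forests can recover; by the Gaussian
class-conditional construction each site's response is logistic in its own
weight vector. Genotypes are Binomial(2, MAF) with causal dosages redrawn
from logit-tilted frequencies (±β/2 by class), β depending on core status.

Alignment, heterogeneity and effect-size defaults were fixed by design-phase
power analysis: at ~90 subjects per stratum under 10-fold CV, the
dataset-level median fold AUC has intrinsic standard deviation ≈ 0.1–0.15
even under a true null, so the planted contrasts must be large for the
ordering BEST > ALL > POOR to be decidable; the chosen defaults put the
best-exemplar AUC near 0.9 and the all-subjects AUC near 0.7, matching the
magnitudes reported for real cohorts of this size. Under the uniform null
every condition saturates (AUC ≈ 1), so the BEST − POOR null difference is
essentially exactly zero — a degenerate but valid null.

What the generator does **not** emulate: linkage disequilibrium and
population structure (SNPs are independent), chip ascertainment, informative
missingness, graded exemplarity (core status is binary), site-level
differences in variable coverage, and measurement error in the response
scale. Passing tests therefore demonstrate that the pipeline recovers the
*assumed* latent structure, not that real cohorts possess it.

## 7. Problem sizes and runtime

Replicate studies (acceptance checks, `scripts/acceptance.py`) run the full
default-size study per replicate — PESO scores the genotyped subsample (the
only subjects whose strata Step 2 consumes under the default scope) with
M = 1, ~370 forest fits per replicate. The acceptance suite uses 8
concentrated and 5 uniform-null replicates; the acceptance script 3 and 2,
plus a 5-permutation label-shuffle null. Monte-Carlo validity checks use
B = 199 replications over 500 null simulations. These counts are the
package's replicate-study sizes; single replicates at larger M scale
linearly.

## 8. Known limitations

* The exemplar score is one bounded instantiation of "accuracy plus
  agreement"; alternative normalizations (e.g. reciprocal-error based) are
  order-similar but not numerically identical, which is why the score
  function is pluggable.
* Fold-level metrics in ~90-subject strata are intrinsically noisy (test
  folds of ~9); single-replicate condition comparisons should be read with
  the Kruskal–Wallis gate, not fold medians alone.
* Sign-consistency across folds is a stability filter, not an error-rate
  control; with 80–90% fold overlap many correlated coefficients pass it.
  The FDR control applies to the gene-set stage only.
* The randomization chi-square and permutation tests assume exchangeability
  under the null within the compared strata; stratum selection itself is
  conditioned on the clinical features being tested, so the univariate
  comparisons are descriptive of the strata, not causal statements.
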