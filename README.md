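# exemplarscore

Clinical exemplar scoring of lithium response in bipolar disorder, and
exemplar-stratified genomic classification.

## The problem

Long-term lithium response in bipolar disorder is predicted better by a
detailed clinical phenotype than by genotype, but the clinical predictors
differ between sites in multi-centre studies. Some patients, however, carry
a phenotype that *every* site's classifier recognises the same way — the
"classical", episodic, late-onset lithium responder and its non-responding
counterpart. If the classical phenotype is biologically grounded, then
responders and non-responders with such *exemplary* phenotypes should be
easier to separate genetically than patients whose phenotype predicts their
response unreliably.

This package implements that two-step analysis for researchers working with
multi-site clinical cohorts plus a genotyped subsample:

1. **Clinical exemplar scoring.** A *predict-every-subject-out* (PESO)
   protocol trains one random-forest classifier per site (100 trees, no
   hyperparameter search; missing values marginalized by sampling from
   uninformative priors on each variable's domain; class imbalance handled by
   SMOTE with Tomek-link cleaning, training partitions only). Every subject
   receives one out-of-sample predicted probability of response from each
   site's model — own-site predictions via leave-one-out. With per-site
   probabilities `p_is` and true label `y_i`, the exemplar score is

       a_is = 1 − |y_i − p_is|          per-site accuracy
       A_i  = mean_s a_is               accuracy component
       G_i  = 1 − 2·mean_s |p_is − p̄_i| between-site agreement
       E_i  = (A_i + G_i) / 2           clinical exemplar score ∈ [0, 1]

   Within each response class the top quartile of `E` are the **best**
   exemplars (LRBest / NRBest) and the bottom quartile the **poor** exemplars
   (LRPoor / NRPoor). Strata are characterized variable-by-variable with
   two-sample permutation tests (continuous) and randomization chi-square
   tests (categorical), Bonferroni-corrected.

2. **Genomic validation.** Within the genotyped subsample, L2-penalized
   logistic regression (C = 1, fixed a priori) classifies responders from
   additively coded SNP dosages under stratified 10-fold cross-validation in
   three conditions — ALL subjects, POOR exemplars, BEST exemplars — scored
   primarily by Matthews correlation coefficient and compared with
   Kruskal–Wallis and Mann–Whitney tests. Variants whose coefficients keep
   one strict sign across all folds are mapped to nearest genes and tested
   for gene-set enrichment (one-sided Mann–Whitney on gene scores,
   Benjamini–Hochberg FDR).

Because the motivating study's clinical and genomic data are private, the
package ships a synthetic-data module that generates multi-site cohorts with
the latent structure the analysis assumes: a "core" subgroup whose features
align with a shared effect across sites (everyone else couples to
site-specific effects), and SNP effects concentrated in that core subgroup.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic data
(outputs under `results/`):

```bash
python analysis/01_simulate_cohort.py --seed 1
python analysis/02_score_exemplars.py --seed 2
python analysis/03_compare_clinical.py
python analysis/04_classify_genomic.py --seed 4
python analysis/05_gene_enrichment.py --seed 5
```

With seed 1 the simulated cohort has 1200 subjects across 6 sites (33.8%
responders; 33.9% latent core). Scoring prints

```
scored 1200 subjects with 6 site models (1206 forest fits, 0 leakage violations)
core fraction: best exemplars 0.72 vs cohort 0.34 (enrichment ratio 2.12)
```

— the best-exemplar strata are heavily enriched for the latent core subgroup
the score is supposed to find. Genomic classification then prints

```
median MCC (IQR): ALL 0.38 [0.32, 0.47], POOR 0.00 [-0.25, 0.00], BEST 0.76 [0.76, 1.00]
median AUC (IQR): ALL 0.74 [0.72, 0.78], POOR 0.53 [0.43, 0.71], BEST 0.97 [0.94, 1.00]
Kruskal-Wallis on fold MCC: H = 23.39, p = 0.0000
  POOR vs BEST: U = 0, p = 0.0002*
```

— genotype separates response among the best clinical exemplars (AUC 0.97)
but not among the poor ones (0.53), exactly the concentration the generator
planted. The enrichment stage recovers the planted pathway only from the
best-exemplar coefficients:

```
best: 311 sign-consistent variants -> 311 scored genes; significant sets (q<0.05): SET_TARGET
poor: 288 sign-consistent variants -> 288 scored genes; significant sets (q<0.05): none
```

A `exemplarscore` CLI exposes the same stages for external data
(`simulate`, `peso`, `score`, `stratify`, `compare-clinical`,
`classify-genomic`, `enrich`, `run-all`); inputs are TSV + JSON dictionary
for clinical data, VCF or dosage TSV for genotypes, BED6 for gene annotation
and GMT for gene sets.

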