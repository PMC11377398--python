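# genesieve

Detecting and removing mislabeled samples from case-control sequencing
cohorts with an annotation-guided sparse neural network.

## The problem

Case-control cohorts for psychiatric disorders carry a non-negligible rate
of diagnostic error: registry-defined schizophrenia diagnoses hold up under
re-evaluation only ~75–94 % of the time depending on how broadly the
disorder is defined, and population controls include undiagnosed cases at
roughly the disorder's prevalence. A classifier trained on such a cohort
learns a genetic signature polluted by samples whose genotype contradicts
their label. `genesieve` implements a two-stage procedure for flagging and
removing those samples:

1. **Stage 1 — score on the training data.** A sparse network is trained on
   the *entire* cohort, then scored on the same samples (test-on-train, by
   design). The model, forced to separate the observed classes, leaves
   samples whose genetics match the *other* class with contradictory
   scores. An ensemble of independently seeded runs yields a mean score
   s̄ᵢ ∈ [0, 1] per sample and a count of runs in which the sample fell on
   the wrong side of 0.5.
2. **Exclusion by epidemiology.** The ⌊ρ·n_controls⌋ labeled controls with
   the highest scores are removed (ρ = prevalence, expected undiagnosed
   cases), and the ⌊m·n_cases⌋ labeled cases with the lowest scores
   (m = misdiagnosis rate; under the *narrow* definition a case must also
   be misclassified in at least half the runs to be eligible).
3. **Stage 2 — retrain and evaluate.** Models are retrained on the filtered
   cohort over repeated stratified 60/20/20 splits with early stopping, and
   the test-AUC distribution is compared against the unfiltered baseline
   with an unpaired two-tailed t-test.

## The model

With a topology table assigning each variant *v* (additively encoded
genotype x_v ∈ {0, 1, 2}) to exactly one gene *g*:

    gene value:  z_g = Σ_{v ∈ g} w_v x_v + b_g          (parallel regression per gene)
    prediction:  ŷ  = σ( Σ_g u_g z_g + c )              (logistic output)

Trainable scalars: n_variants + 2·n_genes + 1. Training is mini-batch Adam
(batch 64, lr 10⁻³) on binary cross-entropy, fully deterministic per seed.
Gene importance is the ensemble mean of |u_g| (or signed u_g), feeding a
hypergeometric over-representation analysis of the top-ranked genes.

Because the real cohorts this procedure targets are controlled-access, the
package ships a synthetic-cohort generator: Hardy–Weinberg genotypes over a
log-uniform allele-frequency spectrum, gene-level causal effects on a
liability-threshold phenotype, and observed case/control pools in which a
configurable fraction of each pool carries the wrong label.

## Worked example

The numbered scripts under `analysis/` run the whole study on a simulated
cohort (2,400 samples, 400 SNPs on 120 genes, 30 causal, 10 % of the case
pool mislabeled):

```
$ python analysis/01_simulate_cohort.py --seed 1
cohort: 2400 samples x 400 variants
observed cases 1200, controls 1200, mislabeled 120 (all in the case pool)
genetic-liability oracle AUC vs true labels: 0.991

$ python analysis/02_quality_control.py
sites in: 400; kept: 400; dropped: 0

$ python analysis/03_association_screen.py
variants tested: 400 of 400; selected at p < 0.05: 69

$ python analysis/04_outlier_detection.py --seed 1
stage-1 test-on-train AUC: 0.9528
excluded 4 controls and 120 cases (broad mode)
mislabeled cases score below genuine cases: rank-sum p = 7.56e-64
mislabeled fraction of excluded cases: 0.775 (base rate 0.100)

$ python analysis/05_retrain_evaluate.py --seed 1
unfiltered mean test AUC: 0.8982 (max 0.9043)
filtered   mean test AUC: 0.9613 (max 0.9662)
two-sample t-test: t(8) = 14.29, p = 5.6e-07

$ python analysis/06_enrichment.py --seed 1
top 20 genes contain 19 of 30 causal genes
         set  k  n  K   N enrichment_ratio  p_value      fdr
causal_genes 19 20 30 120             3.80 1.68e-13 8.39e-13
```

Reading: the ensemble pushes the 120 truly mislabeled cases toward
control-like scores (rank-sum p ≈ 10⁻⁶⁴); the quota-driven exclusion
recovers them at 7.8× the base rate; retraining on the cleaned cohort
lifts mean test AUC from 0.898 to 0.961; and the network's top-weighted
genes are overwhelmingly the causal ones (enrichment ratio 3.8 against a
120-gene reference).

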