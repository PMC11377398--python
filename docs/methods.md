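# Methods

## Model

The classifier is a three-layer sparse network whose connectivity is fixed
by a variant-to-gene annotation ("topology") table: input node *v* carries
the additive genotype code x_v ∈ {0, 1, 2} and connects to exactly one gene
node; gene node *g* computes z_g = act(Σ_{v∈g} w_v x_v + b_g); the gene
layer is fully connected to one logistic output,
ŷ = σ(Σ_g u_g z_g + c). Each gene node is therefore a small regression
over its own variants, and the output is a logistic regression over gene
values — the trainable scalars number n_variants + 2·n_genes + 1, several
orders of magnitude fewer than a dense layer, and each weight is
attributable to a named variant or gene.

The gene activation defaults to linear, which matches the
parallel-regressions-into-logistic-regression reading of the architecture
and makes gene values interpretable on the liability scale; `tanh` is
available as a configuration for the saturating variant. No regularization
is applied by default (optional L1 on the variant weights exists as
config).

**Training.** Mini-batch Adam (β₁ = 0.9, β₂ = 0.999, ε = 10⁻⁸), batch size
64, learning rate 10⁻³, binary cross-entropy loss. Batch order is
reshuffled every epoch from a single run seed, and initialization is
N(0, 0.05²) on weights with zero biases, so a run is bit-reproducible.
Stage-1 (full-data) training uses a hard epoch cap with no validation
split; stage-2 training early-stops on validation loss (patience 20 by
default, 10 in the scaled experiments) under the same cap, restoring the
best-epoch parameters. Missing genotypes are filled with 0 (homozygous
reference) at the model input; the ≥ 90 % call-rate floor enforced by QC
bounds the distortion, and per-variant mean imputation is available.

## Two-stage outlier procedure

Stage 1 trains an ensemble (default 10 models; 5 in the scaled runs) of
independently seeded networks on the entire cohort and predicts on the same
samples. Testing on the training data is deliberate: the interest is not
generalization but which samples the model *cannot* pull to their observed
class. Per sample we record the mean score and the number of runs scoring
it on the wrong side of 0.5 (a score of exactly 0.5 reads as *case*).

Exclusion quotas are external epidemiology, not data-driven thresholds:
⌊rate × pool⌋ with the control rate set to the population prevalence
(0.34 % in the motivating Swedish setting: ⌊0.0034 × 6245⌋ = 21) and the
case rate to a literature misdiagnosis estimate — 6 % under a broad
disorder definition, 19 % under the narrow one (⌊0.19 × 4969⌋ = 944).
Floor rounding reproduces both of those counts; the reported broad-mode
exclusion of 300 cases exceeds ⌊0.06 × 4969⌋ = 298, so an explicit
count-override parameter exists and the discrepancy is surfaced rather
than absorbed into a different rounding rule. In narrow mode a case must
additionally have been misclassified in at least ⌈n_runs/2⌉ runs to be
eligible; if fewer cases are eligible than the quota, all eligible cases
are excluded with a warning. All orderings tie-break on sample id.

Stage 2 evaluates unfiltered and filtered cohorts identically: repeated
(default 30; 5 in the scaled runs) fully randomized class-stratified
60/20/20 splits with largest-remainder per-class allocation, training with
validation early stopping, and rank-based (Mann–Whitney, ties = ½) test
AUC. AUC lists are compared with a two-tailed unpaired pooled-variance
t-test; zero pooled variance with equal means returns (t = 0, p = 1) and
with unequal means is an error rather than a silent infinity.

Master-seed handling: every consumer of randomness (ensemble runs, split
draws, training runs) derives its seeds from the master seed through a
seed-sequence stream with a distinct stream index, so each stage is
individually reproducible and the whole pipeline is byte-identical across
runs with the same master seed.

## Preprocessing

**QC.** Site metrics (mean depth over non-missing DP values, call rate over
fully called genotypes, ALT frequency over called alleles) are recomputed
from the genotype columns rather than trusted from INFO tags.
Multi-allelic records are split into one biallelic child per ALT; any
genotype carrying an allele foreign to a child is set missing there, and
children are filtered on their own recomputed metrics. Thresholds follow
exclusion wording: drop when mean DP < 8 or call rate < 0.90; retain only
QUAL > 30 — so mean DP = 8 and call rate = 0.90 survive and QUAL = 30 does
not. Half-called genotypes count as missing; a called genotype with
missing DP still counts as called (depth and genotype are independent
tags). Samples with an out-of-scope phenotype label (e.g. a bipolar
diagnosis class) are dropped before any metric is computed, and external
recalibration is accommodated by a site-whitelist pass-through rather than
re-implemented. The whole-cohort variant recalibration (VQSR) step that
full-scale workflows apply is out of scope here.

**Association screen.** Variants are restricted to biallelic autosomal
SNPs, then tested with a Pearson chi-squared test on a phenotype-class ×
genotype table. Only two phenotype classes exist, so the table is 2 × 3
(a 2 × 4 variant with a missing-genotype column is available by config);
zero-total genotype columns are dropped with df reduced accordingly, and
sites with fewer than two informative columns are flagged untestable and
excluded from selection. Selection keeps p < α (strict; α = 0.05) with
**no multiple-testing correction** — the screen is dimensionality
reduction, and its representativeness is checked downstream by
over-representation analysis, not by genome-wide significance.
Multi-gene annotations resolve to the alphabetically first symbol (a
priority list can override), because the topology format requires exactly
one gene per variant.

## Enrichment

Over-representation of a prioritized gene list (ensemble-mean gene weights,
top k = 150 at full scale, top 20 at the scaled gene count; magnitude
averaging guards against sign non-identifiability across runs) is scored
per gene set by the upper-tail hypergeometric probability of the observed
overlap and the enrichment ratio (k/n)/(K/N), with Benjamini–Hochberg FDR
within each collection (different databases are separate testing
families). The reference universe size N is a required input — "the whole
genome" is not a number, and N moves every p-value. Query genes absent
from the collection's universe are kept in the draw by default (the
conservative choice when a collection covers only part of the genome);
an option drops them and shrinks n.

## Synthetic cohorts

The generator stands in for a controlled-access exome cohort; no public
generative model exists for it, so all simulation choices are explicit
stand-ins:

- **Genotypes.** Biallelic autosomal SNPs in Hardy–Weinberg proportions,
  i.i.d. across samples; allele frequencies log-uniform on
  [0.005, 0.5], giving the rare-heavy spectrum typical of exome data. No
  linkage disequilibrium, population structure or relatedness — tests that
  pass here say nothing about confounding from those features.
- **Phenotype.** Liability ℓᵢ = Σ_g β_g s_ig + εᵢ with s_ig the z-scored
  per-gene burden of additive codes, β_g ~ N(0, effect_sd²) on
  `n_causal_genes` genes and ε standard normal. True cases are samples
  above the empirical upper-`prevalence` quantile. Gene-level (not
  variant-level) effects match what the network aggregates, making
  gene-recovery assertable. Defaults: 30 causal of 120 genes,
  effect_sd = 1.0 — genetic heritability of liability ≈ 0.97, so the
  genotype-only oracle (the genetic liability itself) separates true
  classes with AUC > 0.9, the regime the exclusion mechanism presumes.
- **Prevalence 0.30.** The threshold calibration only needs an upper-tail
  cut; a realistic 0.34 % prevalence would require simulating ~350× more
  samples than the case pool to fill it. 0.30 keeps the reserve pool small
  while preserving the asymmetric-threshold structure. The *exclusion*
  quotas, where prevalence actually matters to the method, use the real
  0.34 % figure.
- **Label noise.** Mislabeling rates are properties of the *observed*
  pools: the case pool of size n contains exactly round(rate × n) true
  controls (misdiagnosed cases), and symmetrically for controls, drawn
  uniformly from a simulated reserve. Defaults: 10 % of cases, 0 % of
  controls. Counts use round-half-even; the flipped mask is exactly the
  XOR of true and observed labels.
- **Output.** VCF v4.2 with GT and DP (Poisson depths clipped ≥ 8 so QC is
  not tripped by default; a `low_dp_fraction` option degrades a known site
  subset to exercise the depth filter), phenotype and truth TSVs, topology
  CSV (header `variant_node,variant,gene_node,gene`).

## Scaled study conditions

Full-scale runs (≈ 11,000 samples × 19,000 variants × 10-model ensembles ×
30 repeats) are not meaningful on synthetic data and not necessary to test
the mechanism. The package's standard experiment uses 1,200 cases + 1,200
controls, 400 variants on 120 genes, a 5-model stage-1 ensemble capped at
50 epochs, and 5 stage-2 repeats; a full recovery experiment completes in
well under a minute. At these conditions (medians over 5 master seeds):
mislabeled cases score below genuine cases (rank-sum p ≪ 0.01), the
excluded-case set is ≥ 3× enriched for mislabeled samples, and filtering
raises mean test AUC. The null configuration (effect_sd = 0, no flips,
1,000 variants) checks calibration: chance-level test AUC and ≈ 5 % screen
retention.

## Known limitations

- The gene-importance ranking inherits the sign/scale non-identifiability
  of the hidden layer; magnitude averaging mitigates but does not remove it
  (a gene can matter through its bias without a large output weight).
- Test-on-train scoring conflates genuine mislabeling with any other source
  of atypicality (ancestry, batch); the synthetic cohorts contain neither,
  so recovery results are an upper bound on real-data behavior.
- Exclusion quotas assume the literature rates transfer to the cohort at
  hand; the procedure has no internal estimate of the true noise rate.
- The chi-squared screen ignores covariates and LD; it is a feature
  selector, not an association study.
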