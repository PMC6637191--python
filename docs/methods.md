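# Methods

## The problem

Given a biallelic SNP panel genotyped in cases and controls, two questions
are addressed jointly: (i) how well can standard machine-learning families
— penalized logistic regression, gradient-boosted trees, feed-forward
networks — classify disease status from genotypes, and (ii) how stable are
the loci those models flag as important, across data folds, across model
families and across importance criteria. The second question is the one
the package is organized around: a locus that tops the ranking of one
model on one fold but vanishes elsewhere is an artefact, not a finding.

## Synthetic data

Real Immunochip-scale cohorts are access-restricted, so the pipeline is
exercised on synthetic data whose generator reproduces the statistical
features that matter to every downstream stage.

**Genotypes.** Each SNP has a minor-allele frequency drawn uniformly from
`maf_range` (default (0.001, 0.5]). An individual's two allele tracks are
sampled independently, so genotypes are Binomial(2, q) — Hardy-Weinberg —
marginally. Inside an LD block (default 10 consecutive SNPs) each allele
copies the corresponding allele of the previous SNP with probability
`ld_rho` (default 0.5) and is a fresh Bernoulli draw otherwise. This
first-order copying is the simplest mechanism that makes nearby SNPs
partially interchangeable as predictors, which is the property the
stability analysis must cope with; it does not attempt to reproduce human
LD maps.

**Phenotypes.** Case status is Bernoulli with
`P(case | g) = σ(β₀ + Σ βⱼ gⱼ)`; the `n_causal` causal SNPs (default 20)
get `βⱼ = log ORⱼ` with ORs uniform in `causal_or_range` (default
1.1–1.5, the typical effect-size band of common-variant associations).
Causal SNPs are restricted to MAF ≥ 0.05: rare causal alleles carry almost
no classification signal at desk-scale sample sizes, and GWAS-ascertained
loci are common variants by construction. β₀ is calibrated by bisection on
an independent genotype sample so that the expected prevalence matches the
requested case fraction; individuals are then drawn and labelled until the
requested case and control counts are filled (rejection capped at
`max_draw_factor` times the target, default 30×, after which a
`CalibrationError` is raised). Default sample sizes are 1,733 cases and
3,267 controls — a 5,000-sample cohort at the case/control ratio 0.53 of
large inflammatory-bowel-disease collections.

**Density and missingness.** SNP positions are sorted uniform draws per
chromosome (five 50 Mb chromosomes by default), except that 500 kb windows
containing a causal SNP receive `density_enrichment`× (default 2×) the SNP
density — emulating disease-focused genotyping arrays and required to
reproduce the null-model locus-overlap artefact discussed below.
Missing genotypes are injected independently per entry at class-specific
rates; the two alleles of a genotype are jointly missing. A differential
rate (e.g. 5% in cases vs 1% in controls) makes the missingness indicator
itself predictive, the artefact the coding comparison quantifies. The
differential-rate mechanism is a stand-in — the missingness process of
real consortium data is uncharacterized beyond the suspicion of bias.

**What passing tests do not show.** The generator has no population
structure, no sex chromosomes, no genotyping batch effects and no
epistasis; results on it demonstrate that the pipeline's statistics behave
as specified, not that any particular model will attain a particular AUC
on real cohorts.

## Pre-processing

QC applies three filters in a fixed, logged order: samples with missing
rate > 5%, then SNPs with missing rate > 2%, then SNPs with HWE p < 10⁻¹⁰
computed in surviving controls only. The HWE test is the 1-df chi-squared
goodness-of-fit against p², 2pq, q² (the convention behind 10⁻¹⁰-scale
cuts at cohort sample sizes; monomorphic SNPs return p = 1). The filter
sequence is one-pass, matching how such screens are run in practice; it is
a fixpoint whenever removals do not push survivors' rates over the
thresholds, which holds at realistic scale but not for tiny matrices with
rates at the threshold edge.

Imputation: `Maj` replaces a missing genotype with two copies of the
locally most common allele; `HWc`/`HWa` draw Binomial(2, q̂) with q̂
estimated from observed controls / all observed samples. "Binomial
satisfying HWE" is read as a draw at the estimated minor-allele frequency
(genotype-class frequencies would be the alternative reading). Each SNP
uses its own (seed, SNP-index) random stream so imputed data are
reproducible. `Unkw` leaves missing values in place for the
unknown-genotype coding.

Codings: `sum` = minor-allele count; `OHE` = three indicators per SNP;
`raw` = two per-allele binary features (genotype g ↦ ⌈g/2⌉, ⌊g/2⌋), an
encoding with the same span as OHE at 2/3 the width; `OHE4` adds a U-U
class for unimputed data. `sum` is exactly the (0,1,2)-weighted collapse
of `OHE`.

## Preselection

Four chi-squared tests per SNP (missing genotypes dropped per SNP):
genotypic (2×3, 2 df, df reduced when a genotype class is empty), dominant
(AA vs Aa+aa), Cochran-Armitage trend with weights (0,1,2) — algebraically
N·corr(y,g)², the score test of the additive logistic model — and allelic
(2×2 on 2N allele counts; "combined alleles counting" is read as this
standard test). No continuity corrections; degenerate tables give p = 1.
The retained panel is the union of the four lists at MAF > 0.01 (strict)
and p < 10⁻⁴ (strict); these are screening thresholds, not inference, so
no multiple-testing adjustment is applied anywhere.

## Models

All families sit behind one adapter exposing probabilities, optional
per-feature weights (linear, random) and split gains (trees). Linear
families delegate to scikit-learn and their scores are reproduced exactly
as σ(w·x + b) from the exported weights. Boosted trees use LightGBM in
deterministic single-thread mode; the exported `gain` importance is the
library's total split gain per feature. The neural families are a native
numpy implementation: ReLU hidden layers of equal width (default 64),
sigmoid output, Adam (lr 10⁻³, batch 128), L2 weight decay 10⁻⁴, early
stopping on a 10% stratified validation split (patience 8, max 60 epochs).
The residual variant requires an odd hidden-layer count: the first layer
projects to the hidden width and each subsequent pair forms a full
pre-activation residual block `z ← z + W_b·g(W_a·g(z))`. Optimizer and
epoch settings are package defaults chosen as standard practice, not
asserted to replicate any particular study's grids; hyper-parameter grids
are configuration (λ on a log grid 10⁻⁴…10², ElasticNet mixing
{0.1, 0.5, 0.9}), selected by stratified 10-fold CV on the training split
with ties resolved toward stronger regularization.

The random model assigns i.i.d. standard-normal weights to the input
features and never trains. On a large null panel its held-out AUC
concentrates tightly around 0.5; on a *small, signal-enriched* panel a
single random projection can land visibly away from 0.5 on one fold —
expected behaviour, since the variance of the random AUC scales inversely
with the number of (effective) features.

## Importance and loci

PFI scores a feature by the test-set AUC drop averaged over 10 independent
column permutations; positive = drop, negative values are kept and rank
below zero, and constant columns score exactly 0. Linear scorers use an
incremental update (only the permuted column's additive term changes);
other models re-score the matrix. |weight| and gain rankings come from the
adapter exports. Ties everywhere break by ascending feature/SNP/locus
index so that ranked lists are deterministic, which the robustness
statistics require.

Loci are fixed 500 kb windows per chromosome: window index
`⌊(bp − 1 + shift)/500000⌋` with 1-based positions. Multi-column codings
collapse to a SNP score by the maximum over the SNP's sub-features, and a
locus scores the maximum over member SNPs. The "bis" partition shifts the
grid by 250 kb to smooth window-boundary bias (the shift direction is
immaterial to that purpose). Because enriched windows hold more SNPs, even
random rankings hit them more often — the density-matched null that locus
overlap curves must be compared against.

## Robustness and agreement

For M ranked lists and prefix length x, appearance counts of each locus in
the M top-x prefixes are tallied; R = (sum of the x largest counts)/(M·x),
with count ties at the cut broken by locus id. R = 1 for identical
prefixes and 1/M for pairwise-disjoint ones. Spearman agreement of two
top-x lists is computed over the union of the prefixes with absent loci
padded at rank x + 1 (a convention; an intersection-only variant is a
reasonable alternative). Intra-model summaries pair all C(M,2) fold
couples (45 for 10 folds); between-model summaries pair two models on the
same fold. Rank combination across models admits a locus at the smallest x
at which it is in every list's top-x, with ties broken by rank sum then
locus id.

## Pipeline defaults and numerical choices

Stratified splitting allocates `round(frac·n)` samples to the training
split with the case count `round(frac·n_cases)`, realizing the full
dataset's class ratio on both subsets exactly. Refold seeds derive from
the global seed via a seed sequence; every stage's randomness is a pure
function of the global seed, so a rerun serializes to a byte-identical
report. Preselection runs on the training split only by default —
screening on the full dataset leaks test labels into feature selection —
with `paper_mode=True` available to reproduce the common
screen-then-split practice when comparing against analyses that used it.
Control subsampling to a target case/control ratio removes controls only.

Desk-scale problem sizes used in the shipped tests and the acceptance
script (2,000–5,000 samples, 500–10,000 SNPs, 10 refolds) were chosen so
the full pipeline runs in minutes on one CPU; the association-test
calibration check simulates null SNPs at MAF ∈ [0.1, 0.5], the regime
where the chi-squared approximation is accurate (the MAF > 0.01 screen
precedes the tests in any real run).

## Known limitations

* The LD model is first-order within fixed-size blocks; long-range LD and
  recombination-map realism are out of scope.
* `Maj` imputation is allele-wise, which for jointly-missing genotype
  calls means 0 minor alleles whenever the major allele is truly major.
* The residual network is a compact reference implementation (no batch
  normalization or dropout); it is not tuned for GPU-scale problems.
* Cross-partition (original vs bis) locus matching is by window identity
  after shifting, i.e. ≥ 250 kb overlap; finer-grained reconciliation of
  boundary-straddling signals is not attempted.
* Statistical significance of robustness differences between models is not
  assessed; curves are reported as mean ± SE over pairs.
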