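# Methods

## The analysis

The package studies whether common colorectal-cancer (CRC) risk alleles
contribute to the multiple-adenoma phenotype (5–100 colorectal adenomas with
no pathogenic Mendelian-polyposis variant) and whether they modify polyposis
severity in familial adenomatous polyposis (FAP).

The central quantity is a weighted polygenic risk score over a fixed panel
of 18 CRC susceptibility SNPs: S_i = Σ_j β_j n_ij, with n_ij the count
(0–2) of risk alleles of SNP j in individual i and β_j the per-allele
ln(OR) from unconditional (single-SNP) logistic regression in a reference
case–control panel, oriented so β_j ≥ 0. The score's theoretical range is
[0, 2Σβ], which is [0, 4.78] for the default panel.

Inference proceeds in five stages.

**QC.** Samples with a genotype call rate below 94% are excluded (a rate
exactly at the threshold is kept). Each marker is then tested for deviation
from Hardy–Weinberg equilibrium (HWE) with the exact conditional test,
*in controls only*: under a true association, case genotype frequencies
deviate from HWE even with perfect genotyping, so including cases would
confound genotyping error with signal. Markers with exact P ≤ 0.05 are
flagged but not removed — the expected state of a curated panel is zero
flags, and no removal rule is prescribed. The exact test enumerates, for
the observed allele counts, every possible heterozygote count with exact
integer combinatorics (weights C(N,n_AA)·C(N−n_AA,n_Aa)·2^n_Aa) and sums
the probabilities of all tables whose probability does not exceed the
observed one. Ties are decided by exact integer comparison, so P = 1 is
attainable and there is no floating-point tie ambiguity; arithmetic is
rationals converted to float only at the end.

**Weights.** One logistic regression per SNP (additive dosage coding,
maximum likelihood via statsmodels), not a joint fit: the panel SNPs are
on different chromosomes or far apart, so the single-SNP model matches how
GWAS effect sizes are defined. A SNP whose fitted coefficient is negative
has its orientation flipped (risk allele swapped, dosage recoded 2−n) so
that every stored β is positive; the flip is recorded. Wald standard
errors come from the observed information at the MLE. Monomorphic SNPs and
(quasi-)separation raise errors naming the SNP; a fitted |β| > 15 is
treated as separation.

**Scoring.** Score and unweighted risk-allele count per individual.
Samples passing the 94% filter can still carry an occasional failed call;
the default policy imputes a missing dosage by its control-population
expectation 2p̂ (unbiased under HWE and missingness-at-random). A
"rescale" policy (multiply by Σβ_all/Σβ_observed) and an "omit" policy are
available. Under imputation the risk-allele count is likewise the expected
count and may be non-integer for affected samples.

**Association.** Shapiro–Wilk is reported as a score-normality diagnostic.
Case groups are compared with controls by two-sample t-test — Welch with
Satterthwaite df by default because group sizes and variances differ;
the pooled variant is provided, as is a summary-statistics entry point
(`t_from_summary`) so published n/mean/SD rows can be checked without raw
data. Severity ordering (controls < 5–9 adenomas < ≥10 adenomas) is tested
with a proportional-odds cumulative-logit model (statsmodels OrderedModel,
BFGS; a stop reporting "precision loss" is accepted as converged when the
gradient norm is below 1e-5). Per-SNP effects come from one joint logistic
regression on all 18 dosages, reported as OR with Wald 95% CI and nominal
P (no multiplicity correction, since individual-SNP findings are reported
as nominal). Variance explained is Nagelkerke pseudo-R² by default, with
the intercept-only log-likelihood in closed form; a liability-scale
transform is available but requires an explicit population prevalence —
the case fraction in a case–control sample carries no prevalence
information, so no default is supplied.

**FAP modifier.** Ordinary least squares of ln(polyp count at colectomy)
on score + age + sex + APC variant-position class (treatment coding,
reference level "other"; classes: codons 1265–1389, attenuated-FAP
regions, other). Modelling the log count makes the exponentiated score
coefficient a multiplicative effect on polyp number, the most coherent
reading of an "OR with CI" from a severity regression; a raw-count linear
model sits behind `log_outcome=False`. Because patients cluster in
families, family-clustered sandwich standard errors are available next to
the naive ones. The per-SNP scan repeats the model with each dosage in
place of the score.

## Synthetic data

No genotype resource of this design is public, so the generators are
first-class package code emulating each required input.

*Reference panel.* Controls are independent per-SNP Hardy–Weinberg draws
Binomial(2, p_j); cases are Hardy–Weinberg draws at the retrospective
frequency p' = p·OR/(1 − p + p·OR) implied by a multiplicative per-allele
model — exact and fast, with no rejection step.

*Study cohorts.* Controls as above. The MA cases' joint score shift is
produced by exponential tilting: weighting genotype vectors by
exp(λ·score) factorises over SNPs into tilted binomials with
p_j(λ) = p_j e^{λβ_j}/(1 − p_j + p_j e^{λβ_j}), and λ is solved (Brent)
so the expected mean score exceeds the control mean by exactly the
configured shift (default 0.17). Every marginal stays in HWE. Each case's
adenoma count is tied to its score through a logistic link for
P(count ≥ 10) — intercept logit(103/178), slope 0.5 per score unit, which
reproduces a ≈0.09 score gap between the ≥10 and 5–9 subgroups — with
counts drawn uniform on 5–9 or 10 + geometric (mean 7, capped at 100).
Controls are *not* screened to be adenoma-free; a contamination-rate
option mixes case-distributed individuals into the control arm.
Missingness is completely at random (no mechanism is asserted by the
design); a configurable fraction of samples is simulated with a 0.35
per-genotype failure rate, which almost surely puts an 18-SNP sample
below the 94% filter.

*FAP families.* Families share an APC class drawn from configurable
probabilities; polyp counts are log-normal around the class mean (default
means 1000 / 30 / 300 for severe / attenuated / other, dispersion 0.5 on
the log scale, mean-corrected by σ²/2), multiplied by
score_effect^(score − E[score]); default score_effect 1.0 (no modifier
effect, the null the analysis is expected to confirm). Defaults of 30
families with mean size 64/30 give ≈64 patients. Genotypes are
independent HWE draws — within-family genotype correlation (≈0.5 for
relatives) is *not* modelled, which makes the family-clustered standard
errors conservative relative to real pedigree data.

### The default panel and its calibration

The 18 markers carry the published rsIDs, hg19 positions and alleles. The
default weights are GWAS-scale: 18 distinct values with mean 4.78/36 ≈ 0.133
(so the score maximum is exactly 4.78) spread along a standardized
normal-quantile ladder (ORs 1.03–1.27). Irregular spacing matters: an
arithmetic ladder puts scores on a coarse lattice that a Shapiro–Wilk test
detects at n = 818, whereas the quantile ladder leaves cohort-scale score
distributions indistinguishable from normal. Control risk-allele
frequencies (0.34–0.69) and the ladder spread were solved analytically,
once, so the control score distribution has mean 2.27 and SD 0.42 — the
scale on which the study design is defined. The three markers individually
associated with the phenotype (rs6983267, rs10795668, rs3802842) receive
the largest weights; rs10795668's risk allele is G (its printed variant
allele A is protective). Their reported case–control odds ratios
(1.54, 0.64, 1.31) are kept as an explicit generator override
(`MA_ASSOCIATION_ORS`) for effect-recovery experiments rather than as
default panel weights: weights of that size on an SD-0.42 score force the
three SNPs to extreme frequencies, which skews the score distribution and
decouples the weighted score from the simple allele count — neither of
which matches the reported behaviour of the score.

What passing tests on these generators do **not** show about real data:
no linkage disequilibrium between panel SNPs, no population
stratification, no within-family genotype sharing, missingness is MCAR,
and case ascertainment is reduced to a pure score shift plus a
score-linked severity split.

## Numerical choices and defaults

| Parameter | Default | Why |
|---|---|---|
| call-rate threshold | 0.94 (exclusive) | panel-QC convention; boundary retained |
| HWE alpha | 0.05 | flag level; controls only |
| missing policy | impute 2p̂ | unbiased under HWE + MCAR |
| t-test | Welch | unequal n and variance across groups |
| score_shift | 0.17 | the case–control mean gap on the 2.27/0.42 scale |
| n_ma_cases / n_controls | 178 / 818 | the study design |
| n_ref_cases / n_ref_controls | 5000 / 5000 | weight-estimation panel size |
| missing_rate | 0.002 | keeps overall call rate > 99.5% |
| low_callrate_fraction | 0 (0.043 in QC demos) | 0.043 × 186 ≈ 8 excluded samples |
| FAP families / mean size | 30 / 64÷30 | ≈64 patients in 30 families |
| ordered-logit convergence | BFGS, gtol 1e-8 | gradient < 1e-5 accepted at "precision loss" stops |

Degenerate inputs are errors, not warnings: empty groups, groups of one,
zero SD summaries, monomorphic or separated SNPs, rank-deficient joint
designs, all-zero HWE tables, unknown severity categories.

Reproducibility: every generator derives its stream from
(seed, stage-key) via `numpy.random.SeedSequence` spawn keys, so a config
seed fixes all outputs bit-for-bit; the pipeline manifest records SHA-256
digests of every file written.

## Problem sizes in the shipped checks

The test-suite and acceptance-script simulations use: one 5000/5000
reference panel for weight recovery; 200 replicates of 600/600 panels for
joint-model CI coverage; 500 replicates for each null-calibration check
(t-test at 60/120, ordered logit at 120/240, joint model at 250/250, FAP
scan at 30 families); 200 replicates of the full 178/818 design for the
power/consistency check; and exhaustive HWE-oracle comparison over all
genotype tables with total ≤ 200 (~690k tables). These sizes keep every
Monte-Carlo standard error well inside the asserted bands.

## Known limitations

- Weights estimated from a finite reference panel wobble the score scale:
  the control mean under re-estimated weights varies by ≈±0.2 across
  panels at n = 5000/5000. Distribution-level checks therefore score with
  the fixed default panel weights, mirroring a study that takes its
  weights as given.
- The liability-scale R² uses the standard threshold-model ascertainment
  correction, which assumes multivariate normality of the latent liability
  given the score — approximate for a discrete 18-SNP score.
- The proportional-odds model assumes a common slope across the two
  cutpoints; no test of that assumption is built in.
- The per-SNP modifier scan drops records with a missing call SNP-by-SNP,
  so its fits are on slightly different subsets per SNP.
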