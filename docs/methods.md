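# Methods

This note documents the models, rules and numerical choices behind
`trdprs`, what the synthetic-data generator does and does not emulate,
and the known limitations.

## Phenotyping model

Dates are integer day numbers; calendars are an I/O concern. For each
patient × drug (full 7-character ATC code), dispense dates are
de-duplicated (same-day repeats carry no duration information) and
sorted; a *treatment episode* is a maximal run in which every
consecutive gap is ≤ `gap_days` (default 120 — "within 120 days" is
read inclusively, so a gap of exactly 120 joins and 121 splits).
Episode duration is last-minus-first dispense date; a single dispense
therefore has duration 0 and is never adequate — no days-of-supply
imputation is attempted, since the registers modeled here carry dispense
dates only. Adequacy is duration ≥ `min_adequate_days` (default 42,
i.e. six 7-day weeks, inclusive).

"Before the first ECT" is enforced by censoring: only dispenses with
date strictly below the patient's first ECT date enter the censored
episode build, so an episode must *complete* its qualifying span before
ECT to count. "Different antidepressants" counts distinct full ATC
codes with at least one adequate episode (two adequate episodes of the
same substance count once; lithium N05AN01 is not under N06A and never
counts).

Classification per definition:

| definition | TRD | non-TRD | excluded |
|---|---|---|---|
| broad | ever ECT | never ECT | — |
| narrow_1 | ECT ∧ ≥1 adequate before first ECT | no ECT ∧ ≥1 N06A dispense ∧ ≤2 adequate (uncensored) | all others |
| narrow_2 | ECT ∧ ≥2 adequate before first ECT | same as narrow_1 | all others |

Two deliberate interpretations: (1) a narrow non-TRD patient must have
at least one antidepressant dispense — "have used antidepressants but
with no more than two of adequate duration" is read as requiring use, so
a patient with no dispensing history is excluded rather than non-TRD
under the narrow definitions; (2) patients failing both arms of a
narrow definition are labeled `excluded` and reported, never silently
dropped. These choices are config-independent; the thresholds
(`gap_days`, `adequate_days`) are configuration keys.

The episode builder is verified against a brute-force oracle: the
greedy left-to-right split is the unique coarsest contiguous partition
whose within-block gaps all stay within the threshold, and tests
enumerate all partitions on random streams of up to 8 dispenses.

## Genotype QC

Dosages are a samples × variants float matrix with `NaN` for missing;
count-based tests use hard calls (dosage rounded to the nearest
genotype). Filters run sequentially with per-rule removal counts
(variant order: call rate < 0.98; invariant; HWE exact p < 1e-6 in
cases or in controls separately; |case−control call-rate difference| >
0.01; MAF < 0.01 strict. Sample rules: call rate < 0.98,
|F_het| > 0.20). Re-running the cascade on its own output removes
nothing. A merge-stage pre-pass (monomorphic, indels, strand-ambiguous,
MAF < 0.01) is available as an option using the same machinery.

The HWE test is the conditional exact test: given the observed allele
counts, every possible heterozygote count (same parity as the
minor-allele count) is enumerated, probabilities computed in log space
via log-gamma and normalized with log-sum-exp, and the two-sided p-value
sums configurations with probability ≤ the observed one (with a 1e-12
relative tolerance for ties). Monomorphic tables return p = 1.

Heterozygosity F is 1 − observed/expected heterozygote count per
sample, with expectations Σ 2p(1−p) over that sample's non-missing
variants and allele frequencies estimated from the study data itself —
the pipeline is self-contained and uses no external frequency panel.

Ancestry outliers: variants are standardized by the reference panel's
allele frequencies (mean 2p, SD √(2p(1−p))), principal axes come from
an SVD of the standardized reference matrix, and study samples are
projected onto those axes. A sample is flagged when PC1 or PC2 lies
more than 6 SD from the target population's mean, where mean and SD are
computed from the target-population subset's own reference scores (the
natural reading of the 6-SD rule; projecting reference samples through
their own loadings reproduces their scores to 1e-8, which is tested).

Relatedness: method-of-moments IBD estimation from identity-by-state
counts. Per pair, observed counts of loci sharing 0/1/2 alleles IBS are
compared to their expectations under IBD = 0/1/2 given study allele
frequencies; the IBD-state probabilities are solved in sequence,
clipped to [0, 1], and π̂ = P(IBD=2) + P(IBD=1)/2. A self-pair gives
exactly 1; simulated parent–offspring pairs recover 0.5 ± 0.05 at 5000
variants. No finite-sample frequency correction is applied, which
biases π̂ upward by O(1/n_samples) — negligible at cohort scale but
visible if frequencies are estimated from a handful of samples. The
all-pairs path is computed with matrix products; π̂ noise scales as
~1/√(n_variants), so thresholding at 0.2 needs a few thousand variants
to be meaningful. Pruning is greedy: repeatedly drop the sample in the
most above-threshold pairs, ties broken by lower call rate then
lexicographic id (the pair-member choice is not dictated by the
phenotyping rules; this is our deterministic convention).

## PRS

Summary-statistic filters run in order with logged counts: MAF < 0.1 or
INFO < 0.9 (GWAS-side metadata preferred; study-side estimates are
substituted with a log message when the weight table lacks them);
duplicated ids (all copies dropped — a duplicated id is unresolvable);
strand-ambiguous allele pairs {A,T}/{C,G}, judged from the weight
table's own alleles since genotype strand cannot be audited without an
external reference; the MHC region chr6:28–34 Mb inclusive on both ends
(the conservative, larger exclusion); then whitelist intersection.

Harmonization maps each weight onto the genotype's alt-allele dosage:
effect = alt keeps the weight, effect = ref flips its sign, anything
else is dropped and counted. Scoring is the plain weighted dosage sum
with mean imputation (2 × alt-allele frequency in the scored sample)
for missing dosages — the convention of standard scoring tools.
Standardization uses the sample SD (n−1) and happens once within the
whole scored sample; subset analyses (narrow definitions, lithium
exclusion) reuse those z-scores rather than re-standardizing, matching
the whole-sample standardization convention. Quartiles cut at the
empirical 25/50/75 percentiles with ties going to the lower quartile.

LD-aware rescaling of GWAS effects (SBayesR and kin) is consumed, not
reimplemented: the weight table input is assumed already rescaled.

## Association battery

- Mean difference: Welch (unequal-variance) two-sided t-test — the
  robust default when arm variances are not assumed equal.
- OR per SD: logistic regression of TRD status on the PRS z-score plus
  the first four PCs, maximum likelihood via Newton scoring (tolerance
  1e-8, ≤ 50 iterations, backed by statsmodels), Wald 95% CI
  exp(β ± 1.959964·se) and Wald p — matching the OR + CI reporting
  style. Perfect separation is detected and reported naming the
  offending predictor; rank-deficient designs are rejected.
- Nagelkerke R²: [1 − exp((2/n)(ll₀ − ll₁))]/[1 − exp((2/n)·ll₀)]
  where the baseline model contains the covariates only and the full
  model adds the PRS — so the R² isolates the score's contribution.
- Liability conversion: the ascertainment-corrected threshold-model
  factor C = [K(1−K)/z²]·[K(1−K)/(P(1−P))], z the standard-normal
  density at Φ⁻¹(1−K); K defaults to 0.10 (assumed TRD share of MDD
  cases) and P is the analyzed sample's case fraction per definition.
  K = P = 0.5 gives exactly π/2, which is tested to 1e-10.
- Quartile trend: Cochran–Armitage 1-df chi-square with scores
  (1,2,3,4) (invariant to affine rescaling), validated against R's
  `prop.trend.test`. A plain k×2 heterogeneity chi-square is exposed as
  an option, since "chi-squared test across quartiles" is ambiguous;
  the trend test is the default because a *trend* is the stated target.
- Multiple testing: Bonferroni α/m with m = #traits × #definitions
  (6 in the canonical battery); significance is p ≤ threshold.
- Sensitivity: refits additionally adjusted for disorder PRSs
  (MDD, bipolar, both) and a refit excluding lithium users from the TRD
  arm only, mirroring the design where lithium exposure could confound
  a lithium-response score.

## Synthetic cohorts

The generator's defaults encode the study conditions the pipeline
models: ~1500 TRD-destined vs ~2500 non-TRD-destined MDD cases, true
lithium-response-PRS effect OR = 1.12 per SD, registry category
probabilities matching the reported register proportions (60.8% of ECT
cases with ≥2 adequate antidepressants before first ECT, 83.6% with ≥1,
94.2% with any antidepressant use; 66.5% of non-ECT cases with ≤2
adequate; ~28% lithium use among ECT cases, 5% otherwise). Variants are
independent biallelic sites in Hardy–Weinberg proportions with MAF
uniform in (0.05, 0.5); 10% are planted strand-ambiguous, 3% inside the
MHC window, INFO is uniform in [0.3, 1.0], background missingness is
0.2% (realistic for post-imputation data) with a handful of planted
low-call-rate samples and variants so the 0.98 call-rate filters have
deterministic work. A causal fraction (default 10%) of variants gets
Normal(0, 0.05²) weights; 20% of weight rows are emitted in swapped
allele orientation with sign-flipped weight to exercise harmonization.
True TRD status is Bernoulli(logistic(base + ln(OR)·z)) on the
standardized true score, with the baseline logit set to hit the target
case fraction; truth is written to a separate file the pipeline never
reads.

The registry generator is exactly invertible at zero noise: with every
TRD-destined patient given ≥2 adequate pre-ECT episodes and every
non-TRD-destined patient given 1–2 adequate episodes and no ECT,
phenotyping recovers the generated status with 100% agreement under all
three definitions (tested). Noise knobs inject gap-boundary episodes
(gaps of exactly 120/121 days), single-dispense streams, and
post-ECT-only histories, which break the narrow definitions in
controlled ways.

What the generator does **not** emulate — and hence what passing tests
do not establish about real register data: linkage disequilibrium
between variants (each variant is independent, so the measured PRS is
an attenuated proxy of the true score once the INFO/MAF filters drop
variants); realistic days-of-supply per dispense; family/twin
structure; diagnosis-code noise in case ascertainment; batch effects
between genotyping waves; calendar effects (register coverage windows,
drug launches).

## Problem sizes and numerics

Tests and the acceptance script run at deliberately reduced scale,
chosen so the whole suite completes in a few minutes while keeping
every statistical check well-powered: demonstration cohorts of 800
samples × 2000 variants; parameter recovery with 200 replicates of
n = 4000 (mean log-OR bias bound 10% of ln 1.12, CI coverage within
[0.91, 0.98]); type-I calibration with 1000 replicates of n = 1000
(rejection rate within [0.03, 0.07]); IBD benchmarks at 5000 variants.
Floating-point tolerances: scoring vs brute force 1e-10, z-score
moments 1e-8, PCA self-projection 1e-8, logistic vs closed form 1e-6,
exact-test vs enumeration 1e-10.

Degenerate inputs are errors, not silent results: empty cohorts,
constant scores (zero-variance standardization), single-sample arms in
the t-test, single-class outcomes, rank-deficient or separated designs,
zero comparisons in the Bonferroni rule. All-tied quartiles warn and
assign Q1.

## Known limitations

- The logistic Wald inference is first-order; no Firth correction, so
  very sparse strata (tiny arms) should use exact methods instead.
- π̂ uses study-estimated allele frequencies without small-sample
  correction; with fewer than ~50 samples the unrelated expectation is
  visibly above 0.
- The PCA outlier rule assumes the reference panel's target population
  is genetically homogeneous; admixed study samples get flagged or
  passed as a whole, not decomposed.
- The pipeline consumes pre-rescaled GWAS weights; no LD-aware
  shrinkage, clumping or multi-ancestry scoring is provided.
- Sex-chromosome checks (sex mismatch) are out of scope — inputs are
  autosomal dosages.
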