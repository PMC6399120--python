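# Methods

This note documents the statistical procedures `cgas` implements, the
assumptions behind them, the synthetic-cohort generator used to exercise
them, and the design decisions taken where the analysis protocol left the
choice open.

## Data model and missingness policy

Genotypes are effect-allele dosages in {0, 1, 2} with an explicit missing
sentinel; the effect allele defaults to the minor allele in the analysed
sample (overridable per SNP), which makes odds ratios interpretable
against the rarer allele and matches MAF-based reporting conventions.
There is **no imputation anywhere**: every fit is a complete-case fit, and
multivariate models use one fixed subject set with complete data for all
their SNPs so that AICs are comparable across models (a likelihood is only
comparable on a common sample). Race is collapsed to Caucasian /
non-Caucasian for modelling. Subjects present in only one of the
genotype/phenotype inputs are dropped with a warning, not an error.

## Quality control

Filters apply in a fixed, logged order: sample missingness (default
threshold 0.5), arm-specific total missingness (a SNP genotyped in no
control cannot contribute to a case-control contrast and is removed),
variant missingness (default threshold 0.5 — deliberately permissive,
since candidate-gene panels can retain SNPs with ~46% plate-failure
missingness), and Hardy–Weinberg. HWE is tested two ways on cases and
controls pooled: a 1-df χ² without continuity correction, and the
conditional exact test (full enumeration of heterozygote counts given the
allele counts, two-sided by summing configurations whose conditional
probability does not exceed the observed one). A SNP is *in* HWE only if
neither test rejects at α (default 0.05). A monomorphic SNP has a single
attainable configuration, so the exact test returns p = 1 while the χ² is
flagged untestable (NaN). The uncorrected χ² was chosen because it tracks
the exact test more closely at these sample sizes than the
Yates-corrected version.

Duplicate-sample concordance is the fraction of jointly non-missing SNPs
with equal calls; allele-frequency comparisons between groups (or against
external reference frequencies with an effective allele count) use the
two-sided Fisher exact test on the 2×2 allele-count table.

## Single-SNP association

Each SNP is encoded under five inheritance models — dominant (0,1,1),
recessive (0,0,1), overdominant (0,1,0), additive (0,1,2), codominant
(two indicators, 2 df) — and fitted by logistic regression including the
adjusting covariates (sex, age, Caucasian y/n by default) on the SNP's
complete-case set. Akaike's criterion (AIC = 2k − 2ℓ) selects the coding;
when only two genotype classes are observed, several codings collapse to
the same fit and ties are broken by the fixed order dominant < recessive <
overdominant < additive < codominant. The reported OR is the Wald OR of
the SNP term (for the codominant coding the summary carries the term with
the larger |log OR|; both terms stay in the detail output). The adjusted
p-value is the likelihood-ratio test of the chosen SNP model against the
covariates-only model (χ² with 1 or 2 df).

The logistic fitter is a Newton/IRLS core with step-halving: convergence
when the largest absolute score falls below 1e−8 or the relative
log-likelihood change below 1e−10, at most 100 iterations. Complete
separation is detected as diverging coefficients and flagged (the fit is
returned with a warning, not corrected — no Firth penalty). The fitter is
cross-checked in the tests against statsmodels GLM, against the closed-form
2×2 odds ratio for a single binary predictor, and against a coarse-to-fine
grid-search maximiser on small fixtures.

### Permutation test

For SNPs passing α, a permutation p-value accompanies the adjusted LRT:
the likelihood-ratio statistic of the **unadjusted** SNP model
(2·(ℓ_SNP − ℓ_null)) is recomputed under uniformly random permutations of
the case/control labels, and p = (1 + #{LR\* ≥ LR_obs}) / (n_perm + 1)
with n_perm = 20,000 by default. Two deliberate choices:

- *Unadjusted statistic.* Permuting labels destroys the covariate–outcome
  association, so a covariate-adjusted statistic is not exchangeable under
  the permutation null; the pipeline therefore pairs an adjusted LRT p
  with an unadjusted permutation p. A covariate-respecting variant
  (stratified permutation within covariate-risk strata, in the spirit of
  Freedman–Lane) is available behind a flag.
- *Add-one estimator.* (r+1)/(n+1) rather than r/n avoids impossible zero
  p-values; at n_perm = 20,000 the difference is below reporting
  precision.

Because a logistic model whose only predictor takes ≤ 3 distinct values
depends on the data only through the per-genotype-cell case counts, each
permuted statistic is recomputed from aggregated counts — closed form for
saturated (1-df and codominant) codings, a small vectorised Newton solve
for the additive coding. This is an exact algebraic reformulation of
refitting the model per permutation (pinned by a replay-oracle test), and
makes 20,000 permutations take seconds.

## Linkage disequilibrium and haplotypes

Two-locus haplotype frequencies are estimated from unphased genotypes by
EM: every genotype pair except the double heterozygote contributes known
haplotype counts; the double-heterozygote cell is split between the
cis/trans phases in proportion to their current expected frequencies.
Initialisation is at linkage equilibrium; iteration stops when the largest
frequency change is < 1e−8 (the log-likelihood is verified non-decreasing
at every step). From the estimate: D = p11 − p1·p2, D′ (D over its
frequency-constrained bound), r² = D²/(p1(1−p1)p2(1−p2)), and the LD
χ² = 2n·r² (2n gametes) on 1 df. A panel-wide scan flags pairs at
configurable r²/p thresholds (defaults 0.5 / 0.05); LD is computed on the
pooled sample, matching the pooled HWE choice. A sample in which every
subject is doubly heterozygous leaves the phase unidentifiable and is
flagged rather than reported. The per-pair haplotype report adds a
"haplotype structure supported" flag defined as LD p < α and |D′| ≥ 0.7 —
an explicit stand-in criterion (labelled as such in the output) for a
qualitative judgement, since no sharper rule is standard.

## Multivariate model search

All 2^m − 1 non-empty subsets of the m univariately significant SNPs
(each under its chosen coding, always with the adjusting covariates) are
fitted on the fixed complete-case set. Aliased codings — encoded columns
perfectly collinear on that sample, which genuinely happens when two SNPs
in complete LD are coded identically — are detected beforehand by exact
rank tests; only the first member of each aliased group (panel order)
enters the enumeration, and every best subset is expanded with its
aliased substitutions, which tie by construction (verified by refit in the
tests). Subsets within `aic_tie_tol` (default 1e−6, i.e. numerically
identical) of the minimum AIC are all reported; the tie-break takes the
lexicographically first subset by panel index. The pipeline feeds the
search at most the 12 most significant SNPs (configurable): best-of-five
coding selection inflates the univariate pass rate above α, and the
subset enumeration is meant for panels of roughly a dozen candidate SNPs,
not for every borderline hit.

Stepwise refinement then considers the clinical risk factors (diabetes,
hypertension) and all SNP×clinical and SNP×SNP products: bidirectional
steps by AIC under a hierarchy constraint (an interaction may enter only
while both parents are present; a parent cannot leave while its
interaction remains; adjusting covariates never leave). A p-value-driven
backward-elimination mode (drop the least significant droppable term
while its Wald p ≥ α) is available as an alternative; note the AIC mode
admits a null 1-df term with probability P(χ²₁ > 2) ≈ 0.16 per candidate,
so on null data occasional spurious interactions are *expected* — the
p-value mode is the stricter screen.

Predicted-risk profiles (e.g. a high-risk genotype/covariate combination
versus a reference profile) are contrasted on the linear predictor:
OR = exp(η_profile − η_ref) with a delta-method CI on the contrast; age
defaults to a stated value (such as the sample median) when profiles omit
it.

## ROC evaluation

The AUC is the Mann–Whitney estimator (ties counted ½), identical to the
trapezoidal area under the empirical ROC. Paired model comparisons use
DeLong's variance from case/control placement values. Bootstrap CIs
resample subjects with replacement **stratified by outcome**, refit the
model on each resample, and take the 2.5/97.5 percentiles of the resample
AUCs (a score-only fast mode skips the refit). The optimal threshold
maximises Youden's J = sensitivity + specificity − 1 (the ROC point
furthest from the diagonal), ties broken toward higher specificity;
PPV/NPV are computed at the sample case fraction and all four operating
statistics get Wilson 95% CIs (chosen for small-sample behaviour; the
underlying CI convention for such tables is rarely stated in reports).
Discrimination is evaluated in-sample (apparent AUC) by design — no
held-out set is part of the protocol — so AUCs are optimistic relative to
external validation; a split-sample mode exists but is off by default.

## Synthetic cohorts

The generator draws covariates, HWE genotypes (binomial(2, MAF)) and LD
pairs (two haplotypes per subject from a four-haplotype pool), forms a
logistic linear predictor η = intercept + Σ β·encoding + covariate effects
+ interaction terms, solves the intercept numerically (Brent) so that
E[logistic(η)] hits a target case fraction, and draws the outcome
Bernoulli. Missingness is applied afterwards: per-SNP random rates, block
missingness (one subject subset missing a SNP group), arm-specific total
missingness, and optionally a *shared failure order* — one latent
per-subject score drives every rate, so missing subsets are nested across
SNPs the way plate failures are, and the complete-case fraction is one
minus the largest rate rather than a product of retentions. Everything is
bit-reproducible under the mandatory seed.

`paper_template_config()` ships the study-like template: n = 3,004 with an
81.4% case share; covariate margins and *crude* by-arm odds ratios
matching a typical CKD case-control table (hypertension ≈ 18.6, diabetes
≈ 2.8, female ≈ 0.71, non-Caucasian ≈ 1.95, smoking ≈ 0.84); 12
modest-effect SNPs (ORs 1.22–1.74) under their stated inheritance models;
three LD pairs, one of them perfectly correlated to reproduce the
aliasing/tied-subset phenomenon; one hypertension×SNP interaction
(OR 2.68 on the recessive genotype, with a compensating negative main
effect so the marginal SNP effect stays near its univariate OR); 54 null
SNPs; 13 SNPs fully missing in controls; and the nested missingness
profile (46.3% block on two SNPs, ~6% on the rest) that leaves ~53% of
subjects complete for all 12 effect SNPs.

Two template calibrations are solved once, on a fixed internal reference
population, before any testing: the intercept (for the case share) and
the covariate effect sizes. The latter matters because logistic effects
are non-collapsible — a conditional log-OR understates the crude OR when
other strong risk factors sit in the predictor — so conditional betas are
iterated until the implied *crude* ORs match the table margins. The
template also correlates diabetes and age with hypertension (diabetics
are largely hypertensive; hypertensives are older), which keeps the
conditional diabetes/age effects modest while their crude contrasts stay
strong — without this, a clinical risk model built from independent
covariates discriminates unrealistically well. Covariates are generated
causally through this liability model only; a retrospective per-arm
sampling mode was considered and rejected because it cannot represent
interactions or LD effects coherently, and the crude-OR calibration
already reproduces the by-arm margins.

What the template does **not** emulate: genotyping batch effects,
population stratification or relatedness, covariate measurement error,
informative (outcome- or genotype-dependent) missingness, and linkage
beyond two-locus pairs. Passing tests on template data therefore
demonstrate the correctness and calibration of the procedures under the
model's assumptions, not robustness to those violations.

## Numerical choices and degenerate inputs

- Wald CIs use z = 1.959964; AIC = 2k − 2ℓ with k the number of estimated
  parameters.
- Rank deficiency raises an error naming the aliased columns (upstream
  aliasing detection should have removed them); single-class responses
  are errors; separated fits are returned flagged.
- Permutation p-values are compared with a 1e−9 slack on the LR so
  floating-point ties count as exceedances (conservative).
- Exact-test tie comparisons use a relative (log-scale) tolerance of
  1e−12 when summing configurations "as extreme as" the observed one.
- Monomorphic SNPs: untestable in association (error recorded per SNP,
  scan continues), p = 1 in the exact HWE test, undefined in LD (flagged).
- EM haplotype estimation stops at 1e−8 frequency change or 1,000
  iterations; the all-double-heterozygote sample is flagged
  phase-indeterminate.

## Problem sizes used in the checks

The shipped tests and the acceptance script scale the heavier experiments
to sizes a single CPU handles in minutes, as the package's own test
design: permutation calibration uses 1,000 null replicates at n = 600
with n_perm = 199; OR recovery uses 500 replicates at n = 3,004;
interaction recovery uses 200 replicates at n = 3,000 with a three-SNP
base model; the template pipeline run uses the full protocol parameters
(n_perm = 20,000, 1,000 bootstrap resamples). Larger replicate counts
change none of the conclusions, only the Monte-Carlo error.

## Known limitations

- Inference after AIC model selection (best of five codings, best subset)
  is not corrected for selection: univariate type-I error exceeds α and
  no multiple-testing correction is applied across SNPs, matching the
  analysis protocol; the per-SNP permutation p inherits the same
  selection.
- Separation is flagged, not penalised (no exact logistic or Firth fit).
- Only biallelic autosomal SNPs; no phasing beyond two loci; no
  haplotype-based association testing.
- Apparent (in-sample) discrimination only, by default.
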