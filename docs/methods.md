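# Methods

## Cohort representation and missingness

Genotypes are unphased diploid calls at biallelic SNPs, stored as a
minor-allele dosage matrix (0/1/2, −1 missing) plus per-SNP metadata
(`SnpDef`: gene, allele pair, declared minor-allele frequency, grouping
model).  The dosage plus the declared alleles is a lossless encoding of
the unordered allele-pair calls in the TSV/VCF inputs, and makes the
encodings and the EM pattern aggregation vectorizable.

Missingness is handled **complete-case per analysis**, not globally: each
2×2 table, EM run or model fit drops only the subjects missing one of the
columns it actually uses.  This matches the varying denominators across
the published per-variable tables (e.g. 141 subjects for rs7079, 139 for
rs275651, 120 comedication records among controls).  No genotype or
covariate imputation is attempted.

Three grouping models define the "exposed" pole of each genotype
contrast: minor-allele carriers vs major homozygotes (dominant), everyone
vs the minor-allele homozygote (recessive contrast), and heterozygotes vs
homozygotes.  The per-SNP assignments in `published.SNP_DEFS` reproduce
the published grouped-genotype splits exactly.  Age is dichotomized at 65
years for modelling; the continuous value is carried for reporting only.

## Synthetic cohort generator

The generator draws, independently per subject:

- two *ACE* haplotypes from the published pool — H1 CGA 41.8%, H2 TCG
  47.0%, H3 TCA 4.7%, H4 CCG 4.1%, H5 TGA 1.4% — collapsed to unphased
  three-locus genotypes (Hardy–Weinberg at the haplotype level).  The
  printed frequencies sum to 0.990; they are renormalized
  proportionally, which distorts no frequency by more than 0.005 and
  keeps every generating value within rounding distance of its published
  counterpart (concentrating the residual on a single haplotype would
  bias it by a full percentage point);
- each non-*ACE* SNP under Hardy–Weinberg from its published MAF, with no
  LD across genes (the study reports LD only within *ACE*);
- binary covariates at their published prevalences, independent by
  default; a Gaussian-copula hook accepts a user correlation matrix,
  since no joint structure is estimable from published margins;
- the outcome from Bernoulli(logistic(β₀ + Σ βⱼ·xⱼ)) with default effects
  equal to the published adjusted odds ratios: ln 5.04 for rs5050
  carriage, ln 3.17 for rs2640543 carriage, ln 0.12 for the H2/H2
  diplotype.

The intercept β₀ is **calibrated by exact enumeration**: the expected
marginal incidence is a finite sum over the 2^k joint exposure states
(the terms are independent by construction), and β₀ is solved by Brent's
method so that this sum equals the target incidence 21/142 to below 1e−6.
The same enumeration yields the model-implied crude (marginal) odds
ratio for any term, used as an oracle for the simulation tests.
Missing genotype calls can be injected completely at random at a
configurable per-call rate.  Follow-up time, INR and valve position are
decorative metadata; no time-to-event structure is simulated.

Because covariates and genotypes are independent of each other, the
adjusted and crude effects in the generator differ only through
non-collapsibility — passing the recovery tests shows the estimators are
correct under the stated model, not that real confounding structure is
handled; that caveat applies to all synthetic-data claims here.

## EM haplotype estimation, LD and diplotypes

Distinct multilocus genotype patterns are aggregated with counts before
the EM loop, so per-iteration cost is O(patterns · pairs) ≤ O(3^k · 2^k),
independent of cohort size; blocks are limited to k ≤ 8 loci.
Initialization is the product of observed allele frequencies
(deterministic; no seed dependence), convergence is max |Δf| < 1e−8
within 1,000 iterations, and the observed-data log-likelihood trace is
recorded — it must be non-decreasing, which the tests assert, and the
fixed point is checked against direct likelihood maximization (1-D grid
at two loci, multi-start simplex at three).

Haplotypes below a reporting threshold (1% by default, mirroring the
published five-haplotype list) are removed and the remainder
renormalized; pre-filter frequencies are kept in provenance.  Diplotypes
are hard maximum-posterior calls with lexicographic tie-breaking; the
posterior is retained so a dosage-weighted sensitivity analysis remains
possible.  A genotype incompatible with every retained haplotype is
called against the unfiltered set with a warning.  D′ and r² come from
EM two-locus frequencies with the standard normalizations; monomorphic
loci raise rather than return 0/0.

## Association and model building

The univariate test is the uncorrected Pearson χ² when all expected cells
are ≥ 5 and the two-sided Fisher exact test (point-probability method)
otherwise.  This rule was chosen because it reproduces every published
p-value at its printed precision (0.001 for rs5050, 0.045 for atrial
fibrillation, 1.000 for the sparse rows); Yates-corrected χ² does not.
Woolf's logit-method CI reproduces every published odds-ratio interval
from the integer tables to two decimals, with Haldane–Anscombe +0.5 on
empty cells (flagged).  No multiplicity correction is applied by default,
mirroring the motivating analysis; Bonferroni/BH are available and off.

The multivariable fit is Newton–Raphson ML (statsmodels) with Wald SEs
from the pseudo-inverse of the observed information; a singular Hessian
falls back to L-BFGS, and |β| > 15 flags quasi-complete separation
(flagged, not Firth-corrected).  Backward elimination removes the largest
Wald p ≥ 0.05 per step — Wald rather than likelihood-ratio, matching
conventional stepwise output in clinical statistics packages — never
removing forced-in terms; by default age and sex *enter* but may leave,
which is how the published final model ends with only the three genetic
terms.  Hosmer–Lemeshow groups are probability quantiles with ties kept
together (df = groups − 2; g = 10 default, g = 7 reproduces the published
5 df); AUROC uses the rank/Mann–Whitney identity with half-credit ties.

## Risk statistics and the weighted risk score

Attributable risk is ((AOR − 1)/AOR) × 100, computed on 1/AOR for
protective terms with the inversion recorded.  NNG = ⌈1/(RRR ×
Risk_ref)⌉; the reference risk ("risk without genotyping") has no single
canonical definition, so the package defaults to the overall cohort
incidence — which yields NNG = 8 for the H2/H2 term — and reports the
exposed-group and unexposed-group conventions side by side in an audit
structure rather than committing to one.

WRS points are the nearest-integer-rounded betas (minimum 1 point per
retained term) after recoding protective terms to their absence; on the
published betas this gives 2/1/2 points, a maximum score of 5 and the
published percentile cut points 2 and 4.  Raw-beta mode is retained for
sensitivity analysis.  Stratification takes scores ≤ the 25th-percentile
value as low and ≥ the 75th-percentile value as high, with a strict
interior middle; with integer scores the group sizes necessarily deviate
from a nominal 25/50/25 split, which is why explicit cut points can be
supplied.

## Cross-validated benchmark

Each repeat draws a fresh stratified 5-fold split (repeat seed = base
seed + repeat index); hyperparameters are tuned per outer fold on inner
3-fold grids scored by AUROC, so test folds never leak into tuning.  The
grids are conventional defaults (elastic-net mixing 0.1–1.0 × log-C;
RF 500 trees, √p or p/3 features per split; SVM cost 2⁻⁵–2⁵ with a
median-heuristic RBF bracket) since the motivating analysis states none;
all are overridable.  Margin classifiers are scored by decision-function
value, which is rank-equivalent and avoids probability calibration.  The
95% CI is the normal approximation over the 10 repeat means.  Fold
assignments depend only on the seed, so model comparisons are paired.

## Problem sizes and numerical choices

The test suite and drivers use cohort sizes chosen to make sampling error
small relative to the tolerance being asserted: 100,000 subjects for
adjusted-OR recovery (±5%), 50,000 for incidence/HWE checks (3 SE bands),
10,000 for haplotype-frequency recovery (±0.01), 2,000 × 60 replicates
for the elimination Monte-Carlo, 300 replicates for CI-coverage bands
(0.92–0.98, i.e. the nominal 0.95 ± 3 Monte-Carlo SEs).  EM tolerance is
1e−8, intercept calibration 1e−12, logistic Newton tolerance 1e−10 with a
gradient-norm check at 1e−6.

## Known limitations

- The demo cohort reconstructed from published margins has no joint
  structure across columns; it validates marginal statistics only and
  must not be used for haplotype or multivariable work (the synthetic
  generator exists for that).
- Quantities that depend on the unpublished subject-level data — the
  real-cohort cross-validated AUROCs, the fitted adjusted ORs, the
  within-cohort Hosmer–Lemeshow χ², the published NNG trio (8, 14, 19,
  whose reference-risk convention is underdetermined) — are checked at
  range level or via convention audits, not for exact equality.
- No Firth correction, trend tests, CMH stratification, HWE exact tests,
  reference-panel phasing or survival modelling.
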