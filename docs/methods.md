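# Methods

## The model

Total cholesterol is analysed on the 100·log₁₀(TC) scale, which removes
the right skew of raw TC and puts effect sizes on a convenient unit (one
unit ≈ 0.23% of the TC level; around TC = 195 mg/dL, one transformed unit
corresponds to about 4.5 mg/dL). Associations follow the additive genetic
model: the transformed phenotype is regressed on the minor-allele dosage,
adjusted for cross-sectional age, whole-genome amplification of the DNA
sample, sex, and cohort (generation) indicators where the sample spans
more than one. Covariates constant within a stratum (sex inside a
single-sex cell, cohort inside one generation) are dropped automatically.

Familial and longitudinal correlation are absorbed by nested random
intercepts: a *two-level* model (family) for baseline, one-record-per-
person analyses, and a *three-level* model (family, subject-within-family)
when all repeated examinations enter — the latter estimates the cumulative
genetic effect over follow-up and typically yields a smaller standard
error than the baseline fit because it uses several phenotype records per
person.

Estimation is restricted maximum likelihood. Because every random effect
is a scalar intercept over a nested grouping, each family's marginal
covariance is I + λ_s·blockdiag(J) + λ_f·J up to the residual variance,
and its inverse and determinant have closed forms via two Woodbury steps.
The REML criterion, profiled over the fixed effects and the residual
variance, is therefore a function of the one or two variance *ratios*
only; it is minimised by bracketed Brent (one ratio) or L-BFGS-B with the
analytic REML score (two ratios). A fit costs a fraction of a millisecond,
which is what makes the Monte-Carlo calibration below affordable. The
test-suite cross-checks estimates against a dense-matrix GLS oracle
(agreement to 1e-8) and against statsmodels `MixedLM`; note statsmodels
reports fixed-effect standard errors from the joint observed information,
whereas this package (like lme4) uses the model-based GLS covariance
σ̂²(XᵀV̂⁻¹X)⁻¹ — the two differ at the percent level.

Inference is a two-sided Wald test against the normal reference. With the
cell sizes this package targets (hundreds of subjects across scores of
families) the normal reference is adequate; the type-I calibration runs
below confirm rejection rates within [0.04, 0.06] at α = 0.05. A variance
ratio that lands on the zero boundary (< 1e-6) triggers a refit without
that component, so reported variance components are exactly zero rather
than numerically tiny; a single record per subject likewise collapses the
three-level model to the two-level one, where the subject variance is
confounded with the residual. The convergence tolerance on the profiled
objective is 1e-8. Individuals missing the dosage of the SNP under test
are dropped from that fit only (complete case), so per-SNP sample sizes
may differ.

## Stratification and heterogeneity

Scans partition genotyped individuals into sex × generation cells (six for
three generations); every entry is an independent fit restricted to the
cell, bitwise identical to a standalone fit on the same subset, and is
classed significant (p ≤ 0.05), suggestive (0.05 < p ≤ 0.1) or null.
Birth-cohort strata split a cell at the median age at biospecimen
collection — 40 years in generation 3, 60 in generation 2 by default, with
the cutoff itself belonging to the older stratum; members with unknown age
are excluded from both strata and counted in a log line. Cross-generation
comparisons at matched ages rank one cohort's examinations by the distance
of their mean age at measurement from the target cohort's mean age; the
top-ranked exam is the default selection, but all candidates are returned
and the selection can be overridden, because substantive grounds can
favour a marginally more distant exam.

Between-cell heterogeneity uses Cochran's Q with inverse-variance weights
and I² = 100·max(0, (Q − df)/Q). The S/W partition enumerates all
bipartitions of a SNP's cells; feasible S-candidates are subsets with
minimal within-group I² (zero when attainable — sampling noise rarely
yields exactly Q ≤ df, so "zero" is relaxed to "minimal") whose pooled
effect carries the reference sign; the winner maximises the between-group
I² of the two pooled estimates (df = 1), with ties broken by the larger
pooled |z| and then lexicographic cell order. All feasible candidates are
retained for audit. When no subset pools to the reference sign the
partition is flagged `no_support`; when the best achievable between-group
I² is zero (all cells identical) it is flagged `degenerate`. With noisy
estimates under a homogeneous truth the flag will generally not trigger —
the between-group I² is merely small — so the homogeneous-limit flag is a
property of the exact limit, not of sampled data. Pooling here is
fixed-effect at the cell-summary level; a pooled-individual mixed-model
fit of the S- or W-subsample can be obtained by running the association
module on the union of the S cells, and reports state which route produced
each number.

## Power

Under Hardy-Weinberg and additivity a SNP explains v = 2·MAF·(1−MAF)·β²
of trait variance, giving N = ⌈(z₁₋α/₂ + z_power)²·σ²/v⌉ for unrelated
samples. Defaults: two-sided α = 0.05, power 0.80, σ = 38 mg/dL (the
population TC standard deviation used throughout). The 0.80 power level is
a derived constant: it reproduces the published per-SNP projections to
within 0.1% under this formula, and is overridable. σ² defaults to the
*total* trait variance, the most optimistic convention and the one
matching the published projections most closely; subtracting the explained
variance (σ² − v) is available as an option. Family samples need larger N
than these unrelated-sample lower bounds. `power_at_n` inverts the formula
and a vectorised Monte-Carlo (`empirical_power`) cross-validates it by
simulating unrelated Hardy-Weinberg samples with the additive shift and
applying the two-sided slope test.

## Enrichment

A scan of n independent tests at level α expects n·α significant results;
the fold excess is observed/(n·α). Two one-sided p-values are attached:
the exact binomial upper tail P(X ≥ observed) and a normal approximation
on the observed proportion with variance taken at that proportion. Cells
of a scan are disjoint, which is what motivates the independence
assumption; residual dependence between SNPs is not modelled (the SNPs are
simulated and analysed as unlinked). Because the significant count is
integer-valued, the exact tail is conservative (super-uniform) under the
null, which the acceptance suite verifies empirically.

## The synthetic cohort generator

The generator emulates a three-generation family study: per family, a
founder couple (generation 1), their children plus married-in spouses
(generation 2), and grandchildren (generation 3). Defaults follow the
emulated design — birth years 1911/1937/1963 with SDs 6/10/9 (truncated at
±2 SD to keep enrollment windows and biospecimen ages realistic), baseline
examinations in 1948/1971/2001, 16 biennial exams for generation 1, 7
quadrennial for generation 2, one for generation 3, and DNA collection in
1990/1998/2001 which determines the age at biospecimen used for age
strata. Spouses are modelled as unrelated founders who share the family
identifier of their partner's lineage: this reproduces household
clustering in the random-effect structure without inventing genetic
relatedness. Offspring counts default to 1 + Poisson(2) per couple.

Founder genotypes are Hardy-Weinberg at the specified MAF; descendants
receive one allele per parent with transmission probability dosage/2, so
Mendelian consistency is exact by construction. SNPs are unlinked.

Phenotypes are generated on the transformed scale — cell intercept + age
slope·(age − reference age) + Σ SNP effects + family + subject + residual
Gaussian components — and back-transformed, which makes the fitted model
exactly correctly specified and enables parameter-recovery testing. Cell
intercepts are calibrated by exact log-normal moment matching so the
back-transformed mean and SD hit the per-cell demographic targets
(e.g. generation-3 men: 192.8 ± 37.0 mg/dL); the naive 100·log₁₀(mean)
intercept would overshoot the raw-scale mean by ~2 mg/dL. The calibrated
variance splits into family/subject/residual shares of 0.15/0.50/0.35 by
default, reflecting the strong within-person tracking of cholesterol and
a modest familial share; the age slope defaults to 0.22 transformed units
per year (≈ +1 mg/dL/yr). Fasting (12 h+ in 10/90/95% of exams by
generation, 5% unknown), lipid-lowering treatment (2/8/15%) and WGA flags
(10%) are assigned at configurable prevalences with zero phenotype effect
by default, so covariate screens are testable against planted shifts.
Per-exam missingness is completely at random at a configurable rate
(default 0), and an optional age-dependent thinning of generation-1
biospecimen ages (off by default) emulates survival selection.

Scenario profiles plant effect structure uniformly across the ten study
SNPs: `homogeneous` (one β everywhere; β = 0 is the null), 
`generation_clustered` (β only in generation 3), `antagonistic` (the
younger generation-3 stratum carries −β against +β elsewhere, so pooled
effects cancel), and `age_stratum` (β only in the younger strata of the
two generations with an age cutoff).

What the generator does *not* emulate: linkage disequilibrium, genotyping
error, realistic mortality, assortative mating, secular trends beyond the
between-generation intercept differences, or informative missingness.
Passing tests therefore demonstrate the machinery's correctness under a
correctly specified generative model, not robustness to those real-data
complications.

## Validation problem sizes

The Monte-Carlo acceptance checks use scaled-down cohorts chosen to keep
the full suite fast while preserving the asymptotics the tests rely on:
type-I calibration uses 2000 null replicates of ~1050 generation-2
subjects (170 families, 7 exams) per model level; parameter recovery uses
200 replicates at ~1500 subjects with β = 0.4 transformed units; the
power cross-validation simulates 2000 unrelated samples at the computed
N ≈ 6.6 k; scan behaviour uses 200 replicates of 85-family cohorts
(signal localisation), 50 replicates of 120-family cohorts (antagonism),
and 1000 null 60-test scan replicates of 100-family cohorts shared
between the mean-count check (first 500) and the enrichment
super-uniformity check. Smallest scan cells run ~100 individuals, where
the normal-reference Wald test is still calibrated to within a few
thousandths.

## Known limitations

- No kinship-matrix (GRM) models: correlation is intercept-nesting only.
- Fixed-effect pooling only in the heterogeneity module (no τ²
  random-effects meta-analysis beyond I²).
- Wald/normal inference; no small-sample df corrections
  (Satterthwaite/Kenward-Roger), so very small cells (< ~50 families)
  are mildly anti-conservative.
- The exhaustive S/W partition is exponential in the cell count; it is
  exact and instant for the ≤ 8 cells arising here but not meant for
  dozens of cells.
- Binary-trait and matched-design power calculations are out of scope.
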