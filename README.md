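# demostrat

Demographically stratified re-analysis of GWAS SNP effects on a
quantitative lipid trait in multi-generation family cohorts.

Large GWAS meta-analyses treat a risk allele's effect as an unconditional
constant. In long-running family studies spanning several generations, the
same allele can show effects that differ by sex, birth cohort and age — up
to full sign reversal ("antagonistic" effects) that cancel in a pooled
analysis. `demostrat` packages the analysis pattern needed to detect and
exploit that structure, for biostatisticians and genetic epidemiologists
working with pedigree-based cohorts (or, out of the box, with the included
synthetic three-generation cohort generator standing in for restricted
data such as the Framingham Heart Study).

## What it computes

**Association.** Total cholesterol (TC, mg/dL) is analysed as
100·log₁₀(TC) under the additive genetic model: the phenotype is regressed
on minor-allele dosage g ∈ {0,1,2}, adjusted for age, sex, whole-genome
amplification and cohort. Two mixed-model levels handle the cohort's
correlation structure,

- *baseline* (two-level): one record per person, random intercept per
  family;
- *cumulative* (three-level): all repeated examinations, random intercepts
  for family and subject-within-family,

fitted by a profiled-REML solver specialised to nested random intercepts
(closed-form Woodbury algebra per family; sub-millisecond fits that the
Monte-Carlo validation depends on), with two-sided Wald tests.

**Stratification.** SNP × cell scans over sex × generation cells, plus
birth-cohort strata split at the median age at DNA collection (40 years in
the youngest generation, 60 in the middle one), with significant
(p ≤ 0.05) / suggestive (0.05 < p ≤ 0.1) classes, and exam-level age
matching for cross-generation comparisons.

**Heterogeneity.** Cochran's Q, I² = 100·max(0, (Q − df)/Q), and
inverse-variance pooling; per SNP, an exhaustive S/W bipartition of the
cells into a homogeneous subsample supporting a reference (meta-analytic)
effect and the weak-support complement, maximising between-group I².

**Power.** The additive variance explained v = 2·MAF·(1−MAF)·β² gives the
minimal unrelated-sample size N = ⌈(z₁₋α/₂ + z_power)²·σ²/v⌉ at nominal
(α = 0.05) and genome-wide (5×10⁻⁸) significance, with σ = 38 mg/dL as the
population TC standard deviation.

**Enrichment.** Observed significant-test counts against the n·α chance
expectation: fold excess plus exact binomial and normal tail tests.

## Worked example

Sample size to detect the published rs2479409 effect on TC
(β = 1.96 mg/dL per minor allele, MAF 0.34):

```sh
$ demostrat power --beta 1.96 --maf 0.34 --sd 38 --gw
N(alpha=0.05) = 6574
N(alpha=5e-08) = 33168
```

About 6.6 k unrelated individuals reach nominal significance at 80% power,
and genome-wide significance needs ~5× as many. A full synthetic run —
simulate a cohort with effects confined to the youngest generation, scan
it, partition it, and test enrichment:

```sh
$ demostrat run --config run.yaml --seed 7 --out demo_run
run complete: 60 scan tests, 16 significant (seed=7, outdir=demo_run)
```

with `run.yaml` containing `scenario: generation_clustered` and
`n_families: 120`. The bundle's `scan.tsv` shows the 16 significant flags
concentrated in the two generation-3 cells; `enrichment.tsv` reports a
5.33-fold excess over the 3 expected by chance (exact p = 2.8×10⁻⁸); and
`partition_sw.tsv` places exactly the generation-3 cells of rs2479409 in
the S-subsample with a between-subsample I² of 92% — the planted
demographic clustering, recovered end to end. Re-running with the same
seed reproduces every file byte for byte.

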