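# Methods

## Pre-WGD LOH calling

A region is called loss of heterozygosity (LOH) when its minor allele
copy number is 0. The rationale is temporal: after a whole-genome
doubling (WGD), both homologue copies of a retained allele would have to
be lost independently for the minor copy number to reach zero, which is
vanishingly unlikely; a zero minor copy number therefore marks LOH that
predates the doubling. The single `minor_cn == 0` rule uniformly covers
deletion LOH (total copy 1), copy-neutral LOH (e.g. 2+0), and LOH with
gain (3+0, 4+0), so no upstream class labels are needed.

Implementation details that matter:

* Only the 22 autosomes enter any LOH statistic; sex chromosomes are
  parsed but excluded.
* Abutting or overlapping LOH calls are merged; calling the merged
  intervals again returns them unchanged (idempotence is tested).
* The LOH genome fraction divides total LOH bp by the *total* autosomal
  genome length, not by the covered length — uncovered gaps count in the
  denominator only.
* All internal coordinates are 0-based half-open. Segment files are
  1-based inclusive on disk (ASCAT dialect); BED and cytoband files are
  already half-open. Conversion happens once, in the I/O layer.

Stratum comparisons use the two-sided Wilcoxon rank-sum test on
per-sample fractions (pooled and per cancer type with Benjamini–Hochberg
adjustment across types) and, per chromosome, a two-sided Fisher's exact
test on the has-LOH × WGD-status 2×2 table. Fisher's exact is this
package's choice for the per-chromosome contrast; significance is flagged
at 0.05 and 0.1. A WGD/nWGD proportion ratio with a zero nWGD denominator
is reported as infinite, and a chromosome with no LOH anywhere as NaN.

## Mutation timing groups

Mutations arrive labelled by an upstream timing tool as early clonal,
clonal, late clonal, or subclonal. Relative to the doubling:

| phase | WGD samples              | nWGD samples |
|-------|--------------------------|--------------|
| pre   | early_clonal + clonal    | clonal       |
| post  | late_clonal + subclonal  | subclonal    |

nWGD samples have no doubling to time against, so only clonal/subclonal
labels are meaningful there; early/late labels appearing on an nWGD
sample are ignored. `unassigned` labels never enter an analysis.

## Density ratio

Per sample and variant type, `log10((n_in/bp_in) / (n_out/bp_out))` with
`bp_in` the total autosomal LOH length and `bp_out` its complement. When
either count is zero, 0.5 is added to both counts and the value is
flagged corrected; a sample with `bp_in == 0` (or a fully-LOH genome) is
not computable. The denominators use full autosomal lengths — unsequenced
gaps are not modelled. Group contrasts are two-sided rank-sum tests on
the per-sample log ratios, BH-adjusted across cancer types when
stratified.

## Selection odds ratio

For one gene list (essential, CGC, or TSG) and one stratum, cells are
pooled over all samples: `a` = mutations in listed genes inside the
sample's own LOH, `b` = mutations in other genes inside LOH, `c`/`d` the
same outside. Intergenic mutations are excluded from every cell; a
position inside any listed gene counts as listed. `OR = (a/b)/(c/d)`,
95% CI from the log-normal approximation
`exp(ln OR ± 1.96·sqrt(1/a + 1/b + 1/c + 1/d))`; any zero cell triggers a
Haldane 0.5 added to all four cells, and the result is flagged. Per-sample
odds ratios are deliberately not computed — one pooled OR per stratum
matches how the statistic is used. A class-restricted variant contrasts
amino-acid-disrupting mutations (indels, nonsynonymous and stop-gain
SNVs) with synonymous SNVs. Comparing two strata's ORs uses a two-sided
z-test on the ln OR difference; this contrast is interpretive, since the
two pooled tables share no samples but do share the gene catalog.

## Survival screening

Each factor is dichotomized within its stratum — median split for
continuous factors with ties going to the low group, presence/absence for
chromosome 17 LOH — and fitted in a Cox proportional-hazards model
(lifelines, Efron tie handling) with cancer type (indicator contrasts),
sex, and age at diagnosis as covariates; stage is added only when
recorded for ≥ 80% of the stratum. The pre phase screens four factors
(LOH length, chr17 LOH, TSG mutations in LOH, density ratio); the post
phase the two late-mutation factors. Non-convergence, complete
separation, and event-free strata are reported as non-computable results
rather than raised. Kaplan–Meier product-limit curves accompany each fit.

Note that single-factor fits are marginal: TSG-mutation load inside LOH
is mechanically correlated with total LOH length, so a planted
LOH-length hazard leaks into the marginal TSG fit. The stratum-asymmetry
tests therefore plant only the TSG effect when checking that it is
detected in nWGD and absent in WGD samples.

## Prognostic gene screens

*LOH-length percentile screen.* Within each cancer type × stratum (and a
pooled "ALL" mode), samples at or above the 75th percentile of total LOH
length form H and those at or below the 25th form L (linear-interpolation
percentiles; membership is sensitive to the method, so it is fixed and
documented). Genes present in ≥ 1 sample's LOH among H ∪ L are scored by
`delta = n_H/|H| − n_L/|L|` — the normalization is count ÷ group size, a
proportion — and genes with delta at or above the 75th percentile of the
delta distribution are candidates (ties included; the cutoff is applied
per stratum, not globally). Each candidate's presence-in-LOH is Cox
fitted with the standard covariates; BH families are all candidates of
one cancer type × stratum × screen, and hits must satisfy p < 0.05,
FDR < 0.25, HR > 1. Gene presence uses ≥ 1 bp overlap by default (full
containment is available).

*TSG-mutation screen.* Every TSG with a phase-selected mutation inside
LOH in at least one sample of the stratum is fitted on mutated-vs-not
with the same covariates and retention thresholds.

Hits map to chromosome arms by gene start position against a cytoband
table; genes spanning the centromere are assigned to the start arm with a
warning.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes,
emitting exactly the on-disk formats the readers consume.

* **Cohort composition** — per-cancer-type WGD/nWGD counts default to the
  packaged pan-cancer frequency table (19 types, 806 WGD / 1,912 nWGD);
  a `scale` knob shrinks every stratum proportionally (small nonzero
  strata are kept at ≥ 1; zero stays zero).
* **Genome** — 22 × 10 Mb toy autosomes by default (desk-scale runtimes);
  GRCh37 lengths are packaged and selectable.
* **LOH extent** — each sample draws a target genome fraction from a Beta
  distribution: Beta(2.5, 7.5) (mean 0.25) for WGD and Beta(1.2, 10.8)
  (mean 0.10) for nWGD samples, chosen so the WGD/nWGD separation is
  strong but overlapping, as in real pan-cancer cohorts. Non-overlapping
  exponential tracts (mean 15% of a chromosome) are placed until the
  target is met exactly, choosing chromosomes by length with chromosome
  17 up-weighted ×3 in WGD samples. Two designated loci behave as
  recurrently lost regions: a prognostic (non-TSG) gene and an effect TSG
  are covered by an anchored tract with probability
  `min(1, fraction × boost)` (boost 2.5), modelling the focally recurrent
  LOH that real prognostic loci show; without this, a gene's H/L presence
  difference carries no signal and no screen could recover it.
* **Gene catalog** — 2,000 genes of 20 kb on a uniform grid; 100 TSGs
  (chr17 up-weighted ×3 to exercise the LOH–TSG correlation test), 50
  essential, 60 CGC, flags drawn independently.
* **Mutations** — Poisson placement at 2×10⁻⁶ per bp (all timing classes
  combined) split by a stratum-specific timing mixture; intensity inside
  LOH is multiplied per (stratum, phase) — defaults 2.0/2.5 (WGD
  pre/post) and 1.3/1.2 (nWGD) — and TSG bp inside LOH is further
  up-weighted by the selection factor (1.3 WGD, 2.0 nWGD), encoding
  stronger selective pressure in nWGD samples. Variant type is SNV 90% /
  indel 10%; functional classes for genic positions are nonsynonymous
  0.45, synonymous 0.30, stop-gain 0.10, other 0.15.
* **Survival** — exponential baseline hazard 1/1500 per day with
  independent exponential censoring (1/3000 per day) and administrative
  censoring at 10 years, event rate ≈ 60%. The linear predictor applies
  planted log hazard ratios to the same median-split labels the analysis
  recomputes: LOH length ln 1.8 and chr17 LOH ln 1.5 in both strata, TSG
  mutation count ln 2.0 in nWGD only, the prognostic gene's LOH presence
  ln 2.5 in both, and the effect TSG's mutated-in-LOH status ln 2.5 in
  nWGD only. `SimConfig.null()` switches every planted effect off.
* **Determinism** — one seed feeds a `SeedSequence` whose children give
  each sample two private streams (genome and survival); identical seeds
  yield byte-identical files.

What the generator does *not* emulate: mutational signatures and sequence
context, subclonal copy number, kataegis/chromothripsis, per-sample
burden heterogeneity beyond Poisson, informative censoring, and
covariate–outcome associations (age, sex, and stage are noise). Passing
tests therefore demonstrate that the statistics recover the planted
structure under the model's assumptions, not that the biological claims
hold in real cohorts.

## Numerical and testing choices

* Wilcoxon rank-sum p-values come from `scipy.stats.mannwhitneyu`, exact
  where SciPy supports it; all tests are two-sided.
* BH adjustment uses statsmodels; the test suite checks it against a
  hand-written step-up rule.
* Cox fits that fail (non-convergence, separation, |ln HR| > ~14) are
  non-computable results, never exceptions; screens skip such genes with
  a log entry.
* Calibration and recovery tests run at reduced problem sizes chosen a
  priori for statistical power: 200 replicates for null calibration
  (odds-ratio CI coverage ≥ 90%, Cox type-I ≤ 7% at α = 0.05), 50
  replicates for parameter recovery (hazard ratio and odds ratio within
  [1.6, 2.5] for planted effects of 2, prognostic-gene recovery ≥ 80%),
  and three seeded cohorts for the stratum-asymmetry checks.

## Known limitations

* The pipeline consumes WGD status, purity, ploidy, and timing labels as
  inputs; none are inferred here.
* The minor_cn = 0 rule cannot separate pre-WGD LOH from a post-WGD loss
  of both copies of one homologue (assumed negligible) and ignores
  subclonal copy number.
* The selection odds ratio has no sequence-context normalization (no
  dN/dS-style correction); gene length and mutability differences are
  absorbed into the contrast between listed and non-listed genes.
* Marginal single-factor survival fits inherit the correlation structure
  of the factors (see above); the screens make no causal claim.
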