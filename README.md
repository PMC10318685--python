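# wgdloh

Whole-genome doubling (WGD) is one of the most common macro-mutations in
cancer. Because a parental allele that is already lost (loss of
heterozygosity, LOH) is vanishingly unlikely to reach copy number zero on
*both* homologue copies after a doubling, any segment with minor allele
copy number 0 can be interpreted as LOH that predates the WGD event. This
package builds a complete, testable analysis pipeline around that
observation for tumour cohorts with allele-specific copy-number segments,
timing-annotated somatic mutations, and clinical follow-up:

* **Pre-WGD LOH calling** — a segment is LOH iff its minor copy number is
  0 (covering deletion LOH, copy-neutral LOH, and LOH with gain with one
  rule); per-sample profiles report total LOH length, autosomal genome
  fraction, and per-chromosome flags, compared between WGD and non-WGD
  (nWGD) strata by Wilcoxon rank-sum and per-chromosome Fisher tests.
* **Timing-stratified mutation statistics** — mutations labelled
  early clonal / clonal / late clonal / subclonal by an upstream timing
  tool are grouped relative to the doubling (pre phase: early clonal +
  clonal in WGD samples, clonal in nWGD; post phase: late clonal +
  subclonal in WGD, subclonal in nWGD). Two statistics follow:
  the per-sample density contrast
  `log10((n_in/bp_in) / (n_out/bp_out))` of mutation rates inside versus
  outside LOH, and the pooled selective-pressure odds ratio on a gene
  list, `OR = (a/b)/(c/d)` with `a`/`b` the listed-gene/other genic
  mutation counts inside LOH and `c`/`d` the same outside (log-normal 95%
  CI; Haldane 0.5 correction on zero cells).
* **Survival screening** — Cox proportional-hazards fits (Efron ties;
  cancer type, sex, age as covariates; stage when sufficiently recorded)
  of four LOH-derived factors within each WGD stratum: total LOH length,
  LOH on chromosome 17, TSG mutations inside LOH, and the density ratio;
  plus Kaplan-Meier summaries.
* **Prognostic gene screens** — the LOH-length percentile screen (H/L
  groups at the 75th/25th percentiles, normalized presence difference
  n'_H − n'_L, top-25% candidates, per-gene Cox fits retained at
  p < 0.05, BH FDR < 0.25, HR > 1) and the TSG-mutation-in-LOH screen,
  with hits mapped to chromosome arms via a cytoband table.
* **Synthetic cohorts** — a seeded generator that emits every input file
  the pipeline reads, with WGD-dependent LOH extent, chromosome 17
  enrichment, in-LOH mutation enrichment by timing phase, TSG-selection
  effects, recurrently lost loci, and proportional-hazards survival tied
  to the planted factors, so every stage is testable without any data
  download.

## Worked example

```python
import wgdloh as w

cfg = w.SimConfig(
    cancer_counts={"Lung": (60, 40), "CNS": (30, 70)},
    n_genes=300, n_tsg=30, n_essential=15, n_cgc=18,
    chrom_length=1_000_000, mutation_rate=2e-5,
)
cohort = w.simulate_cohort(cfg, seed=1)
profiles = w.profiles_from_frame(cohort.segments)

frac = w.compare_loh_fraction(profiles, cohort.samples, cohort.genome_lengths)
print(frac[["cancer_type", "n_wgd", "n_nwgd", "median_wgd", "median_nwgd", "p_value"]])

sel = w.selection_table(cohort.mutations, profiles, cohort.samples,
                        cohort.genes, phase="pre")
print(sel[["stratum", "gene_list", "a", "odds_ratio", "ci_low", "ci_high"]])

factors = w.compute_factors(cohort.mutations, profiles, cohort.samples,
                            cohort.genes, cohort.genome_lengths, phase="pre")
from wgdloh.surv import results_table
res = results_table(w.run_factor_screen(factors, cohort.clinical, phase="pre"))
print(res[["factor", "stratum", "hazard_ratio", "p_value"]].round(4))
```

Output:

```
  cancer_type  n_wgd  n_nwgd  median_wgd  median_nwgd       p_value
0         ALL     90     110    0.212392     0.066579  9.175098e-21
  stratum  gene_list    a  odds_ratio    ci_low   ci_high
0     WGD  essential  136    1.030599  0.824921  1.287560
1     WGD        cgc  127    0.811546  0.650651  1.012228
2     WGD        tsg  389    1.662413  1.430257  1.932252
3    nWGD  essential   40    0.883040  0.631017  1.235720
4    nWGD        cgc   46    0.832765  0.608612  1.139472
5    nWGD        tsg  191    2.296723  1.922129  2.744320
               factor stratum  hazard_ratio  p_value
0          loh_length     WGD        2.6787   0.0003
1           chr17_loh     WGD        1.5074   0.4443
2  tsg_mutation_count     WGD        1.3844   0.1795
3       density_ratio     WGD        1.0125   0.9576
4          loh_length    nWGD        2.8082   0.0000
5           chr17_loh    nWGD        2.1101   0.0011
6  tsg_mutation_count    nWGD        3.8800   0.0000
7       density_ratio    nWGD        1.0991   0.6659
```

Reading the numbers: WGD samples carry about three times the LOH genome
fraction of nWGD samples (medians 0.21 vs 0.07, rank-sum p ≈ 9e-21). TSG
mutations are enriched inside LOH in both strata but more strongly in
nWGD samples (odds ratios 2.30 vs 1.66), while essential genes show no
selection — the generator plants exactly this structure. In the survival
screen, total LOH length is prognostic in both strata, whereas the TSG
mutation load inside LOH carries a hazard only in nWGD samples,
reproducing the intended stratum asymmetry.

The same stages are available from the shell via the `wgdloh` executable
(`simulate`, `annotate-loh`, `selection`, `survival`, `screen`), each
taking a YAML config plus `--seed` and `--out` and writing TSV tables
with a JSON run manifest.

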