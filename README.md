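# mirsites

Tools for analysing how predicted miRNA target sites are distributed across
gene classes. miRNAs repress genes through short sites in 3′UTRs; regulatory
genes (transcription factors and other noise-prone genes) tend to carry many
more distinct sites than housekeeping or structural genes. This package builds
that analysis as a reusable, tested pipeline for anyone working with
TargetScan/miRanda-style site predictions, expression compendia and genome
tracks: it constructs binary gene × miRNA interaction matrices, stratifies
genes by their distinct-miRNA counts, relates the counts to expression
variability and promoter-sequence noise proxies, overlays conservation and
repeat annotations, and traces normalized site counts across a species ladder.

## The statistics at its core

* **Distinct-miRNA count.** Sites are filtered per category by context-score
  strength (keep sites above the 50th percentile for conserved and the 75th
  for non-conserved sites), then collapsed into a binary incidence matrix:
  several sites of one miRNA in a 3′UTR count once; a site recognised by *k*
  miRNAs counts *k* times. The per-gene row sum is the statistic everything
  else is stratified on — quartile groups (Q1: counts below the 25th
  percentile; Q4: above the 75th) and 20 equal-size rank bins (vigintiles).
* **Expression variability.** For each gene, the coefficient of variation
  ϑ = σ/μ across samples (sample standard deviation); Q1-vs-Q4 distributions
  are compared with a two-sample Kolmogorov–Smirnov test.
* **Promoter noise proxies.** GC fraction and the ratio of nucleosome-favoring
  (GC, CG, GG) to disfavoring (AA, CA, AC) dinucleotides in ±1 kb of the TSS.
* **Conservation and repeats.** Length-weighted mean per-base conservation over
  3′UTR and CDS intervals (uncovered bases excluded from the denominator);
  LTR/SINE overlap flags with rank-sum comparisons of counts.
* **Cross-species trajectories.** Per species, each gene's count is normalized
  by that species' mean count; group means ordered by evolutionary distance
  rank are summarized by a Spearman trend statistic.

A fully seeded synthetic-data generator emulates every input (site tables,
expression matrix, promoter FASTA, annotations, conservation bedGraph, repeat
and miRNA-locus tracks, gene sets) with planted class structure, so the whole
pipeline can be validated end to end without downloads.

## Worked example

```sh
mirsites simulate --seed 1 --outdir demo --n-genes 300 --n-mirnas 80 \
    --n-samples 30 --n-species 5
mirsites run-all --config demo/run_config.yaml
mirsites report --config demo/run_config.yaml
```

The report (`demo/results/report.json`) collects every stage's statistics.
With the seed above the key entries are:

```
"stratify":      {"q25_threshold": 3.0, "q75_threshold": 11.0, "n_q1": 42, "n_q4": 75}
"expression":    {"ks_D": 0.9495, "mean_cv_q1": 0.363, "mean_cv_q4": 0.837,
                  "vigintile_spearman_cv": 0.949}
"promoter":      {"vigintile_spearman_gc": 0.965, "vigintile_spearman_dinuc_ratio": 0.965}
"repeats":       {"frac_ltr_sine_q1": 0.143, "frac_ltr_sine_q4": 0.60,
                  "within_q4": {"median_with": 34.0, "median_without": 32.5, "wilcoxon_p": 0.157}}
"cross_species": {"trend_q1": 1.0, "trend_q4": -1.0}
```

Reading: genes with fewer than 3 distinct miRNAs form Q1, more than 11 form
Q4. The CV distributions of the two groups separate almost completely
(KS D ≈ 0.95), vigintile-mean CV and promoter GC rise monotonically with the
vigintile-mean count (Spearman ≈ 0.95), LTR/SINE repeats are ~4× more common
in Q4 3′UTRs yet do not raise counts *within* Q4 (rank-sum p = 0.157), and
across the species ladder the Q1 group's normalized count rises with distance
while Q4's falls — the planted gain/loss asymmetry.

Every stage is also exposed as a library function (`mirsites.interaction`,
`mirsites.variability`, `mirsites.promoter`, `mirsites.tracks`,
`mirsites.species`, `mirsites.stats`, `mirsites.synthetic`) and as individual
subcommands (`build-matrix`, `stratify`, `expression-cv`, …).

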