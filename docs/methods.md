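# Methods

## Site filtering and the interaction matrix

Predicted sites arrive as tab-separated tables (TargetScan-style "context+
score" layouts, miRanda/mirSVR-style tables, or a generic dialect). Context
scores are negative, more negative meaning stronger predicted repression, so
"keep sites above the Xth percentile" is interpreted on *score strength*
(the negated score): within each category independently — 50th percentile for
conserved, 75th for non-conserved sites — a site survives iff its strength
reaches the category's threshold. The threshold is the higher-interpolation
quantile of the observed strengths (the value at 0-based sorted index
⌈(n−1)·p/100⌉), which retains exactly the strongest (100−p)% on distinct
scores; ties at the threshold are kept, so a category of identical scores is
retained whole. A `direction="raw"` switch thresholds the score as printed
instead, for conventions where larger raw values are stronger. Whether the
cut should instead be per gene is a plausible alternative reading; the filter
is genome-wide per category, which is the natural reading of a single
percentile per category.

The miRanda dialect drops rows above a configurable mirSVR cutoff (default
−0.1). There is no community constant for a "good" mirSVR score, so the
default is deliberately mild and must be set per data release.

Filtered records collapse into a binary incidence matrix: incidence[g, m] = 1
iff at least one record links gene g to miRNA m. Duplicate sites of one miRNA
in a 3′UTR therefore count once, while one physical site recognised by k
miRNAs contributes k incidences. Genes of a declared universe without any
site keep an all-zero row and take part in all downstream stratification.
Readers are lossless; de-duplication happens only here.

## Stratification

Quartile thresholds are classic nearest-rank percentiles (value at 1-based
rank ⌈p/100·n⌉) of the distinct-miRNA counts; Q1/Q4 membership uses strict
inequalities (counts strictly below the 25th / above the 75th percentile),
so a constant count distribution yields two empty groups (with a warning)
rather than arbitrary halves. Note the two percentile conventions differ by
design: the site filter's higher-interpolation quantile retains exact
fractions; the quartile cut reproduces the "less than / more than" group
definitions.

Vigintiles sort genes by (count, gene id) and split them into 20 contiguous
bins whose sizes differ by at most one (earlier bins take the remainder);
the lexicographic tie-break makes assignments identical across runs. Bin
summaries are arithmetic means; genes missing a value are dropped from that
bin's mean with a logged count, never imputed.

## Expression variability

ϑ = σ/μ per gene across samples, with the sample (n−1) standard deviation —
the unbiased-variance convention appropriate for panels of hundreds of
arrays. Expression is consumed on the scale provided; because public
intensity compendia do not always state their scale, a `log2` pre-transform
(log2(x+1)) is available but off by default. Genes with non-positive mean are
an error, not silently skipped. Q1-vs-Q4 CV distributions are compared with
the two-sample KS test described below.

## Promoter noise proxies

The promoter window is [TSS−1000, TSS+1000), clipped to the chromosome.
Sequences are taken on the gene's annotated strand (minus-strand windows
reverse-complemented) before counting, since the promoter of a gene is read
on its sense strand; a `strand_mode="plus"` switch keeps the reference
strand, as the two conventions are both defensible. GC content is
(G+C)/(A+C+G+T) with N excluded from both numerator and denominator.
Dinucleotides are counted over all overlapping length-2 windows ("GGG"
contains GG twice — the standard k-mer convention); windows containing N are
skipped. The noise proxy is the ratio of favoring (GC, CG, GG) to disfavoring
(AA, CA, AC) counts; a zero disfavoring count flags the ratio undefined and
excludes the gene from ratio aggregations (logged). These sequence features
stand in for nucleosome occupancy; no trained positioning model is involved.

## Conservation, repeats, length, co-localization

Mean conservation over a gene's 3′UTR or CDS intervals is length-weighted
over the intersection with the track's covered bases; uncovered bases are
excluded from the denominator because conservation tables only cover aligned
bases — treating them as zero would conflate alignability with constraint.
Zero covered bases flag the mean undefined. CDS conservation is aggregated
gene-level (one length-weighted mean over all CDS intervals).

A gene is repeat-flagged iff ≥1 bp of an LTR or SINE element (classes
configurable) intersects its 3′UTR under half-open-interval arithmetic, so
an element abutting the UTR does not count. Count medians for flagged vs
unflagged genes, optionally restricted to a quartile group, are compared
with the rank-sum test.

Co-localization pairs a miRNA locus with a gene iff the locus intersects
[span_start − w, span_end + w) on the same chromosome, with w = 20 kb by
default. The window extends the *full transcript span* (introns included),
not the TSS, because the biological motivation is miRNAs residing in or near
intronic regions; the half-open extended interval makes a locus starting
exactly w bases upstream count as co-localized.

## Cross-species trajectories

Species carry different numbers of annotated miRNAs, so counts are
normalized per species by the mean count over all genes with an orthologous
3′UTR there (not only genes with ≥1 site — the mean of a species' full count
distribution; a `nonzero_only` switch provides the alternative). The
per-species mean of normalized counts is exactly 1. Quartile groups are fixed
on the reference species and propagated through the ortholog map; members
without an ortholog are dropped from that species' mean with a logged count.
Evolutionary distances enter only as ranks, and the trend of a group's mean
normalized count over the ladder is its Spearman correlation with the rank
(+1 = monotone increase with distance). The score-percentile filter is
re-applied per species rather than reusing reference thresholds, since each
species' score distribution is its own.

## Statistical tests

* **Hypergeometric enrichment/depletion**: P(X ≥ x) or P(X ≤ x) computed in
  log space, so p-values far below PMF underflow (overlaps of hundreds of
  genes) remain finite. The universe is an explicit required argument — no
  implicit default exists, because enrichment answers depend on it.
* **Wilcoxon rank-sum**: midranks for ties. For pooled sizes n+m ≤ 16 the
  full permutation distribution of the rank sum is enumerated (C(16,8) =
  12 870 assignments, sub-second), which stays exact under ties; beyond that,
  a normal approximation with tie-corrected variance and 0.5 continuity
  correction. Two constant equal samples return p = 1 with a degenerate flag.
* **Two-sample KS**: D is the sup-distance of the pooled ECDFs computed
  in-package; the p-value uses the exact null distribution when n·m ≤ 10 000
  (the convention R's `ks.test` follows) and the asymptotic Kolmogorov
  distribution beyond. The default keeps small-sample rejection rates
  calibrated (asymptotic-only KS is conservative at moderate n); an
  `asymptotic` method switch forces the limit formula.
* **Spearman**: Pearson correlation of midranks; constant vectors flag the
  statistic undefined rather than returning 0.
* All p-values are reported raw. A Benjamini–Hochberg helper exists but is
  not applied anywhere by default, matching an analysis style that quotes
  individual test p-values.

## Synthetic data: what is planted and what is not

One latent noise level per gene drives everything that should co-vary:
noise_g ~ U(0.05, 0.45) for non-regulatory and U(0.55, 0.95) for regulatory
genes (a deterministic 25% of genes by default). From it:

* **site rate**: Poisson mean rate_class · (1 + site_noise_slope·(noise_g −
  0.5)), with rate_reg = 55 and rate_nonreg = 12 pre-filter — chosen so the
  post-filter count distribution separates the classes about as sharply as
  quartile cut-offs in the mid-teens and mid-fifties imply. The within-class
  slope matters: with class-level rates alone, the 15 non-regulatory
  vigintiles would share one mean CV/GC and vigintile-level correlations
  would be dominated by sampling noise rather than the planted relation.
* **promoter GC**: per-base probability 0.4 + 0.3·noise_g over 2 kb windows.
* **expression**: log-normal with σ_g = 0.2 + 0.8·noise_g on the log scale
  (CVs roughly 0.25–1.3), 100 samples by default.
* **conservation**: segment scores ~ N(mean_class, 0.08) clipped to [0, 1],
  with UTR means 0.8 (regulatory) vs 0.4 and CDS means 0.5 vs 0.8 — the CDS
  contrast deliberately inverted relative to the UTR contrast.
* **repeats**: one LTR/SINE element per 3′UTR with probability 0.6
  (regulatory) vs 0.17, plus LINE decoys that must not flag.
* **cross-species**: the reference is the *derived* state of a
  selective-inclusion history. A species at distance rank d keeps each
  regulatory-gene site with probability exp(−loss_rate·d) (loss_rate = 0.12:
  sites the reference lineage gained are absent deep in the ladder) and adds
  Poisson(gain_rate·d) distinct miRNAs to each non-regulatory gene
  (gain_rate = 0.15: ancestral sites the reference lineage shed). This
  orientation is what makes the low-count group's normalized mean *rise*
  with distance and the high-count group's fall; the opposite orientation
  (distant species losing non-regulatory sites) provably reverses both
  trends. Species diverge independently from the reference (star topology).

The `null()` configuration zeroes every coupling — equal site rates, zero
site/GC/CV slopes, equal conservation and repeat probabilities, no
gain/loss — and is used to verify the pipeline manufactures no signal on
structureless data.

What the generator does **not** emulate: sites are abstract (gene, miRNA)
records without seed-match sequences; genes have a single CDS and 3′UTR
interval and no introns or alternative isoforms; expression has no batch or
platform structure; species share one identity ortholog map. Passing tests
therefore demonstrate that the *pipeline machinery* recovers planted
relationships of realistic magnitude and produces none on null data — they
say nothing about prediction quality of any site-calling algorithm on real
genomes.

## Numerical and degenerate-input choices

Coordinates are 0-based half-open everywhere internally; 1-based formats
(GTF-like annotations, TargetScan UTR positions) convert at the parse
boundary, and minus-strand TSSs are the rightmost transcript base. Interval
lists are normalized (sorted, overlaps merged) on construction. Unsorted
score tracks are sorted with a logged notice; overlapping track intervals are
an error. Quartile stratification requires ≥ 8 genes, vigintiles ≥ 20, CVs
≥ 2 samples, trend statistics ≥ 3 species points. Generators derive one RNG
stream per component from (seed, stream-id), so any output is byte-identical
across runs with the same configuration, and the pipeline report is
byte-identical across reruns on identical inputs.

## Validation problem sizes

The stochastic validation studies run the full generator-to-trend analysis
at 2000 genes × 300 miRNAs × 100 samples × 10 species over 20 seeds (and 20
null seeds), sizes at which every planted effect is comfortably detectable
while a complete study takes a few seconds per seed; test calibration uses
5000 null replicates at n = m = 30.
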