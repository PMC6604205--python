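# Methods

`pdxsoma` implements the post-alignment computational stages of a genomic
characterization pipeline for patient-derived xenografts (PDXs): tumors
engrafted in immunodeficient mice, sequenced as a mixture of human tumor
(graft) and mouse stroma (host) molecules, and — critically — without a
patient-matched normal sample to subtract germline variation. This note
describes the models and procedures, the parameters that matter, what the
synthetic data emulate (and do not), and the design choices made where the
procedure was genuinely open.

## Read preprocessing and host/graft separation (`hostsep`)

Reads are first quality-screened: a read is discarded when at least 70% of
its bases fall below Q30; otherwise the maximal trailing run of sub-Q30
bases is trimmed from the 3' end, and the read is discarded if fewer than
70% of its original bases survive. A pair is discarded when either mate is.
Two boundary readings are deliberate and configurable: the bad-base rule is
inclusive at exactly 70%, while the surviving-length rule discards strictly
below 70%; the first check counts pre-trimming bases. Trimming removes only
the trailing low-quality run, never internal bases — the most literal
reading of 3'-end trimming. A sample is dropped when fewer than 50% of its
reads survive preprocessing (strictly-less-than), and later when less than
75% of the target region is covered at >= 100X by human reads.

Host/graft classification re-implements the k-mer partition idea behind
xenograft read-deconvolution tools. All canonical k-mers (lexicographic
minimum of a k-mer and its reverse complement, so classification is
strand-agnostic) of the two references are partitioned into three disjoint
sets — graft-only, host-only, shared — and each read is classified from the
partitions its k-mers hit: graft-only hits without host-only hits -> human;
the converse -> mouse; shared hits only -> both; graft-only and host-only
together -> ambiguous; no hits (including reads shorter than k) -> neither.
This five-way rule is a simplification of the marginal/ambiguous semantics
of succinct-data-structure tools; category names are kept. The default
k = 25 matches common practice; smaller k increases sensitivity to the host
at the cost of specificity. Only pairs with *both* mates classified human
are retained — a "both"-classified mate drops the pair. The fraction of
mouse-classified reads is reported as a per-sample contamination statistic.

The implementation stores plain Python sets of canonical k-mer strings.
This is deliberate: at the package's intended scale (targeted panels,
simulated references) an exact, transparent structure beats a compressed
index, and the classifier is oracle-testable against brute-force set
membership.

## Tumor-only somatic filtering (`somatic`)

Variant tables (GATK-style SNVs/indels plus Pindel indels) pass through
four ordered stages, each recorded in a per-variant audit trace.

1. **Quality.** Hard filters (SNVs: QD < 2.0, FS > 60.0, MQ < 40.0,
   MQRankSum < -12.5, ReadPosRankSum < -8.0; indels: QD < 2.0, FS > 200.0,
   ReadPosRankSum < -20.0), then depth DP >= 140 and allele fraction
   ALT_AF >= 5% (both inclusive; tuned for high-coverage targeted panels).
   Missing annotations never fail a filter, matching GATK filter-expression
   semantics for, e.g., rank-sum statistics at homozygous sites.
2. **Germline.** An aggregated resource of putative germline variants —
   public databases (dbSNP, 1000 Genomes, ExAC restricted to population
   MAF >= 1%) plus a compendium from normal samples sequenced on the same
   panel, admitting a variant seen in >= 2 of 20 normals, or in >= 1 normal
   and >= 2 tumor-cohort samples (absolute counts, defined for a
   20-normal compendium; proportional rescaling is opt-in). A call is
   flagged germline when present in the resource at allele fraction in the
   closed window [0.40, 0.60] (heterozygous) or strictly above 0.90
   (homozygous). Matching is at full allele resolution (chrom, pos, ref,
   alt). The AF windows make the filter conservative: germline variants
   displaced by copy-number imbalance are intentionally not filtered.
3. **Recurrent false positives.** Positions (chrom, pos resolution) carrying
   a non-germline-flagged variant in >= 25% of cohort samples are treated as
   systematic sequencing/alignment artifacts — in large tumor compendia the
   maximum recurrence of genuinely somatic positions is far lower (~6%).
   Recurrence is computed after quality filtering, excluding
   germline-flagged occurrences from the numerator, with the full cohort
   size as denominator. A position must additionally recur in at least 2
   samples: in a very small cohort any private variant trivially exceeds
   the fraction threshold (at cohort size 1, every variant "recurs" at
   100%), and a single carrier is not recurrence. At realistic cohort sizes
   the extra condition is vacuous.
4. **Clinical rescue.** Quality-passing variants filtered as germline or
   recurrent-FP are reinstated when curated in a clinical knowledgebase
   (matched by genomic key or by gene + protein change) — many actionable
   hotspots sit in dbSNP at germline-like allele fractions and would
   otherwise be lost. Pindel calls are retained *only* on a knowledgebase
   hit, regardless of other flags, reflecting that caller's false-positive
   burden. Hard-filter failures are never rescued (a flag exposes the permissive
   alternative). A clean Pindel call
   without a knowledgebase hit has no bucket in a five-status scheme, so
   the trace carries a sixth final status, `filtered_pindel_no_kb`, keeping
   the status partition exact.

Every variant ends in exactly one final status; statuses are independent of
input row order; rescued variants are always a subset of
(germline-flagged ∪ FP-flagged ∪ Pindel-called).

## Gene-level copy number and LOH (`cna`)

Inputs are allele-specific segments (major/minor copy number, possibly
fractional, accepted unrounded) with a per-sample mean cancer-genome
ploidy, as produced by single-tumor allele-specific segmentation. A segment
is LOH when nMajor >= 0.5 and nMinor <= 0.1. Genes are intersected with
segments (1-based inclusive internally; BED converted at I/O); a gene
crossing a boundary takes the *minimum* total CN of its overlapping
segments (the conservative estimate for the intact gene) and is LOH when
any overlapping segment is — a gene-level convention the segment-level
definition does not fix; the any-segment choice is the sensitive one.
Genes overlapping no segment get missing CN.

Gain/loss calls use r = log2(CN / baseline) with baseline either the
sample's ploidy (preferred: aneuploid genomes make the diploid baseline
systematically call gains) or the diploid state 2: high_gain (r > +1),
gain (+0.4 < r <= +1), normal (|r| <= 0.4), loss (-1 <= r < -0.4),
high_loss (r < -1). CN = 0 maps to high_loss without evaluating log2(0).
Boundary assignment is fixed as: normal includes +-0.4 exactly, high
states are strict beyond +-1. Under the ploidy baseline, calls are invariant
to rescaling all CNs and the ploidy by a common factor — the property that
makes the ploidy baseline robust to segmentation-scale uncertainty.

CN–expression concordance classes samples by log2(CN/ploidy) into
high-level loss (< -1), normal (|r| <= 1) and high-level gain (> +1); each
sample's fold change is log2(TPM+1) minus the mean over *stringently*
normal samples (|r| <= 0.4); gain and loss classes are compared with the
normal class by a two-sided equal-variance t-test. Classes with fewer than
two samples are untestable; a degenerate zero pooled variance with equal
means yields t = 0, p = 1.

## Expression normalization and the EBV-lymphoma classifier (`expression`)

Samples need >= 1,000,000 human reads (inclusive) for quantification.
Counts are upper-quantile normalized: each sample's values are divided by
the 75th percentile (linear interpolation) of its *non-zero* counts and
scaled to 1000, so afterwards every sample's non-zero upper quartile equals
1000 and zeros stay zero. Per-gene z-scores are computed across all
samples with the sample standard deviation (n-1; configurable); zero-sd
genes get z = 0.

The lymphoma signature is derived from a labelled cohort: genes below an
expression floor (mean normalized count > 1) are removed, genes are ranked by the difference of group mean
z-scores (a "fold change" of signed z-values is ill-defined, so the
group-mean difference is the ranking statistic; a raw fold-change
alternative is available by ranking on unsigned normalized values), and the top 24 and bottom 24 genes form the signed
signature. A sample's score is the raw *sum* (not mean) of sign-corrected
signature z-scores, and scores strictly above 3.0 flag putative
EBV-transformed lymphomas — threshold configurable; over
48 terms a sum-based threshold of 3.0 is aggressive, which suits a QC
screen where false flags are cheap and misses are not.

`EBVSignatureClassifier` wraps derivation and scoring as an sklearn-style
estimator (fit/decision_function/predict, get_params/set_params, fitted
attributes with trailing underscores), storing training-cohort gene means
and standard deviations so held-out samples are scored against the
training distribution.

## Benchmarking and cohort statistics (`cohort`)

Benchmarks score predictions against a truth set at (chrom, pos, alt)
resolution over an explicit assessable-locus universe (a
true-negative count is meaningless without one, so it must be supplied, and in synthetic runs it is all planted plus all predicted loci).
Precision and recall default to 0 on empty denominators;
F1 = 2·(recall·precision)/(recall+precision). Allele-fraction recovery is
the Pearson correlation of predicted vs true AF over true positives only
(missing below 2 TPs). Mutational load counts emitted (passing or rescued)
non-silent coding mutations in panel genes.

Gene-set overlap between cohorts uses the one-sided (enrichment) Fisher
exact test over a 2x2 table on the panel universe — direction unstated in
the source; enrichment is the scientifically meaningful side — which equals
the hypergeometric upper tail; both are exposed and oracle-tested against
exhaustive enumeration. Over/under-expression frequencies are the fractions
of samples with z > +1 / z < -1 (strict), compared across cohorts by
Pearson correlation (undefined on zero-variance vectors, reported missing).
The "most varying genes" ranking deserves a note: the variance of z-scores
standardized on the same samples is identically 1 for every gene, so
variation is only meaningful *between* cohorts; given a cohort grouping the
ranking statistic is the variance of per-cohort mean z-scores, otherwise
plain across-sample variance (appropriate when z was standardized on an
external reference). Variance ties break lexicographically by gene id.

## Synthetic data (`simulate`)

Generators are deterministic in the seed; each draws from its own RNG
stream (seed plus a fixed per-generator offset) so one call never perturbs
another. Defaults are fixed study conditions, not tuning knobs:

- **References:** random graft sequence (default 10 kb); host derived by
  i.i.d. substitutions at divergence 0.15 (mouse/human protein-coding
  identity is ~85%).
- **Reads:** pair count = coverage × length / (2 × read length); coverage
  grid {500, 1000, 1500} (default 1000); host contamination
  {0.10, 0.15, 0.25} of total coverage (default 0.15); 150 bp paired-end;
  base errors i.i.d. at 1e-3; a 5% fraction of reads receives a Q2 3' tail
  so preprocessing is exercisable; all other bases Q37.
- **Variant cohorts:** cohort-shared germline loci (entered into the
  synthetic germline resource, carried per sample at p = 0.5 with true AF
  in {0.5, 1.0} for heterozygous/homozygous states), private somatic loci
  with true AF uniform in [0.05, 1.0], and artifact loci planted in
  ceil(0.30 × n) of 20 samples at mid-range AF (0.15–0.35) and absent from
  the resource. Observed AF is binomially resampled at Poisson depth around
  the target coverage; zero resampled alternate reads means the locus is
  not called (a reachable false negative). Quality annotations come from a
  clean regime inside the hard-filter pass region, or a failing regime
  (one annotation pushed past its cut) for a configurable fraction.
- **Expression cohorts:** negative-binomial counts (size 10) around
  per-gene lognormal means with lognormal library-size variation; 24 genes
  shifted up and 24 down by log2 effect 2 in the EBV group (default 20 EBV
  vs 100 non-EBV).
- **CN profiles:** segments tile each chromosome without gaps or overlaps;
  total CN per segment spans 0–6 with a mode at 2; ploidy is the
  length-weighted mean total CN. Coupled mode ties log2(TPM+1) to
  per-gene baseline + log2(CN/ploidy) + Gaussian noise and draws no
  zero-copy segments.

What the synthetic data do *not* emulate: alignment artifacts, indel
sequencing errors and quality-by-cycle structure, PCR duplicates,
structural variants, tumor purity and subclonal architecture, and the
correlated error processes that generate real recurrent artifacts. Passing
tests therefore demonstrate that the filtering logic is correct under its
stated statistical model — binomial AF sampling, genuinely recurrent
artifacts, planted signatures — not that the thresholds are optimal for
any particular real platform.

## Problem sizes and numerical choices

The test suite and the acceptance script run at desk scale by the
package's own choice of problem sizes: 10 kb references, 20-sample variant
cohorts, a 120-sample × 2000-gene expression cohort, ~200 spiked variants
per benchmark sample. The allele-fraction recovery benchmark uses one
sample at depth 500 with ~200 spiked variants over AF 0.05–1.0 and reports
the minimum Pearson r over three seeds; binomial AF noise at depth 500
bounds attainable r near 0.998, against an acceptance floor of 0.99.
Percentiles use linear interpolation; stable mergesort after a
lexicographic pre-sort makes every ranking tie-break deterministic;
floating comparisons in calls use exact threshold arithmetic on log2
ratios rather than tolerance bands.

## Known limitations

- The k-mer index is exact and in-memory; whole-genome references would
  need a succinct structure out of scope here.
- Germline filtering is database-driven; true somatic variants at
  germline-like AF inside database sites are recoverable only through the
  clinical-rescue path.
- The recurrence filter assumes cohort samples are independent models;
  related samples (same patient, passages) would inflate recurrence.
- Multi-allelic records must be decomposed to one alt per record before
  filtering; the VCF reader enforces this.
- The expression classifier is transductive in its primary form
  (z-scores across the scored cohort); the estimator wrapper adds an
  inductive mode but inherits the training cohort's composition as its
  reference distribution.
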