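# Methods

## Overview

`mosaicbench` implements the statistical machinery used to construct a
benchmark of low-allele-fraction (mosaic) SNVs in a well-characterized
cell-line sample, together with the simulation tools needed to validate
that machinery end-to-end without any sequencing data. The pipeline
mirrors a trio-based discovery design: a somatic caller run with the
child as "tumor" and the combined parents as "normal" produces a large
stream of candidate low-fraction variants, which is then filtered by
read support from several orthogonal sequencing technologies, classified
by a decision tree built on one-sided binomial confidence bounds, and
turned into a paired benchmark VCF (confident mosaic SNVs) and BED
(regions in which the sample is confidently homozygous-reference or a
benchmark variant).

## Candidate filtering and the read-support database

Caller output is filtered in two stages. First, records flagged as
detected in the normal sample (`VARIANT_DETECTED_IN_NORMAL`) are
removed, and records are kept only when the tumor allele read count
(TAR) is strictly greater than `min_tar` (default 5). Non-PASS records
are otherwise retained: in-silico mixture experiments show that caller
filters remove a substantial fraction of true low-fraction variants, so
discarding them at this stage would inflate false negatives. Second,
known germline alleles are removed by exact (chrom, pos, ref, alt)
matching — the genotype-blind ("squash-ploidy") comparison, which is
exact for SNVs — and records inside complex/structural-variant
exclusion regions are dropped.

Per-technology allele support is counted from pileup rows after base
quality < 25 and mapping quality < 40 reads are excluded. A technology
supports a candidate when it contributes at least `min_alt_support`
(default 2) alternate reads after filtering; lower counts are recorded
but flagged non-supporting. Context flags (easy-to-map, homopolymer,
tandem repeat, germline-indel overlap) are set by interval membership
against stratification BEDs; "easy-to-map" is defined as *not*
overlapping the configured low-mappability stratum. Candidate indels are
carried through filtering but dropped, with a logged count, at database
assembly: the classification and benchmark are SNV-only.

The TAR field is treated as a single supplied integer; when a
Strelka-style tiered count `(tier1, tier2)` is present in a sample
field, tier 1 is used.

## Binomial confidence bounds

All decisions rest on one-sided bounds for the variant allele fraction
from quality-filtered counts (x alt reads out of n). The interval family
is the Wilson score interval without continuity correction (the default
of the R `binconf` routine); exact Clopper–Pearson bounds are available
as a configuration alternative for sensitivity analysis. A one-sided
coefficient L is realized as the corresponding bound of the two-sided
interval at level 2L − 1 (z is the normal quantile at L):

    (p̂ + z²/2n ± z·sqrt(p̂(1−p̂)/n + z²/4n²)) / (1 + z²/n)

Per-technology bounds use L = 0.95; the pooled ("combined") bound uses
L = 0.99 on x_ci/n_ci, the plain sums of alternate counts and depths
over the included technologies. Pooling deliberately ignores
between-technology heterogeneity, matching the definition of x_ci/n_ci.
By default the pool includes **all** technologies present, including the
high-coverage short-read discovery data (the released benchmark reports
VAFs combined across all technologies); the inclusion set is
configurable (`HeuristicsConfig.combined_include`). The two long-read
instrument datasets are pooled into a single `pacbio` technology.

Numerical notes: bounds are clamped to [0, 1] and to bracket the point
estimate (float rounding can otherwise violate `lower ≤ x/n ≤ upper` by
one ulp); x = 0 forces the lower bound to 0 exactly and x = n the upper
bound to 1 exactly.

Coverage: tests verify by simulation (10,000 replicates) that each
one-sided bound errs at most (1 − L) + 0.02 of the time in the regime
the pipeline consults it: the 99% bounds across p ∈ {0.02, 0.05, 0.1}
and n ∈ {50, 300}, the 95% lower bound for p ≥ 0.05, and the 95% upper
bound near p = 0.02. A known limitation of the score interval is that
its one-sided 95% **lower** bound under-covers at small np (exact
coverage ≈ 0.92 at p = 0.02, n ∈ {50, 300}); the pipeline never uses
that bound in that regime — near-absent sites are screened by the upper
bound — but users re-purposing `wilson_interval` should be aware of it.

## The decision tree

Candidates are classified in a fixed rule order; the first terminal rule
wins and every consulted rule is recorded in a trace:

1. **Near-absent screen.** Pooled upper bound ≤ `upper_ci_floor` (0.03)
   → `EXCLUDE_KEEP_REGION`: the site is confidently close to
   homozygous-reference and remains benchmark territory. This branch
   keeps the region as a whole; region removals are reserved for
   indeterminate sites (see below). The companion constant
   `region_absent_max` (0.02) expresses the region-level claim — "no
   mosaic ≥ 2% here" — and is used when adjudicating curated
   indeterminate sites.
2. **Coverage screen.** Pooled depth n_ci or long-read depth below the
   empirical `coverage_quantile` (0.5%) of the database →
   `EXCLUDE_REMOVE_REGION` (config switch `low_coverage_removes_region`
   retains the region instead). The quantile is the type-1
   (inverse-CDF) order statistic — the ceil(q·n)-th sorted value — since
   no interpolation rule is canonical; at q = 0 it degenerates to the
   minimum and nothing is filtered.
3. **Germline-indel overlap** → `EXCLUDE_REMOVE_REGION` (local alignment
   around indels makes the VAF untrustworthy).
4. **Germline-like fraction.** Pooled x/n > 0.5 →
   `EXCLUDE_REMOVE_REGION`; exactly 0.5 is retained.
5. **Mappability partition.** Easy-to-map candidates are forwarded to
   curation (`CURATE`) when the pooled 99% lower bound is ≥
   `lower_ci_include` (0.05), otherwise their VAF is indeterminate and
   the site is removed from regions. Hard-to-map homopolymer candidates
   are removed outright; other hard-to-map candidates are judged by the
   long-read 95% lower bound against the same 0.05 threshold, since
   short-read support in low-mappability context is unreliable.

Boundary semantics are exact and tested: upper bound equal to 0.03 is
excluded, lower bound equal to 0.05 passes, x/n equal to 0.5 is
retained. Candidates whose pooled fraction exceeds `vaf_target_max`
(0.30, the top of the targeted mosaic band) but not 0.5 get a warning in
the trace and still go to curation rather than being auto-included —
the germline benchmark covers ≥ 30% VAF and curation decides the edge.

Manual-curation labels (`include` / `exclude_keep_region` /
`exclude_remove_region`) resolve the `CURATE` set; labels are only
accepted for curated keys and every curated key must be labeled.
Post-release single-site removals (e.g. a true mosaic coinciding with a
parental germline variant) are appended to the region-removal list and
excised with flanks.

## Benchmark regions

All interval arithmetic is 0-based half-open; 1-based variant positions
are converted exactly once at the boundary. Region sets are kept
canonical (sorted, disjoint, with bookended intervals merged) so base
totals are representation-independent. Construction: intersect the
three per-sample callable-region sets, subtract each repeat stratum
wholesale (the repeat context, not just the variant locus, is
unreliable), subtract flanked indeterminate-VAF sites (the variant base
± 50 bp, 101 bp per site), and finally drop fragments shorter than
`min_region_bp` = 50 (strict `<`; the length filter runs last because
subtraction fragments intervals). Non-autosomal chromosomes are dropped
with a logged count. Gene-level summaries report per-gene covered bases
and the count of genes covered at ≥ 90%.

## In-silico mixture limit of detection

Mixing a fraction f of a carrier sample into a non-carrier background
yields expected allele fraction f/2 at carrier-unique heterozygous
sites. The simulator draws alternate counts binomially at
`af·(1−e) + (1−af)·e/3` over the ladder f ∈ {1, 0.5, 0.2, 0.1, 0.02, 0}
(AFs 50/25/10/5/1/0%), default depth 300. The detector is deliberately
transparent — detect when alt ≥ `min_alt` (3) and the exact binomial
tail probability under the error rate is < `alpha` (1e-4) — so its
acceptance region is an upper tail whose detection probability has a
closed form; simulated recall is tested against that closed form to
3 standard errors. Recall is effectively 1 down to 5% AF at depth 300
and collapses near 1% AF, which motivates the 5% VAF inclusion floor
consumed by the decision tree. Reproducing a specific caller's recall
numbers is out of scope: the real experiment depends on 300x read data
and the caller's internals.

## Callset comparison and batch effects

The comparator is an SNV-exact analog of haplotype-aware benchmarking
tools: allele-exact matching ignoring genotype and VAF, query calls
outside the benchmark regions ignored, an optional germline-union set
suppressing known-germline false positives, and VAF-stratified counts
when VAF fields are available. Representation differences around
indels are not normalized; upstream complex-variant exclusion makes
this a minor limitation for SNVs.

Batch comparison pairs per-variant quality-filtered counts from two DNA
batches: Fisher's exact test per site on the alt/ref 2×2 table, and a
global paired Wilcoxon signed-rank test on per-variant VAF differences
(p = 1 by convention when all differences vanish; direction is the sign
of the median difference). The global test is a design choice — the
underlying study reports significance without naming a procedure — and
is paired and distribution-free. Calibration is verified on simulated
equal-VAF batches at heterozygous fraction and depth 300, where the
Fisher rejection rate at α = 0.05 is ≈ 0.047; at mosaic-range VAFs the
exact test is conservative (rejection rate ≈ 0.038 at depth 300), a
known property of conditional exact tests on sparse tables.

## Synthetic data generator

The generator emulates the *statistical* structure of the candidate
database: a mixture of true-VAF classes (defaults: 95% artifact at
~0.2% VAF, 3% mosaic uniform on 1–30%, 2% germline-like at 50% —
dominance of near-zero artifacts matches a caller's unfiltered somatic
candidate stream); per-technology depths from a truncated
negative-binomial (means 300/100/136/106x for the four default
technologies, dispersion 30 — overdispersion makes the coverage
quantile filter meaningful); per-read substitution errors split evenly
over the three non-reference bases (rates 0.1% short-read, 0.05%
high-accuracy short-read, 0.2% long-read); context flags drawn
independently per configured proportions; and a configurable
germline-indel overlap probability. Each candidate carries a truth
record whose expected decision-tree outcome is computed *analytically*
from the true VAF and flags (the infinite-depth limit of the rules, in
rule order), never by running the tree — keeping recovery tests
non-circular. Realization-dependent coverage-quantile outcomes are
excluded from the analytic expectation.

What the generator does not model: context-dependent or correlated
sequencing errors, mapping artifacts in segmental duplications,
copy-number structure, strand bias, and read-level alignment. Passing
recovery tests therefore demonstrate the correctness and calibration of
the statistical machinery under its stated error model, not performance
on real reads.

Problem sizes used by the test suite and the acceptance script (4,000–
10,000 variants, 5,000 mixture sites per AF, 10 kb toy chromosomes for
brute-force oracles, 1,000 randomized algebra cases) are chosen so
every stochastic assertion has at least 3-standard-error slack while a
full run completes in well under a minute per module on one core.

## Known limitations

- Germline matching and callset comparison are allele-exact; indel
  representation differences are out of scope.
- The 95% one-sided Wilson lower bound under-covers at small np (see
  above).
- Fisher's exact test is conservative at mosaic-range VAFs and moderate
  depth; the global signed-rank test is unaffected.
- The decision tree consumes curation labels; it does not model the
  judgment behind them.
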