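# mosaicbench

Tools for constructing and evaluating benchmarks of **mosaic SNVs** —
variants present in only a fraction of cells, at variant allele
fractions (VAFs) far below the 50%/100% of germline calls. Such
benchmarks pair a VCF of confident mosaic variants with a BED of
regions in which the sample is confidently homozygous-reference or a
benchmark variant, so that somatic/mosaic variant callers can be scored
for both false negatives and false positives.

The package is aimed at people building or stress-testing such
benchmarks: it implements the full statistical pipeline of a trio-based
mosaic benchmark construction — and a synthetic-data generator with
known ground truth so every stage can be validated on a desk.

## What it computes

Given a somatic callset (child as "tumor", combined parents as
"normal") and per-technology quality-filtered read counts, the pipeline:

1. **Filters caller output** — drops variants detected in the normal
   sample, keeps tumor allele read count (TAR) > 5, removes known
   germline alleles by allele-exact matching and sites in complex/SV
   regions (`read_support`).
2. **Assembles a candidate database** — one row per (variant,
   technology) with quality-filtered ref/alt counts (base quality ≥ 25,
   mapping quality ≥ 40; ≥ 2 alt reads for a technology to count as
   supporting) plus genomic-context flags (`read_support`).
3. **Computes binomial confidence bounds** — Wilson score intervals on
   per-technology counts (one-sided level 0.95) and on counts pooled
   across technologies, x_ci/n_ci (one-sided level 0.99)
   (`binomial_ci`).
4. **Classifies every candidate** with a decision tree: pooled upper
   bound ≤ 0.03 → confident homref (region kept); low pooled/long-read
   coverage (below the 0.5% quantile), germline-indel overlap,
   x_ci/n_ci > 0.5, homopolymer context, or indeterminate VAF → excluded
   (region removed with ±50 bp flanks); easy-to-map sites with pooled
   lower bound ≥ 0.05, or hard-to-map sites with long-read lower bound
   ≥ 0.05 → manual curation (`decision_tree`).
5. **Builds benchmark regions** by interval algebra: trio callable-region
   intersection, minus repeat strata, minus flanked indeterminate sites,
   dropping fragments < 50 bp (`regions`).
6. **Estimates the limit of detection** with in-silico two-sample
   mixtures over AFs 50/25/10/5/1/0% and an analytically enumerable
   binomial detector (`mixture_lod`).
7. **Compares callsets and batches** — an SNV-exact benchmarking
   comparator with VAF strata, and a per-variant Fisher + global
   Wilcoxon signed-rank test for VAF differences between DNA batches
   (`compare`).

## Worked example

```python
from mosaicbench import (
    SimulationConfig, simulate_database, run_funnel, HeuristicsConfig,
)

cfg = SimulationConfig(n_variants=5000, seed=42)
database, truth = simulate_database(cfg)       # known ground truth
report = run_funnel(database, HeuristicsConfig())
for stage, count in report.stages():
    print(f"{stage:28s} {count}")
print(report.terminal_counts())
```

prints

```
input                        5000
pass_upper_ci                244
pass_depth                   241
pass_indel_overlap           235
pass_germline_fraction       169
easy_to_map                  143
not_easy_to_map              26
easy_curate                  121
not_easy_non_homopolymer     26
pacbio_curate                20
curate_total                 141
{'CURATE': 141, 'EXCLUDE_KEEP_REGION': 4756, 'EXCLUDE_REMOVE_REGION': 103}
```

Reading the funnel: of 5,000 simulated candidates, 4,756 are confidently
near-absent (pooled 99% upper bound ≤ 0.03) and stay in the benchmark
regions as homozygous-reference territory; 244 survive the upper-bound
screen; coverage, indel-overlap and germline-fraction screens remove a
further 75; and 141 candidates (121 easy-to-map by the pooled lower
bound, 20 hard-to-map by the long-read lower bound) reach manual
curation. Every candidate lands in exactly one terminal category.

The limit-of-detection ladder (depth 300, 2,000 sites per AF):

```python
from mosaicbench import MixtureSpec, run_lod, DEFAULT_MIXTURE_FRACTIONS
specs = [MixtureSpec(f, depth=300, n_sites=2000, seed=i)
         for i, f in enumerate(DEFAULT_MIXTURE_FRACTIONS)]
print(run_lod(specs, error_rate=0.001).rows.to_string(index=False))
```

```
 expected_af  n_sites  detected  recall
        0.50     2000      2000  1.0000
        0.25     2000      2000  1.0000
        0.10     2000      2000  1.0000
        0.05     2000      1999  0.9995
        0.01     2000       418  0.2090
        0.00     2000         0  0.0000
```

Recall holds to 5% AF and collapses near 1% — the basis for a 5% VAF
inclusion floor.

A CLI mirrors the library (`mosaicbench simulate | build-db | classify |
regions | lod | compare | batch-effect`), each subcommand taking a
single YAML config plus `--seed`/`--out-dir` overrides and logging the
resolved configuration.

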