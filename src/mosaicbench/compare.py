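"""Benchmark comparison: callset evaluation and batch-effect VAF tests.

:func:`compare_callset` is an SNV-exact analog of haplotype-aware
benchmarking tools: matching is on (chrom, pos, ref, alt) ignoring
genotype, query calls outside the benchmark regions are ignored, and an
optional germline union suppresses false positives that are known
germline alleles.  :func:`batch_effect_test` compares per-variant allele
fractions between two DNA batches with Fisher's exact test per site and
a paired Wilcoxon signed-rank test globally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import VariantRecord
from .read_support import TechReadSupport, VariantKey
from .regions import RegionSet

__all__ = [
    "ComparisonReport",
    "BatchComparison",
    "compare_callset",
    "batch_effect_test",
]

logger = logging.getLogger(__name__)

DEFAULT_VAF_BINS = (0.0, 0.01, 0.02, 0.05, 0.10, 0.30, 0.50, 1.0)


@dataclass
class ComparisonReport:
    """TP/FN/FP counts with optional VAF stratification."""

    tp: int
    fn: int
    fp: int
    vaf_strata: pd.DataFrame | None  # columns: lo, hi, tp, fn, fp
    matched: list[VariantKey] = field(default_factory=list)
    n_query_non_snv: int = 0
    n_query_outside_regions: int = 0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else float("nan")


def _vaf_of(record: VariantRecord) -> float | None:
    for k in ("VAF", "AF"):
        if k in record.info:
            v = record.info[k]
            if isinstance(v, (tuple, list)):
                v = v[0]
            return float(v)
    return None


def compare_callset(
    query: Sequence[VariantRecord],
    benchmark_variants: Sequence[VariantRecord],
    benchmark_regions: RegionSet,
    germline_union: Iterable[VariantKey] | None = None,
    vaf_bins: Sequence[float] = DEFAULT_VAF_BINS,
) -> ComparisonReport:
    """Compare a query callset with the benchmark inside its regions.

    TP/FN are counted over benchmark variants inside the regions; FP are
    in-region query SNVs matching neither the benchmark nor the germline
    union.  VAF strata use the benchmark VAF for TP/FN and the query VAF
    for FP; if VAF fields are absent the strata table is omitted with a
    warning while totals are still reported.
    """
    germline = set(germline_union or ())

    snv_query = [q for q in query if q.is_snv]
    n_non_snv = len(query) - len(snv_query)
    if n_non_snv:
        logger.info("compare_callset: dropped %d non-SNV query records", n_non_snv)
    in_region = [q for q in snv_query if benchmark_regions.contains(q.chrom, q.pos - 1)]
    n_outside = len(snv_query) - len(in_region)

    bench_in_region = [
        b for b in benchmark_variants if benchmark_regions.contains(b.chrom, b.pos - 1)
    ]
    bench_keys = {b.key for b in bench_in_region}
    query_keys = {q.key for q in in_region}

    matched = sorted(bench_keys & query_keys)
    tp = len(matched)
    fn_records = [b for b in bench_in_region if b.key not in query_keys]
    # collapse duplicate query rows for the same allele
    fp_records = list(
        {
            q.key: q
            for q in in_region
            if q.key not in bench_keys and q.key not in germline
        }.values()
    )
    fp_keys = sorted(q.key for q in fp_records)

    strata: pd.DataFrame | None = None
    bench_vafs = {b.key: _vaf_of(b) for b in bench_in_region}
    if any(v is None for v in bench_vafs.values()) or any(
        _vaf_of(q) is None for q in fp_records
    ):
        logger.warning("compare_callset: VAF field missing; strata omitted")
    else:
        edges = list(vaf_bins)
        rows = []
        for lo, hi in zip(edges[:-1], edges[1:]):
            in_bin = lambda v: (lo <= v < hi) or (hi == edges[-1] and v == hi)
            rows.append(
                dict(
                    lo=lo,
                    hi=hi,
                    tp=sum(1 for k in matched if in_bin(bench_vafs[k])),
                    fn=sum(1 for b in fn_records if in_bin(bench_vafs[b.key])),
                    fp=sum(1 for q in fp_records if in_bin(_vaf_of(q))),
                )
            )
        strata = pd.DataFrame(rows)

    return ComparisonReport(
        tp=tp,
        fn=len(fn_records),
        fp=len(fp_keys),
        vaf_strata=strata,
        matched=matched,
        n_query_non_snv=n_non_snv,
        n_query_outside_regions=n_outside,
    )


@dataclass
class BatchComparison:
    """Per-variant and global VAF comparison between two DNA batches."""

    table: pd.DataFrame  # key columns + vaf_a, vaf_b, p_fisher
    global_statistic: float
    global_p: float
    direction: str  # "B>A", "A>B" or "none"
    n_dropped: int = 0


def batch_effect_test(
    support_a: Mapping[VariantKey, TechReadSupport],
    support_b: Mapping[VariantKey, TechReadSupport],
) -> BatchComparison:
    """Test for systematic VAF differences between two batches.

    Per variant: two-sided Fisher's exact test on the 2x2 table of
    alt/ref counts.  Globally: Wilcoxon signed-rank on the paired
    per-variant VAF differences (p = 1 by convention when every
    difference is zero).  Variants absent from either batch are dropped
    (inner join) with a logged count.
    """
    shared = sorted(set(support_a) & set(support_b))
    n_dropped = len(set(support_a) | set(support_b)) - len(shared)
    if len(shared) < 2:
        raise ValueError(f"need >= 2 shared variants, got {len(shared)}")
    if n_dropped:
        logger.info("batch_effect_test: dropped %d unshared variants", n_dropped)

    rows = []
    diffs = []
    for key in shared:
        a, b = support_a[key], support_b[key]
        table = [[a.alt_count, a.ref_count], [b.alt_count, b.ref_count]]
        _, p = stats.fisher_exact(table, alternative="two-sided")
        rows.append(
            dict(
                chrom=key[0], pos=key[1], ref=key[2], alt=key[3],
                alt_a=a.alt_count, ref_a=a.ref_count, vaf_a=a.vaf,
                alt_b=b.alt_count, ref_b=b.ref_count, vaf_b=b.vaf,
                p_fisher=float(p),
            )
        )
        diffs.append(b.vaf - a.vaf)

    diffs = np.asarray(diffs)
    nonzero = diffs[diffs != 0]
    if len(nonzero) == 0:
        stat, p_global = 0.0, 1.0
    else:
        stat, p_global = stats.wilcoxon(diffs, zero_method="wilcox")
    median_diff = float(np.median(diffs))
    direction = "B>A" if median_diff > 0 else ("A>B" if median_diff < 0 else "none")
    return BatchComparison(
        table=pd.DataFrame(rows),
        global_statistic=float(stat),
        global_p=float(p_global),
        direction=direction,
        n_dropped=n_dropped,
    )
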