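"""Genomic interval sets and the benchmark-region construction algebra.

All interval arithmetic is performed in 0-based half-open coordinates
(the BED convention).  1-based VCF positions are converted exactly once,
at the I/O boundary or when a variant site is turned into an interval
(:func:`flank_intervals`).  A :class:`RegionSet` is always kept in
canonical form: sorted by (chrom, start), with overlapping *and abutting*
intervals merged, so that the total base count is independent of how the
input intervals were written.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "BedInterval",
    "RegionSet",
    "GeneCoverage",
    "intersect_all",
    "subtract",
    "flank_intervals",
    "enforce_min_length",
    "build_benchmark_regions",
    "gene_coverage",
]

#: chromosome names never admitted into benchmark regions (autosomal benchmark)
NON_AUTOSOMAL = {"chrX", "chrY", "chrM", "chrMT", "X", "Y", "M", "MT"}


@dataclass(frozen=True)
class BedInterval:
    """A single 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    name: str | None = None

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    def __len__(self) -> int:
        return self.end - self.start


def _canonicalize(pairs: np.ndarray) -> np.ndarray:
    """Sort an (n, 2) array of [start, end) pairs and merge overlapping or
    bookended intervals."""
    if len(pairs) == 0:
        return pairs.reshape(0, 2)
    order = np.lexsort((pairs[:, 1], pairs[:, 0]))
    pairs = pairs[order]
    out: list[list[int]] = [[int(pairs[0, 0]), int(pairs[0, 1])]]
    for s, e in pairs[1:]:
        if s <= out[-1][1]:  # overlap or abut -> merge
            out[-1][1] = max(out[-1][1], int(e))
        else:
            out.append([int(s), int(e)])
    return np.asarray(out, dtype=np.int64)


class RegionSet:
    """An immutable set of disjoint, sorted genomic intervals with set algebra.

    Internally one ``(k, 2)`` int64 array of ``[start, end)`` pairs per
    chromosome.  Construction always canonicalizes, so every instance
    satisfies the class invariants (sorted, disjoint, non-abutting).
    """

    __slots__ = ("_per_chrom",)

    def __init__(self, per_chrom: Mapping[str, np.ndarray] | None = None, *, _canonical: bool = False):
        data: dict[str, np.ndarray] = {}
        for chrom, arr in (per_chrom or {}).items():
            arr = np.asarray(arr, dtype=np.int64).reshape(-1, 2)
            if len(arr) == 0:
                continue
            if not _canonical:
                if np.any(arr[:, 0] < 0) or np.any(arr[:, 0] >= arr[:, 1]):
                    raise ValueError(f"invalid intervals on {chrom}")
                arr = _canonicalize(arr)
            data[chrom] = arr
        self._per_chrom = {c: data[c] for c in sorted(data)}

    # -- constructors ------------------------------------------------------

    @classmethod
    def empty(cls) -> "RegionSet":
        return cls({})

    @classmethod
    def from_intervals(cls, intervals: Iterable[BedInterval | tuple]) -> "RegionSet":
        grouped: dict[str, list[tuple[int, int]]] = {}
        for iv in intervals:
            if isinstance(iv, BedInterval):
                chrom, start, end = iv.chrom, iv.start, iv.end
            else:
                chrom, start, end = iv[0], int(iv[1]), int(iv[2])
            if start < 0 or start >= end:
                raise ValueError(f"invalid interval {chrom}:{start}-{end}")
            grouped.setdefault(chrom, []).append((start, end))
        return cls({c: np.asarray(v, dtype=np.int64) for c, v in grouped.items()})

    # -- basic views -------------------------------------------------------

    @property
    def chroms(self) -> tuple[str, ...]:
        return tuple(self._per_chrom)

    def array(self, chrom: str) -> np.ndarray:
        return self._per_chrom.get(chrom, np.empty((0, 2), dtype=np.int64))

    def intervals(self) -> list[BedInterval]:
        out = []
        for chrom, arr in self._per_chrom.items():
            out.extend(BedInterval(chrom, int(s), int(e)) for s, e in arr)
        return out

    def __iter__(self) -> Iterator[BedInterval]:
        return iter(self.intervals())

    def __len__(self) -> int:
        return sum(len(a) for a in self._per_chrom.values())

    @property
    def total_bases(self) -> int:
        return int(sum((a[:, 1] - a[:, 0]).sum() for a in self._per_chrom.values()))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RegionSet):
            return NotImplemented
        if self.chroms != other.chroms:
            return False
        return all(np.array_equal(self._per_chrom[c], other._per_chrom[c]) for c in self.chroms)

    def __hash__(self):  # pragma: no cover - mutable-free but unhashed
        raise TypeError("RegionSet is not hashable")

    def __repr__(self) -> str:
        return f"RegionSet({len(self)} intervals, {self.total_bases} bp, {len(self.chroms)} chroms)"

    # -- membership --------------------------------------------------------

    def contains(self, chrom: str, pos0: int) -> bool:
        """True if the 0-based position ``pos0`` lies inside the set."""
        arr = self._per_chrom.get(chrom)
        if arr is None:
            return False
        i = int(np.searchsorted(arr[:, 0], pos0, side="right")) - 1
        return bool(i >= 0 and pos0 < arr[i, 1])

    # -- set algebra -------------------------------------------------------

    def union(self, other: "RegionSet") -> "RegionSet":
        data = {}
        for chrom in set(self.chroms) | set(other.chroms):
            data[chrom] = np.concatenate([self.array(chrom), other.array(chrom)])
        return RegionSet(data)

    def intersect(self, other: "RegionSet") -> "RegionSet":
        data = {}
        for chrom in set(self.chroms) & set(other.chroms):
            a, b = self.array(chrom), other.array(chrom)
            out = []
            i = j = 0
            while i < len(a) and j < len(b):
                s = max(a[i, 0], b[j, 0])
                e = min(a[i, 1], b[j, 1])
                if s < e:
                    out.append((s, e))
                if a[i, 1] <= b[j, 1]:
                    i += 1
                else:
                    j += 1
            if out:
                data[chrom] = np.asarray(out, dtype=np.int64)
        return RegionSet(data, _canonical=False)

    def subtract(self, other: "RegionSet") -> "RegionSet":
        data = {}
        for chrom in self.chroms:
            a, b = self.array(chrom), other.array(chrom)
            if len(b) == 0:
                data[chrom] = a
                continue
            out = []
            j = 0
            for s, e in a:
                cur = int(s)
                while j < len(b) and b[j, 1] <= cur:
                    j += 1
                k = j
                while k < len(b) and b[k, 0] < e:
                    if b[k, 0] > cur:
                        out.append((cur, int(b[k, 0])))
                    cur = max(cur, int(b[k, 1]))
                    if cur >= e:
                        break
                    k += 1
                if cur < e:
                    out.append((cur, int(e)))
            if out:
                data[chrom] = np.asarray(out, dtype=np.int64)
        return RegionSet(data)

    def filter_min_length(self, min_bp: int) -> "RegionSet":
        data = {}
        for chrom, arr in self._per_chrom.items():
            keep = arr[(arr[:, 1] - arr[:, 0]) >= min_bp]
            if len(keep):
                data[chrom] = keep
        return RegionSet(data, _canonical=True)

    def drop_chroms(self, names: set[str]) -> "RegionSet":
        return RegionSet(
            {c: a for c, a in self._per_chrom.items() if c not in names}, _canonical=True
        )


# -- module-level operations ----------------------------------------------


def intersect_all(sets: Sequence[RegionSet]) -> RegionSet:
    """Per-base intersection of one or more region sets."""
    if not sets:
        raise ValueError("intersect_all requires at least one RegionSet")
    result = sets[0]
    for s in sets[1:]:
        result = result.intersect(s)
    return result


def subtract(base: RegionSet, exclusions: RegionSet) -> RegionSet:
    """Per-base set difference ``base \\ exclusions``."""
    return base.subtract(exclusions)


def flank_intervals(sites: Iterable[tuple[str, int]], flank_bp: int) -> RegionSet:
    """Turn 1-based variant positions into flanked exclusion intervals.

    Each site becomes ``[pos - 1 - flank_bp, pos + flank_bp)`` (the variant
    base plus ``flank_bp`` on either side, 2*flank_bp + 1 bases total),
    clipped at zero; the result is merged.
    """
    if flank_bp < 0:
        raise ValueError("flank_bp must be >= 0")
    ivs = []
    for chrom, pos in sites:
        if pos < 1:
            raise ValueError(f"1-based position must be >= 1, got {chrom}:{pos}")
        ivs.append((chrom, max(0, pos - 1 - flank_bp), pos + flank_bp))
    return RegionSet.from_intervals(ivs)


def enforce_min_length(regions: RegionSet, min_bp: int) -> RegionSet:
    """Drop intervals shorter than ``min_bp`` (strict ``<`` removal)."""
    if min_bp < 1:
        raise ValueError("min_bp must be >= 1")
    return regions.filter_min_length(min_bp)


def build_benchmark_regions(
    trio_sets: Sequence[RegionSet],
    strata_exclusions: Sequence[RegionSet],
    variant_region_removals: Iterable[tuple[str, int]],
    *,
    flank_bp: int = 50,
    min_region_bp: int = 50,
    drop_non_autosomal: bool = True,
    logger=None,
) -> RegionSet:
    """Construct benchmark regions from trio callable regions and exclusions.

    Pipeline: intersect the per-sample callable region sets, subtract each
    repeat/context stratum wholesale, subtract flanked indeterminate-VAF
    variant sites, and finally drop fragments shorter than ``min_region_bp``
    (the length filter runs last because subtraction fragments intervals).
    """
    base = intersect_all(list(trio_sets))
    if drop_non_autosomal:
        n_before = len(base)
        base = base.drop_chroms(NON_AUTOSOMAL)
        if logger is not None and len(base) != n_before:
            logger.info("dropped %d non-autosomal intervals", n_before - len(base))
    if base.total_bases == 0 and logger is not None:
        logger.warning("trio intersection is empty")
    for stratum in strata_exclusions:
        base = base.subtract(stratum)
    base = base.subtract(flank_intervals(variant_region_removals, flank_bp))
    base = enforce_min_length(base, min_region_bp)
    if logger is not None:
        lengths = [e - s for iv in base for s, e in [(iv.start, iv.end)]]
        logger.info(
            "benchmark regions: %d intervals, %d bp, min %s, max %s",
            len(base),
            base.total_bases,
            min(lengths) if lengths else "-",
            max(lengths) if lengths else "-",
        )
    return base


@dataclass(frozen=True)
class GeneCoverage:
    """Per-gene coverage of benchmark regions."""

    gene: str
    gene_bases: int
    covered_bases: int

    @property
    def fraction(self) -> float:
        return self.covered_bases / self.gene_bases if self.gene_bases else 0.0


def gene_coverage(
    benchmark: RegionSet,
    genes: Mapping[str, RegionSet],
    variants: Iterable[tuple[str, int]] = (),
    coverage_threshold: float = 0.9,
) -> tuple[list[GeneCoverage], int, int]:
    """Coverage of each gene by the benchmark regions.

    Returns ``(per_gene, n_variants_in_genes, n_genes_well_covered)`` where a
    gene is well covered when its covered fraction is at least
    ``coverage_threshold`` and a variant (1-based position) is "in genes"
    when it falls inside any gene interval.
    """
    per_gene = []
    for name, gset in genes.items():
        covered = benchmark.intersect(gset).total_bases
        per_gene.append(GeneCoverage(name, gset.total_bases, covered))
    n_in_genes = 0
    for chrom, pos in variants:
        if any(g.contains(chrom, pos - 1) for g in genes.values()):
            n_in_genes += 1
    n_well = sum(1 for g in per_gene if g.fraction >= coverage_threshold)
    return per_gene, n_in_genes, n_well
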