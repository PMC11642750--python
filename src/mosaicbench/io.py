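"""Readers and writers for the formats the pipeline touches.

VCF is handled through pysam; multi-allelic records are split into one
:class:`VariantRecord` per alternate allele at read time.  BED files are
3+ column, tab-separated, 0-based half-open; reading a BED always returns
a canonical (sorted, merged) :class:`~mosaicbench.regions.RegionSet`.
Coordinate-convention conversions (1-based VCF vs 0-based BED) happen
only here and in :func:`mosaicbench.regions.flank_intervals`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pysam

from .regions import BedInterval, RegionSet

__all__ = [
    "VariantRecord",
    "ParseError",
    "read_vcf",
    "read_bed",
    "read_gene_bed",
    "write_bed",
    "write_benchmark",
]

logger = logging.getLogger(__name__)

SNV_BASES = {"A", "C", "G", "T"}


class ParseError(ValueError):
    """Malformed input file content."""


@dataclass
class VariantRecord:
    """One variant allele from a VCF data line.

    ``pos`` is 1-based.  Multi-allelic source lines produce one record per
    alternate allele, all sharing ``pos`` and ``info``.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    filter: str = "PASS"
    info: dict = field(default_factory=dict)
    sample_fields: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"VCF position must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt must be non-empty")
        if not self.filter:
            raise ValueError("filter must be non-empty (use 'PASS')")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_snv(self) -> bool:
        return self.ref in SNV_BASES and self.alt in SNV_BASES


def _scalarize(value):
    if isinstance(value, tuple):
        return value[0] if len(value) == 1 else value
    return value


def read_vcf(
    path: str | Path, aliases: Mapping[str, str] | None = None
) -> list[VariantRecord]:
    """Read a VCF 4.x text file into VariantRecords, splitting multi-allelics.

    Record order is preserved; symbolic/missing ALT alleles ('.', '*',
    '<...>') are dropped with a logged count.  Chromosome names are
    compared exact-string throughout the package; ``aliases`` optionally
    renames contigs at this boundary (e.g. ``{"1": "chr1"}``) — no
    implicit "chr" normalization is ever applied.
    """
    path = Path(path)
    aliases = dict(aliases or {})
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[VariantRecord] = []
    n_symbolic = 0
    try:
        with pysam.VariantFile(str(path)) as vf:
            samples = list(vf.header.samples)
            for i, rec in enumerate(vf, start=1):
                filt = ";".join(rec.filter.keys()) or "PASS"
                info = {k: _scalarize(v) for k, v in rec.info.items()}
                sample_fields = {
                    s: {k: _scalarize(v) for k, v in rec.samples[s].items()}
                    for s in samples
                }
                for alt in rec.alts or ():
                    if alt in (".", "*") or alt.startswith("<"):
                        n_symbolic += 1
                        continue
                    records.append(
                        VariantRecord(
                            chrom=aliases.get(rec.chrom, rec.chrom),
                            pos=rec.pos,
                            ref=rec.ref,
                            alt=alt,
                            filter=filt,
                            info=dict(info),
                            sample_fields={s: dict(v) for s, v in sample_fields.items()},
                        )
                    )
    except (ValueError, OSError) as exc:
        raise ParseError(f"failed to parse VCF {path}: {exc}") from exc
    if n_symbolic:
        logger.info("read_vcf(%s): dropped %d symbolic/missing ALT alleles", path, n_symbolic)
    return records


def read_bed(path: str | Path, aliases: Mapping[str, str] | None = None) -> RegionSet:
    """Read a BED3+ file into a merged RegionSet.

    Raises :class:`ParseError` naming the offending line for non-integer
    coordinates and for intervals with start >= end.  ``aliases``
    renames chromosomes as in :func:`read_vcf`.
    """
    path = Path(path)
    aliases = dict(aliases or {})
    intervals: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >= 3 tab-separated fields")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from None
            if start < 0 or start >= end:
                raise ParseError(f"{path}:{lineno}: invalid interval start={start} end={end}")
            intervals.append((aliases.get(fields[0], fields[0]), start, end))
    return RegionSet.from_intervals(intervals)


def read_gene_bed(path: str | Path) -> dict[str, RegionSet]:
    """Read a BED4 gene file into one RegionSet per gene name (column 4)."""
    path = Path(path)
    per_gene: dict[str, list[tuple[str, int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(f"{path}:{lineno}: gene BED needs 4 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from None
            per_gene.setdefault(fields[3], []).append((fields[0], start, end))
    return {g: RegionSet.from_intervals(ivs) for g, ivs in per_gene.items()}


def write_bed(regions: RegionSet, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for iv in regions:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def _contig_lengths(
    variants: Sequence[VariantRecord], regions: RegionSet
) -> dict[str, int]:
    lengths: dict[str, int] = {}
    for v in variants:
        lengths[v.chrom] = max(lengths.get(v.chrom, 0), v.pos + len(v.ref))
    for iv in regions:
        lengths[iv.chrom] = max(lengths.get(iv.chrom, 0), iv.end)
    # pad so downstream tools treating these as real contigs do not clip
    return {c: length + 1000 for c, length in lengths.items()}


def write_benchmark(
    variants: Sequence[VariantRecord],
    regions: RegionSet,
    vcf_path: str | Path,
    bed_path: str | Path,
    metadata: Mapping[str, str] | None = None,
) -> None:
    """Write the benchmark VCF + BED pair.

    Header lines record the provenance metadata (tool version, config
    digest, seed, ...).  Unless ``metadata['allow_outside_regions']`` is
    truthy, every variant position must fall inside ``regions``.  The
    output round-trips through :func:`read_vcf`/:func:`read_bed` for
    chrom, pos, ref, alt, filter and the VAF/TAR info fields.
    """
    metadata = dict(metadata or {})
    allow_outside = bool(metadata.pop("allow_outside_regions", False))
    if not allow_outside:
        outside = [v for v in variants if not regions.contains(v.chrom, v.pos - 1)]
        if outside:
            raise ValueError(
                f"{len(outside)} variant(s) outside benchmark regions, first: "
                f"{outside[0].key}; pass metadata['allow_outside_regions']=True to override"
            )

    header = pysam.VariantHeader()
    from . import __version__

    header.add_line(f"##mosaicbenchVersion={__version__}")
    for k, v in metadata.items():
        header.add_line(f"##{k}={v}")
    header.info.add("TAR", 1, "Integer", "Caller tumor allele read count")
    header.info.add("VAF", 1, "Float", "Variant allele fraction (pooled orthogonal support)")
    for filt in sorted({v.filter for v in variants} - {"PASS"}):
        for part in filt.split(";"):
            if part not in header.filters:
                header.filters.add(part, None, None, "caller filter")
    for contig, length in sorted(_contig_lengths(variants, regions).items()):
        header.contigs.add(contig, length=length)

    with pysam.VariantFile(str(vcf_path), "w", header=header) as out:
        for v in variants:
            rec = out.new_record(
                contig=v.chrom,
                start=v.pos - 1,
                stop=v.pos - 1 + len(v.ref),
                alleles=(v.ref, v.alt),
            )
            for part in v.filter.split(";"):
                rec.filter.add(part)
            for k in ("TAR", "VAF"):
                if k in v.info:
                    rec.info[k] = v.info[k]
            out.write(rec)
    write_bed(regions, bed_path)
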