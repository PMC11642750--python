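"""Mosaic-candidate database assembly.

Post-caller filtering of somatic VCF records, attachment of
quality-filtered per-technology allele counts, and genomic-context
annotation.  The database dialect is one TSV row per
(variant, technology) with context flags joined on the variant key,
mirroring per-BAM readcount provenance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io import VariantRecord
from .regions import RegionSet

__all__ = [
    "TechReadSupport",
    "ContextFlags",
    "MosaicCandidate",
    "filter_caller_output",
    "exclude_germline_and_complex",
    "count_allele_support",
    "assemble_database",
    "write_database",
    "read_database",
]

logger = logging.getLogger(__name__)

VariantKey = tuple[str, int, str, str]

#: caller FILTER value marking variants detected in the normal sample
NORMAL_FILTER = "VARIANT_DETECTED_IN_NORMAL"

DATABASE_COLUMNS = [
    "chrom", "pos", "ref", "alt", "caller_filter", "tar", "vaf_caller",
    "technology", "ref_count", "alt_count", "depth",
    "easy_to_map", "homopolymer", "tandem_repeat", "overlaps_germline_indel",
]


@dataclass(frozen=True)
class TechReadSupport:
    """Quality-filtered allele counts for one technology at one site.

    ``supporting`` records whether the technology meets the minimum
    alternate-read threshold; it is set during database assembly.
    """

    technology: str
    ref_count: int
    alt_count: int
    depth: int
    supporting: bool = True

    def __post_init__(self) -> None:
        if min(self.ref_count, self.alt_count, self.depth) < 0:
            raise ValueError("read counts must be non-negative")
        if self.ref_count + self.alt_count > self.depth:
            raise ValueError("ref_count + alt_count cannot exceed depth")

    @property
    def vaf(self) -> float:
        return self.alt_count / self.depth if self.depth else 0.0


@dataclass(frozen=True)
class ContextFlags:
    easy_to_map: bool = True
    homopolymer: bool = False
    tandem_repeat: bool = False
    overlaps_germline_indel: bool = False


@dataclass
class MosaicCandidate:
    """One candidate site: caller annotations, per-technology support, context."""

    chrom: str
    pos: int
    ref: str
    alt: str
    caller_filter: str = "PASS"
    tar: int = 0
    support: dict[str, TechReadSupport] = field(default_factory=dict)
    flags: ContextFlags = field(default_factory=ContextFlags)
    vaf_caller: float | None = None

    def __post_init__(self) -> None:
        if self.tar < 0:
            raise ValueError("tar must be >= 0")

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1 and self.ref != "-" and self.alt != "-"


def _get_tar(record: VariantRecord) -> int:
    """Tumor allele read count: INFO TAR, else first tumor-sample TAR tier."""
    value = record.info.get("TAR")
    if value is None:
        for fields in record.sample_fields.values():
            if "TAR" in fields:
                value = fields["TAR"]
                break
    if value is None:
        raise ValueError(f"record {record.key} is missing the TAR field")
    if isinstance(value, (tuple, list)):
        value = value[0]
    return int(value)


def filter_caller_output(
    records: Sequence[VariantRecord], min_tar: int = 5
) -> list[VariantRecord]:
    """Post-caller filtering of the somatic callset.

    Removes records whose FILTER contains ``VARIANT_DETECTED_IN_NORMAL``
    and records with tumor allele read count <= ``min_tar`` (strictly
    greater than ``min_tar`` is required to survive).  All other FILTER
    values, including non-PASS, are retained.
    """
    out = []
    for rec in records:
        if NORMAL_FILTER in rec.filter.split(";"):
            continue
        if _get_tar(rec) > min_tar:
            out.append(rec)
    return out


def exclude_germline_and_complex(
    records: Sequence[VariantRecord],
    germline_vcf: Sequence[VariantRecord],
    exclusion_regions: RegionSet,
) -> list[VariantRecord]:
    """Remove known germline alleles and records in complex/SV regions.

    Germline matching is allele-exact on (chrom, pos, ref, alt), ignoring
    genotype — the squash-ploidy comparison for SNVs.
    """
    germline_keys = {g.key for g in germline_vcf}
    return [
        rec
        for rec in records
        if rec.key not in germline_keys
        and not exclusion_regions.contains(rec.chrom, rec.pos - 1)
    ]


def count_allele_support(
    reads: Iterable[tuple[str, float, float]],
    ref: str,
    alt: str,
    min_base_qual: float = 25,
    min_map_qual: float = 40,
    technology: str = "",
) -> TechReadSupport:
    """Count quality-filtered allele support from per-read pileup rows.

    Each row is ``(base, base_quality, mapping_quality)``.  Reads failing
    either quality threshold are excluded from all counts; ``depth`` is
    the number of surviving reads regardless of base.
    """
    ref_count = alt_count = depth = 0
    for base, base_qual, map_qual in reads:
        if base_qual < min_base_qual or map_qual < min_map_qual:
            continue
        depth += 1
        if base == alt:
            alt_count += 1
        elif base == ref:
            ref_count += 1
    return TechReadSupport(
        technology=technology, ref_count=ref_count, alt_count=alt_count, depth=depth
    )


def assemble_database(
    records: Sequence[VariantRecord],
    support_rows: Iterable[tuple[VariantKey, TechReadSupport]],
    strata: Mapping[str, RegionSet] | None = None,
    germline_indel_sites: RegionSet | None = None,
    min_alt_support: int = 2,
    low_mappability_stratum: str = "low_mappability",
    drop_non_snv: bool = True,
) -> list[MosaicCandidate]:
    """Join caller records with per-technology support and context flags.

    A technology whose alternate count falls below ``min_alt_support`` is
    recorded but flagged non-supporting.  ``easy_to_map`` is defined as
    NOT overlapping the configured low-mappability stratum.  Indels are
    carried through upstream filtering but dropped here with a logged
    count: the benchmark classification is SNV-only.
    """
    strata = dict(strata or {})
    germline_indel_sites = germline_indel_sites or RegionSet.empty()

    by_key: dict[VariantKey, dict[str, TechReadSupport]] = {}
    for key, sup in support_rows:
        techs = by_key.setdefault(key, {})
        if sup.technology in techs:
            raise ValueError(f"duplicate support row for {key} / {sup.technology}")
        techs[sup.technology] = replace(sup, supporting=sup.alt_count >= min_alt_support)

    low_map = strata.get(low_mappability_stratum, RegionSet.empty())
    homopolymer = strata.get("homopolymer", RegionSet.empty())
    tandem = strata.get("tandem_repeat", RegionSet.empty())

    candidates: list[MosaicCandidate] = []
    n_indels = 0
    for rec in records:
        if drop_non_snv and not rec.is_snv:
            n_indels += 1
            continue
        pos0 = rec.pos - 1
        flags = ContextFlags(
            easy_to_map=not low_map.contains(rec.chrom, pos0),
            homopolymer=homopolymer.contains(rec.chrom, pos0),
            tandem_repeat=tandem.contains(rec.chrom, pos0),
            overlaps_germline_indel=germline_indel_sites.contains(rec.chrom, pos0),
        )
        tar = _get_tar(rec)
        vaf_caller = rec.info.get("VAF")
        candidates.append(
            MosaicCandidate(
                chrom=rec.chrom,
                pos=rec.pos,
                ref=rec.ref,
                alt=rec.alt,
                caller_filter=rec.filter,
                tar=tar,
                support=by_key.get(rec.key, {}),
                flags=flags,
                vaf_caller=float(vaf_caller) if vaf_caller is not None else None,
            )
        )
    if n_indels:
        logger.info("assemble_database: dropped %d non-SNV candidates", n_indels)
    return candidates


# -- database TSV dialect --------------------------------------------------


def write_database(candidates: Sequence[MosaicCandidate], path: str | Path) -> None:
    """Write the database as one TSV row per (variant, technology)."""
    rows = []
    for c in candidates:
        base = dict(
            chrom=c.chrom, pos=c.pos, ref=c.ref, alt=c.alt,
            caller_filter=c.caller_filter, tar=c.tar,
            vaf_caller="" if c.vaf_caller is None else c.vaf_caller,
            easy_to_map=c.flags.easy_to_map,
            homopolymer=c.flags.homopolymer,
            tandem_repeat=c.flags.tandem_repeat,
            overlaps_germline_indel=c.flags.overlaps_germline_indel,
        )
        if c.support:
            for tech in sorted(c.support):
                s = c.support[tech]
                rows.append({**base, "technology": tech, "ref_count": s.ref_count,
                             "alt_count": s.alt_count, "depth": s.depth})
        else:
            rows.append({**base, "technology": "", "ref_count": 0, "alt_count": 0, "depth": 0})
    pd.DataFrame(rows, columns=DATABASE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_database(path: str | Path, min_alt_support: int = 2) -> list[MosaicCandidate]:
    """Read a database TSV back into MosaicCandidates (input order preserved)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
    candidates: dict[VariantKey, MosaicCandidate] = {}
    for row in df.itertuples(index=False):
        key = (row.chrom, int(row.pos), row.ref, row.alt)
        if key not in candidates:
            vaf_caller = getattr(row, "vaf_caller", None)
            candidates[key] = MosaicCandidate(
                chrom=row.chrom, pos=int(row.pos), ref=row.ref, alt=row.alt,
                caller_filter=str(row.caller_filter), tar=int(row.tar),
                flags=ContextFlags(
                    easy_to_map=bool(row.easy_to_map),
                    homopolymer=bool(row.homopolymer),
                    tandem_repeat=bool(row.tandem_repeat),
                    overlaps_germline_indel=bool(row.overlaps_germline_indel),
                ),
                vaf_caller=None if pd.isna(vaf_caller) else float(vaf_caller),
            )
        tech = "" if pd.isna(row.technology) else str(row.technology)
        if tech:
            candidates[key].support[tech] = TechReadSupport(
                technology=tech,
                ref_count=int(row.ref_count),
                alt_count=int(row.alt_count),
                depth=int(row.depth),
                supporting=int(row.alt_count) >= min_alt_support,
            )
    return list(candidates.values())
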