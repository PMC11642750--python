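"""Heuristics decision tree classifying mosaic-database candidates.

Every candidate is routed, in a fixed rule order, into one of three
terminal categories:

* ``EXCLUDE_KEEP_REGION`` — confidently near-absent (the pooled upper
  confidence bound on the VAF is at or below ``upper_ci_floor``); the
  site remains homozygous-reference benchmark territory.
* ``EXCLUDE_REMOVE_REGION`` — the VAF cannot be confidently placed below
  ``region_absent_max`` or above ``lower_ci_include`` (or the site is
  untrustworthy: low coverage, germline-indel overlap, germline-like
  fraction, repeat context); the site and its flanks leave the regions.
* ``CURATE`` — enough pooled (or, in hard-to-map context, long-read)
  support for a 5-30% mosaic; forwarded to manual curation.

The rule order is: pooled upper-bound screen, coverage-quantile screen,
germline-indel overlap, germline-fraction screen (x/n > 0.5), then a
partition by mappability with a pooled lower-bound rule for easy-to-map
sites and a long-read lower-bound rule for hard-to-map non-homopolymer
sites.  The first terminal rule that fires wins; the full trace is kept.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .binomial_ci import combined_ci, binomial_interval
from .read_support import MosaicCandidate, VariantKey

__all__ = [
    "CURATE",
    "EXCLUDE_KEEP_REGION",
    "EXCLUDE_REMOVE_REGION",
    "HeuristicsConfig",
    "DepthThresholds",
    "RuleOutcome",
    "ClassificationResult",
    "FunnelReport",
    "compute_depth_thresholds",
    "classify",
    "run_funnel",
    "apply_curation",
    "collect_region_removals",
]

logger = logging.getLogger(__name__)

CURATE = "CURATE"
EXCLUDE_KEEP_REGION = "EXCLUDE_KEEP_REGION"
EXCLUDE_REMOVE_REGION = "EXCLUDE_REMOVE_REGION"

CURATION_LABELS = {"include", "exclude_keep_region", "exclude_remove_region"}


@dataclass(frozen=True)
class HeuristicsConfig:
    """Thresholds of the decision tree.

    ``upper_ci_floor``: pooled upper bound at/below which a candidate is
    confidently near-absent.  ``lower_ci_include``: lower bound at/above
    which a >= 5% VAF is supported.  ``region_absent_max``: the VAF below
    which a site may remain in regions; used when adjudicating curated
    indeterminate sites.  ``coverage_quantile``: empirical quantile of
    pooled and long-read depth below which candidates are ignored.
    """

    upper_ci_floor: float = 0.03
    lower_ci_include: float = 0.05
    region_absent_max: float = 0.02
    vaf_target_max: float = 0.30
    coverage_quantile: float = 0.005
    xn_germline_cut: float = 0.5
    combined_level: float = 0.99
    per_tech_level: float = 0.95
    min_tar: int = 5
    min_alt_support: int = 2
    flank_bp: int = 50
    min_region_bp: int = 50
    pacbio_technology: str = "pacbio"
    combined_include: tuple[str, ...] | None = None  # None -> all technologies
    interval_method: str = "wilson"
    low_coverage_removes_region: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.region_absent_max < self.lower_ci_include <= self.xn_germline_cut):
            raise ValueError(
                "require 0 < region_absent_max < lower_ci_include <= xn_germline_cut"
            )
        if not (0 < self.coverage_quantile < 1):
            raise ValueError("coverage_quantile must be in (0, 1)")
        for lvl in (self.combined_level, self.per_tech_level):
            if not (0.5 < lvl < 1):
                raise ValueError("confidence levels must be in (0.5, 1)")


@dataclass(frozen=True)
class DepthThresholds:
    combined_depth_min: int
    pacbio_depth_min: int


@dataclass(frozen=True)
class RuleOutcome:
    rule: str
    value: float
    threshold: float
    outcome: str  # "pass", "fail", "warn"


@dataclass(frozen=True)
class ClassificationResult:
    category: str
    rule_trace: tuple[RuleOutcome, ...]

    def __post_init__(self) -> None:
        if not self.rule_trace:
            raise ValueError("rule_trace must be non-empty")
        if self.category not in {CURATE, EXCLUDE_KEEP_REGION, EXCLUDE_REMOVE_REGION}:
            raise ValueError(f"unknown category {self.category!r}")


def _empirical_quantile(values: Sequence[float], q: float) -> float:
    """Type-1 (inverse-CDF) empirical quantile: the ceil(q*n)-th order statistic."""
    v = np.sort(np.asarray(values, dtype=float))
    if len(v) == 0:
        raise ValueError("cannot take a quantile of an empty sample")
    idx = max(int(math.ceil(q * len(v))) - 1, 0)
    return float(v[idx])


def _pooled_depths(
    candidate: MosaicCandidate, cfg: HeuristicsConfig
) -> tuple[int, int]:
    include = None if cfg.combined_include is None else set(cfg.combined_include)
    n_ci = sum(
        s.depth
        for t, s in candidate.support.items()
        if (include is None or t in include) and s.depth >= 1
    )
    pb = candidate.support.get(cfg.pacbio_technology)
    return n_ci, (pb.depth if pb else 0)


def compute_depth_thresholds(
    database: Sequence[MosaicCandidate],
    q: float = 0.005,
    cfg: HeuristicsConfig | None = None,
) -> DepthThresholds:
    """Empirical q-quantiles of pooled depth (n_ci) and long-read depth.

    Uses the type-1 order-statistic quantile; at q=0 this is the minimum
    of the distribution, so nothing is filtered.
    """
    if not database:
        raise ValueError("cannot compute depth thresholds on an empty database")
    cfg = cfg or HeuristicsConfig()
    pooled, pacbio = zip(*(_pooled_depths(c, cfg) for c in database))
    if q == 0:
        return DepthThresholds(int(min(pooled)), int(min(pacbio)))
    return DepthThresholds(
        combined_depth_min=int(_empirical_quantile(pooled, q)),
        pacbio_depth_min=int(_empirical_quantile(pacbio, q)),
    )


def classify(
    candidate: MosaicCandidate,
    thresholds: DepthThresholds,
    cfg: HeuristicsConfig | None = None,
) -> ClassificationResult:
    """Apply the decision-tree rules in order; first terminal rule wins.

    Boundary semantics are exact: a pooled upper bound equal to
    ``upper_ci_floor`` is excluded; a lower bound equal to
    ``lower_ci_include`` passes; a pooled fraction equal to
    ``xn_germline_cut`` is retained.
    """
    cfg = cfg or HeuristicsConfig()
    if not any(s.depth >= 1 for s in candidate.support.values()):
        raise ValueError(
            f"candidate {candidate.key} has no read support; cannot compute CIs"
        )
    comb = combined_ci(
        candidate,
        level=cfg.combined_level,
        include=cfg.combined_include,
        method=cfg.interval_method,
    )
    trace: list[RuleOutcome] = []

    # 1. pooled upper-bound screen: confidently near-absent sites are
    #    excluded from the VCF but stay in the homref benchmark regions.
    trace.append(
        RuleOutcome("combined_upper_ci", comb.ci.upper, cfg.upper_ci_floor,
                    "fail" if comb.ci.upper <= cfg.upper_ci_floor else "pass")
    )
    if comb.ci.upper <= cfg.upper_ci_floor:
        return ClassificationResult(EXCLUDE_KEEP_REGION, tuple(trace))

    # 2. coverage-quantile screen (pooled and long-read depth).
    n_ci, pb_depth = _pooled_depths(candidate, cfg)
    low_cov = n_ci < thresholds.combined_depth_min or pb_depth < thresholds.pacbio_depth_min
    trace.append(
        RuleOutcome("combined_depth", n_ci, thresholds.combined_depth_min,
                    "fail" if n_ci < thresholds.combined_depth_min else "pass")
    )
    trace.append(
        RuleOutcome("pacbio_depth", pb_depth, thresholds.pacbio_depth_min,
                    "fail" if pb_depth < thresholds.pacbio_depth_min else "pass")
    )
    if low_cov:
        category = (
            EXCLUDE_REMOVE_REGION if cfg.low_coverage_removes_region else EXCLUDE_KEEP_REGION
        )
        return ClassificationResult(category, tuple(trace))

    # 3. germline-indel overlap.
    overlap = candidate.flags.overlaps_germline_indel
    trace.append(RuleOutcome("germline_indel_overlap", float(overlap), 0.0,
                             "fail" if overlap else "pass"))
    if overlap:
        return ClassificationResult(EXCLUDE_REMOVE_REGION, tuple(trace))

    # 4. germline-fraction screen: pooled x/n above 0.5 is germline-like.
    trace.append(
        RuleOutcome("xn_germline_fraction", comb.point, cfg.xn_germline_cut,
                    "fail" if comb.point > cfg.xn_germline_cut else "pass")
    )
    if comb.point > cfg.xn_germline_cut:
        return ClassificationResult(EXCLUDE_REMOVE_REGION, tuple(trace))

    # advisory: above the 5-30% target band but not germline-like;
    # curation decides these edge cases rather than auto-inclusion.
    if comb.point > cfg.vaf_target_max:
        trace.append(
            RuleOutcome("above_vaf_target", comb.point, cfg.vaf_target_max, "warn")
        )

    # 5. mappability partition.
    if candidate.flags.easy_to_map:
        trace.append(
            RuleOutcome("combined_lower_ci", comb.ci.lower, cfg.lower_ci_include,
                        "pass" if comb.ci.lower >= cfg.lower_ci_include else "fail")
        )
        if comb.ci.lower >= cfg.lower_ci_include:
            return ClassificationResult(CURATE, tuple(trace))
        return ClassificationResult(EXCLUDE_REMOVE_REGION, tuple(trace))

    # not easy-to-map: homopolymers are excluded outright.
    trace.append(
        RuleOutcome("homopolymer", float(candidate.flags.homopolymer), 0.0,
                    "fail" if candidate.flags.homopolymer else "pass")
    )
    if candidate.flags.homopolymer:
        return ClassificationResult(EXCLUDE_REMOVE_REGION, tuple(trace))

    pb = candidate.support.get(cfg.pacbio_technology)
    if pb is None or pb.depth < 1:
        raise ValueError(
            f"candidate {candidate.key} is hard-to-map but has no "
            f"{cfg.pacbio_technology!r} support for the long-read lower-bound rule"
        )
    pb_ci = binomial_interval(pb.alt_count, pb.depth, cfg.per_tech_level, cfg.interval_method)
    trace.append(
        RuleOutcome("pacbio_lower_ci", pb_ci.lower, cfg.lower_ci_include,
                    "pass" if pb_ci.lower >= cfg.lower_ci_include else "fail")
    )
    if pb_ci.lower >= cfg.lower_ci_include:
        return ClassificationResult(CURATE, tuple(trace))
    return ClassificationResult(EXCLUDE_REMOVE_REGION, tuple(trace))


@dataclass
class FunnelReport:
    """Stage-by-stage counts of the decision tree over a database."""

    n_input: int
    n_upper_excluded: int
    n_after_upper: int
    n_low_coverage: int
    n_after_depth: int
    n_indel_overlap: int
    n_after_indel: int
    n_germline_fraction: int
    n_after_germline: int
    n_easy: int
    n_not_easy: int
    n_easy_curate: int
    n_easy_excluded: int
    n_homopolymer: int
    n_not_easy_nonhp: int
    n_pacbio_curate: int
    n_pacbio_excluded: int
    n_curate_total: int
    thresholds: DepthThresholds
    results: dict[VariantKey, ClassificationResult] = field(repr=False, default_factory=dict)

    def terminal_counts(self) -> dict[str, int]:
        counts = {CURATE: 0, EXCLUDE_KEEP_REGION: 0, EXCLUDE_REMOVE_REGION: 0}
        for res in self.results.values():
            counts[res.category] += 1
        return counts

    def is_conserved(self) -> bool:
        return sum(self.terminal_counts().values()) == self.n_input

    def stages(self) -> list[tuple[str, int]]:
        return [
            ("input", self.n_input),
            ("pass_upper_ci", self.n_after_upper),
            ("pass_depth", self.n_after_depth),
            ("pass_indel_overlap", self.n_after_indel),
            ("pass_germline_fraction", self.n_after_germline),
            ("easy_to_map", self.n_easy),
            ("not_easy_to_map", self.n_not_easy),
            ("easy_curate", self.n_easy_curate),
            ("not_easy_non_homopolymer", self.n_not_easy_nonhp),
            ("pacbio_curate", self.n_pacbio_curate),
            ("curate_total", self.n_curate_total),
        ]


def run_funnel(
    database: Sequence[MosaicCandidate],
    cfg: HeuristicsConfig | None = None,
    thresholds: DepthThresholds | None = None,
) -> FunnelReport:
    """Classify every candidate and tally survivors after each rule stage."""
    cfg = cfg or HeuristicsConfig()
    if thresholds is None:
        thresholds = compute_depth_thresholds(database, cfg.coverage_quantile, cfg)

    counts = dict.fromkeys(
        ["upper", "low_cov", "indel", "germline", "easy", "not_easy",
         "easy_curate", "easy_excl", "homopolymer", "nonhp", "pb_curate", "pb_excl"],
        0,
    )
    results: dict[VariantKey, ClassificationResult] = {}
    for cand in database:
        res = classify(cand, thresholds, cfg)
        if cand.key in results:
            raise ValueError(f"duplicate candidate key {cand.key}")
        results[cand.key] = res
        fired = {ro.rule: ro for ro in res.rule_trace}
        if fired["combined_upper_ci"].outcome == "fail":
            counts["upper"] += 1
            continue
        if fired["combined_depth"].outcome == "fail" or fired["pacbio_depth"].outcome == "fail":
            counts["low_cov"] += 1
            continue
        if fired["germline_indel_overlap"].outcome == "fail":
            counts["indel"] += 1
            continue
        if fired["xn_germline_fraction"].outcome == "fail":
            counts["germline"] += 1
            continue
        if "combined_lower_ci" in fired:
            counts["easy"] += 1
            if res.category == CURATE:
                counts["easy_curate"] += 1
            else:
                counts["easy_excl"] += 1
        else:
            counts["not_easy"] += 1
            if fired["homopolymer"].outcome == "fail":
                counts["homopolymer"] += 1
            else:
                counts["nonhp"] += 1
                if res.category == CURATE:
                    counts["pb_curate"] += 1
                else:
                    counts["pb_excl"] += 1

    n_input = len(database)
    n_after_upper = n_input - counts["upper"]
    n_after_depth = n_after_upper - counts["low_cov"]
    n_after_indel = n_after_depth - counts["indel"]
    n_after_germline = n_after_indel - counts["germline"]
    report = FunnelReport(
        n_input=n_input,
        n_upper_excluded=counts["upper"],
        n_after_upper=n_after_upper,
        n_low_coverage=counts["low_cov"],
        n_after_depth=n_after_depth,
        n_indel_overlap=counts["indel"],
        n_after_indel=n_after_indel,
        n_germline_fraction=counts["germline"],
        n_after_germline=n_after_germline,
        n_easy=counts["easy"],
        n_not_easy=counts["not_easy"],
        n_easy_curate=counts["easy_curate"],
        n_easy_excluded=counts["easy_excl"],
        n_homopolymer=counts["homopolymer"],
        n_not_easy_nonhp=counts["nonhp"],
        n_pacbio_curate=counts["pb_curate"],
        n_pacbio_excluded=counts["pb_excl"],
        n_curate_total=counts["easy_curate"] + counts["pb_curate"],
        thresholds=thresholds,
        results=results,
    )
    assert report.is_conserved(), "funnel lost or duplicated candidates"
    return report


def apply_curation(
    classified: Mapping[VariantKey, ClassificationResult],
    labels: Mapping[VariantKey, str],
    post_hoc_removals: Iterable[VariantKey] = (),
) -> tuple[list[VariantKey], list[VariantKey]]:
    """Resolve CURATE candidates with manual-curation labels.

    Labels: ``include`` -> benchmark variant; ``exclude_remove_region``
    (VAF indeterminate) -> site removed from regions with flanks;
    ``exclude_keep_region`` (confidently < 2% VAF) -> excluded, region
    kept.  Labels for non-CURATE keys are rejected; every CURATE key must
    be labeled.  ``post_hoc_removals`` are appended to the removal list
    (single-site removals identified after release, e.g. mosaics
    coinciding with parental germline variants).
    """
    curate_keys = {k for k, r in classified.items() if r.category == CURATE}
    missing = sorted(curate_keys - set(labels))
    if missing:
        raise ValueError(f"missing curation labels for {len(missing)} keys: {missing[:5]}")
    extra = sorted(set(labels) - curate_keys)
    if extra:
        raise ValueError(
            f"curation labels supplied for {len(extra)} non-CURATE keys: {extra[:5]}"
        )
    bad = {k: v for k, v in labels.items() if v not in CURATION_LABELS}
    if bad:
        raise ValueError(f"invalid curation labels: {bad}")

    benchmark = [k for k in classified if k in curate_keys and labels[k] == "include"]
    removals = [
        k for k in classified
        if k in curate_keys and labels[k] == "exclude_remove_region"
    ]
    removals.extend(post_hoc_removals)
    return benchmark, removals


def collect_region_removals(
    classified: Mapping[VariantKey, ClassificationResult]
) -> list[VariantKey]:
    """Keys whose decision-tree outcome removes the site from regions."""
    return [k for k, r in classified.items() if r.category == EXCLUDE_REMOVE_REGION]
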