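"""Synthetic candidate databases, mixtures and region inputs with known truth.

The generator emulates the statistical structure of a trio-based mosaic
candidate database: a large majority of near-zero-VAF artifact sites, a
minority of genuine mosaics in the 1-30% VAF band, and a small germline
contamination tail near 50%; per-technology depths around the study
coverages (Illumina 300x, BGI 100x, Element 136x, PacBio 106x) with
binomial allele sampling under a symmetric substitution-error model.
Every simulated candidate carries a truth record including the
decision-tree outcome expected analytically from its true VAF and
context flags, so downstream classification can be scored without
circularity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .decision_tree import (
    CURATE,
    EXCLUDE_KEEP_REGION,
    EXCLUDE_REMOVE_REGION,
    HeuristicsConfig,
)
from .read_support import ContextFlags, MosaicCandidate, TechReadSupport, VariantKey
from .regions import RegionSet

__all__ = [
    "VafClass",
    "TechSpec",
    "SimulationConfig",
    "TruthRecord",
    "RegionInputs",
    "simulate_database",
    "simulate_mixture",
    "simulate_region_inputs",
    "expected_category",
    "write_truth",
]

BASES = np.array(["A", "C", "G", "T"])


@dataclass(frozen=True)
class VafClass:
    """One mixture component of true variant allele fractions.

    ``dist`` is ``("point", v)`` or ``("uniform", lo, hi)``.
    """

    label: str
    dist: tuple
    weight: float

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        kind = self.dist[0]
        if kind == "point":
            return np.full(size, float(self.dist[1]))
        if kind == "uniform":
            return rng.uniform(float(self.dist[1]), float(self.dist[2]), size)
        raise ValueError(f"unknown VAF distribution {self.dist!r}")


@dataclass(frozen=True)
class TechSpec:
    """Per-technology depth and error model."""

    name: str
    mean_depth: float
    depth_dispersion: float = 30.0  # negative-binomial shape; larger = tighter
    error_rate: float = 0.001  # per-read substitution rate, split over 3 bases


def default_vaf_classes() -> tuple[VafClass, ...]:
    # database composition dominated by near-zero artifact sites, as in a
    # real somatic candidate stream surviving only caller-level filters
    return (
        VafClass("mosaic", ("uniform", 0.01, 0.30), 0.03),
        VafClass("artifact", ("point", 0.002), 0.95),
        VafClass("germline_like", ("point", 0.50), 0.02),
    )


def default_tech_specs() -> tuple[TechSpec, ...]:
    return (
        TechSpec("illumina", 300, 30.0, 0.001),
        TechSpec("bgi", 100, 30.0, 0.001),
        TechSpec("element", 136, 30.0, 0.0005),
        TechSpec("pacbio", 106, 30.0, 0.002),
    )


@dataclass
class SimulationConfig:
    """Parameters of the synthetic candidate database."""

    n_variants: int = 5000
    vaf_classes: tuple[VafClass, ...] = field(default_factory=default_vaf_classes)
    tech_specs: tuple[TechSpec, ...] = field(default_factory=default_tech_specs)
    # proportions of genomic-context flags (easy_to_map = 1 - low_mappability)
    context_props: dict = field(
        default_factory=lambda: {
            "low_mappability": 0.10,
            "homopolymer": 0.05,
            "tandem_repeat": 0.05,
        }
    )
    indel_overlap_prob: float = 0.01
    seed: int = 0
    genome: dict = field(
        default_factory=lambda: {"sim1": 10_000_000, "sim2": 5_000_000}
    )

    def validate(self) -> None:
        problems = []
        if self.n_variants < 1:
            problems.append("n_variants must be >= 1")
        total_w = sum(c.weight for c in self.vaf_classes)
        if abs(total_w - 1.0) > 1e-9:
            problems.append(f"vaf_classes weights must sum to 1 (got {total_w})")
        for c in self.vaf_classes:
            vals = c.dist[1:]
            if any(not (0 <= float(v) <= 1) for v in vals):
                problems.append(f"class {c.label}: VAF values must be in [0, 1]")
        for t in self.tech_specs:
            if t.mean_depth <= 0:
                problems.append(f"tech {t.name}: mean_depth must be > 0")
            if not (0 <= t.error_rate < 0.5):
                problems.append(f"tech {t.name}: error_rate must be in [0, 0.5)")
        props = dict(self.context_props)
        if "easy_to_map" in props:  # allow specifying the complement directly
            props["low_mappability"] = 1.0 - props.pop("easy_to_map")
        for k, p in props.items():
            if not (0 <= p <= 1):
                problems.append(f"context proportion {k} must be in [0, 1]")
        if not (0 <= self.indel_overlap_prob <= 1):
            problems.append("indel_overlap_prob must be in [0, 1]")
        if problems:
            raise ValueError("invalid SimulationConfig: " + "; ".join(problems))

    @property
    def low_mappability_prop(self) -> float:
        props = dict(self.context_props)
        if "easy_to_map" in props:
            return 1.0 - float(props["easy_to_map"])
        return float(props.get("low_mappability", 0.0))


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one simulated candidate."""

    chrom: str
    pos: int
    ref: str
    alt: str
    label: str
    true_vaf: float
    flags: ContextFlags
    expected_category: str

    def __post_init__(self) -> None:
        if not (0 <= self.true_vaf <= 1):
            raise ValueError("true VAF must be in [0, 1]")
        if self.expected_category not in {CURATE, EXCLUDE_KEEP_REGION, EXCLUDE_REMOVE_REGION}:
            raise ValueError(f"invalid expected category {self.expected_category!r}")

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)


def expected_category(
    true_vaf: float, flags: ContextFlags, cfg: HeuristicsConfig | None = None
) -> str:
    """Analytic decision-tree outcome in the infinite-depth limit.

    Computed from the true VAF and flags only (both CI bounds converge to
    the true VAF as depth grows), mirroring the rule order of
    :func:`mosaicbench.decision_tree.classify`.  Coverage-quantile rules
    are realization-dependent and deliberately ignored here.
    """
    cfg = cfg or HeuristicsConfig()
    if true_vaf <= cfg.upper_ci_floor:
        return EXCLUDE_KEEP_REGION
    if flags.overlaps_germline_indel:
        return EXCLUDE_REMOVE_REGION
    if true_vaf > cfg.xn_germline_cut:
        return EXCLUDE_REMOVE_REGION
    if flags.easy_to_map:
        return CURATE if true_vaf >= cfg.lower_ci_include else EXCLUDE_REMOVE_REGION
    if flags.homopolymer:
        return EXCLUDE_REMOVE_REGION
    return CURATE if true_vaf >= cfg.lower_ci_include else EXCLUDE_REMOVE_REGION


def _alt_probability(vaf: np.ndarray, error_rate: float) -> np.ndarray:
    """P(read shows the alt base): true alt survival plus ref misreads."""
    return vaf * (1 - error_rate) + (1 - vaf) * error_rate / 3.0


def _draw_depths(rng: np.random.Generator, spec: TechSpec, size: int) -> np.ndarray:
    """Overdispersed integer depths, truncated at >= 1."""
    k = spec.depth_dispersion
    p = k / (k + spec.mean_depth)
    return np.maximum(1, rng.negative_binomial(k, p, size))


def simulate_database(
    config: SimulationConfig,
    heuristics: HeuristicsConfig | None = None,
) -> tuple[list[MosaicCandidate], list[TruthRecord]]:
    """Generate a candidate database with aligned truth records.

    Deterministic given ``config.seed``.  For each variant, per-technology
    depth is drawn from the truncated negative-binomial model and the alt
    count binomially at ``vaf*(1-e) + (1-vaf)*e/3``; remaining reads are
    split between ref and third-base errors.
    """
    config.validate()
    heuristics = heuristics or HeuristicsConfig()
    rng = np.random.default_rng(config.seed)
    n = config.n_variants

    weights = np.array([c.weight for c in config.vaf_classes])
    class_idx = rng.choice(len(config.vaf_classes), size=n, p=weights)
    vafs = np.empty(n)
    for i, cls in enumerate(config.vaf_classes):
        mask = class_idx == i
        vafs[mask] = cls.sample(rng, int(mask.sum()))

    # distinct positions across the synthetic genome
    chroms = sorted(config.genome)
    lengths = np.array([config.genome[c] for c in chroms], dtype=float)
    chrom_idx = rng.choice(len(chroms), size=n, p=lengths / lengths.sum())
    positions = np.empty(n, dtype=np.int64)
    seen: set[tuple[int, int]] = set()
    for i in range(n):
        while True:
            pos = int(rng.integers(1, config.genome[chroms[chrom_idx[i]]] + 1))
            if (chrom_idx[i], pos) not in seen:
                seen.add((chrom_idx[i], pos))
                positions[i] = pos
                break
    ref_idx = rng.integers(0, 4, size=n)
    alt_shift = rng.integers(1, 4, size=n)
    refs = BASES[ref_idx]
    alts = BASES[(ref_idx + alt_shift) % 4]

    low_map = rng.random(n) < config.low_mappability_prop
    homopolymer = rng.random(n) < float(config.context_props.get("homopolymer", 0.0))
    tandem = rng.random(n) < float(config.context_props.get("tandem_repeat", 0.0))
    indel_overlap = rng.random(n) < config.indel_overlap_prob

    depths = {t.name: _draw_depths(rng, t, n) for t in config.tech_specs}
    alt_counts = {}
    other_counts = {}
    for t in config.tech_specs:
        p_alt = _alt_probability(vafs, t.error_rate)
        alt_counts[t.name] = rng.binomial(depths[t.name], p_alt)
        # remaining reads: third-base errors vs ref, conditional split
        rest = depths[t.name] - alt_counts[t.name]
        p_other_given_rest = np.divide(
            2 * t.error_rate / 3.0,
            1.0 - p_alt,
            out=np.zeros_like(p_alt),
            where=(1.0 - p_alt) > 0,
        )
        other_counts[t.name] = rng.binomial(rest, np.clip(p_other_given_rest, 0, 1))

    candidates: list[MosaicCandidate] = []
    truths: list[TruthRecord] = []
    illumina = config.tech_specs[0].name
    for i in range(n):
        flags = ContextFlags(
            easy_to_map=not bool(low_map[i]),
            homopolymer=bool(homopolymer[i]),
            tandem_repeat=bool(tandem[i]),
            overlaps_germline_indel=bool(indel_overlap[i]),
        )
        support = {}
        for t in config.tech_specs:
            d = int(depths[t.name][i])
            a = int(alt_counts[t.name][i])
            o = int(other_counts[t.name][i])
            support[t.name] = TechReadSupport(
                technology=t.name,
                ref_count=d - a - o,
                alt_count=a,
                depth=d,
                supporting=a >= heuristics.min_alt_support,
            )
        tar = support[illumina].alt_count if illumina in support else 0
        label = config.vaf_classes[class_idx[i]].label
        cand = MosaicCandidate(
            chrom=chroms[chrom_idx[i]],
            pos=int(positions[i]),
            ref=str(refs[i]),
            alt=str(alts[i]),
            caller_filter="PASS" if label != "artifact" else "LowEVS",
            tar=tar,
            support=support,
            flags=flags,
            vaf_caller=support[illumina].vaf if illumina in support else None,
        )
        candidates.append(cand)
        truths.append(
            TruthRecord(
                chrom=cand.chrom,
                pos=cand.pos,
                ref=cand.ref,
                alt=cand.alt,
                label=label,
                true_vaf=float(vafs[i]),
                flags=flags,
                expected_category=expected_category(float(vafs[i]), flags, heuristics),
            )
        )
    return candidates, truths


def simulate_mixture(
    sites: int,
    hg002_fraction: float,
    depth: int = 300,
    error_rate: float = 0.001,
    seed: int = 0,
    fixed_depth: bool = True,
    depth_dispersion: float = 30.0,
) -> pd.DataFrame:
    """Two-sample in-silico mixture at heterozygous sites unique to one sample.

    Mixing a fraction f of the carrier sample into a non-carrier
    background yields an expected allele fraction of f/2 at sites where
    the carrier is heterozygous and the background homozygous reference.
    Returns one row per site with ``alt``, ``depth`` and ``expected_af``.
    """
    if not (0 <= hg002_fraction <= 1):
        raise ValueError("hg002_fraction must be in [0, 1]")
    if not (0 <= error_rate <= 1):
        raise ValueError("error_rate must be in [0, 1]")
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if sites < 1:
        raise ValueError("sites must be >= 1")
    rng = np.random.default_rng(seed)
    expected_af = hg002_fraction * 0.5
    if fixed_depth:
        depths = np.full(sites, depth, dtype=np.int64)
    else:
        spec = TechSpec("mixture", depth, depth_dispersion, error_rate)
        depths = _draw_depths(rng, spec, sites)
    p_alt = float(_alt_probability(np.array([expected_af]), error_rate)[0])
    alts = rng.binomial(depths, p_alt)
    return pd.DataFrame(
        {"alt": alts, "depth": depths, "expected_af": expected_af}
    )


@dataclass
class RegionInputs:
    """Synthetic BED-side inputs to the region-construction pipeline."""

    trio: list[RegionSet]
    strata: dict[str, RegionSet]
    complex_exclusions: RegionSet


def _random_cover(
    rng: np.random.Generator,
    length: int,
    mean_kept: float,
    mean_gap: float,
) -> list[tuple[int, int]]:
    """Alternating kept/gap segments along one chromosome."""
    out = []
    pos = int(rng.exponential(mean_gap))
    while pos < length:
        seg = 1 + int(rng.exponential(mean_kept))
        end = min(pos + seg, length)
        out.append((pos, end))
        pos = end + 1 + int(rng.exponential(mean_gap))
    return out


def simulate_region_inputs(config: SimulationConfig) -> RegionInputs:
    """Trio callable-region BEDs, context strata and complex-variant exclusions.

    The three trio sets each cover ~90% of the synthetic genome so their
    pairwise intersections are non-empty; each stratum is disjoint within
    itself by construction.  Deterministic given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    trio = []
    for _ in range(3):
        ivs = []
        for chrom, length in sorted(config.genome.items()):
            ivs.extend(
                (chrom, s, e) for s, e in _random_cover(rng, length, 20_000, 1_500)
            )
        trio.append(RegionSet.from_intervals(ivs))
    strata_params = {
        "homopolymer": (30, 3_000),
        "tandem_repeat": (120, 6_000),
        "low_mappability": (4_000, 40_000),
    }
    strata = {}
    for name, (mean_kept, mean_gap) in strata_params.items():
        ivs = []
        for chrom, length in sorted(config.genome.items()):
            ivs.extend(
                (chrom, s, e) for s, e in _random_cover(rng, length, mean_kept, mean_gap)
            )
        strata[name] = RegionSet.from_intervals(ivs)
    complex_ivs = []
    for chrom, length in sorted(config.genome.items()):
        complex_ivs.extend(
            (chrom, s, e) for s, e in _random_cover(rng, length, 200, 50_000)
        )
    return RegionInputs(
        trio=trio,
        strata=strata,
        complex_exclusions=RegionSet.from_intervals(complex_ivs),
    )


TRUTH_COLUMNS = [
    "chrom", "pos", "ref", "alt", "label", "true_vaf",
    "easy_to_map", "homopolymer", "tandem_repeat", "overlaps_germline_indel",
    "expected_category",
]


def write_truth(truths: Sequence[TruthRecord], path: str | Path) -> None:
    """Truth table as TSV (one row per simulated candidate)."""
    rows = [
        dict(
            chrom=t.chrom, pos=t.pos, ref=t.ref, alt=t.alt, label=t.label,
            true_vaf=t.true_vaf,
            easy_to_map=t.flags.easy_to_map,
            homopolymer=t.flags.homopolymer,
            tandem_repeat=t.flags.tandem_repeat,
            overlaps_germline_indel=t.flags.overlaps_germline_indel,
            expected_category=t.expected_category,
        )
        for t in truths
    ]
    pd.DataFrame(rows, columns=TRUTH_COLUMNS).to_csv(path, sep="\t", index=False)
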