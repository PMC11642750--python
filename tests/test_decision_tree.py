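"""Decision-tree classification: thresholds, rule order, boundaries, curation."""

from __future__ import annotations

import math

import numpy as np
import pytest

from mosaicbench.binomial_ci import wilson_interval
from mosaicbench.decision_tree import (
    CURATE,
    EXCLUDE_KEEP_REGION,
    EXCLUDE_REMOVE_REGION,
    DepthThresholds,
    HeuristicsConfig,
    apply_curation,
    classify,
    collect_region_removals,
    compute_depth_thresholds,
    run_funnel,
)
from mosaicbench.read_support import ContextFlags, MosaicCandidate, TechReadSupport
from mosaicbench.synthetic import SimulationConfig, VafClass, simulate_database

CFG = HeuristicsConfig()
NO_DEPTH_FILTER = DepthThresholds(0, 0)


def candidate(
    alt_by_tech: dict[str, tuple[int, int]],
    easy=True,
    homopolymer=False,
    indel=False,
) -> MosaicCandidate:
    return MosaicCandidate(
        chrom="c", pos=1000, ref="A", alt="T",
        support={
            t: TechReadSupport(t, d - a, a, d) for t, (a, d) in alt_by_tech.items()
        },
        flags=ContextFlags(easy, homopolymer, False, indel),
    )


# -- depth thresholds ------------------------------------------------------


def test_constant_depths_give_that_threshold():
    db = [candidate({"pacbio": (0, 500)}) for _ in range(50)]
    thr = compute_depth_thresholds(db, 0.005)
    assert thr.combined_depth_min == 500
    assert thr.pacbio_depth_min == 500


def test_quantile_equals_order_statistic_oracle():
    db = [candidate({"pacbio": (0, d)}) for d in range(1, 1001)]
    thr = compute_depth_thresholds(db, 0.005)
    # brute force: smallest k with k/n >= q  ->  ceil(0.005*1000) = 5th value
    values = sorted(range(1, 1001))
    assert thr.combined_depth_min == values[math.ceil(0.005 * 1000) - 1] == 5


def test_quantile_zero_is_the_minimum():
    db = [candidate({"pacbio": (0, d)}) for d in (17, 99, 5, 200)]
    thr = compute_depth_thresholds(db, q=0)
    assert thr.combined_depth_min == 5


def test_empty_database_is_an_error():
    with pytest.raises(ValueError):
        compute_depth_thresholds([], 0.005)


# -- classify: rule outcomes and boundaries --------------------------------


def test_confidently_absent_keeps_region():
    cand = candidate({"illumina": (0, 300), "pacbio": (0, 100)})
    res = classify(cand, NO_DEPTH_FILTER, CFG)
    assert res.category == EXCLUDE_KEEP_REGION
    assert res.rule_trace[0].rule == "combined_upper_ci"
    assert res.rule_trace[0].outcome == "fail"


def test_upper_ci_boundary_exactly_at_floor_is_excluded():
    # find (x, n) with upper CI just at/below 0.03 under the 99% one-sided level
    cand = candidate({"illumina": (4, 642)})
    upper = wilson_interval(4, 642, 0.99).upper
    assert upper <= 0.03
    res = classify(cand, NO_DEPTH_FILTER, CFG)
    assert res.category == EXCLUDE_KEEP_REGION


def test_low_coverage_removes_region():
    cand = candidate({"illumina": (30, 200), "pacbio": (10, 50)})
    thr = DepthThresholds(combined_depth_min=500, pacbio_depth_min=0)
    res = classify(cand, thr, CFG)
    assert res.category == EXCLUDE_REMOVE_REGION
    assert any(r.rule == "combined_depth" and r.outcome == "fail" for r in res.rule_trace)


def test_low_coverage_keep_region_config_switch():
    cand = candidate({"illumina": (30, 200), "pacbio": (10, 50)})
    thr = DepthThresholds(500, 0)
    cfg = HeuristicsConfig(low_coverage_removes_region=False)
    assert classify(cand, thr, cfg).category == EXCLUDE_KEEP_REGION


def test_germline_indel_overlap_removes_region():
    cand = candidate({"illumina": (30, 300), "pacbio": (10, 100)}, indel=True)
    res = classify(cand, NO_DEPTH_FILTER, CFG)
    assert res.category == EXCLUDE_REMOVE_REGION
    assert res.rule_trace[-1].rule == "germline_indel_overlap"


def test_germline_like_fraction_removed_with_named_rule():
    cand = candidate({"illumina": (180, 300), "pacbio": (60, 100)})  # x/n = 0.6
    res = classify(cand, NO_DEPTH_FILTER, CFG)
    assert res.category == EXCLUDE_REMOVE_REGION
    assert res.rule_trace[-1].rule == "xn_germline_fraction"


def test_xn_exactly_half_is_retained():
    cand = candidate({"illumina": (150, 300), "pacbio": (50, 100)})  # x/n = 0.5
    res = classify(cand, NO_DEPTH_FILTER, CFG)
    # not dropped by the germline-fraction rule; lands in the easy branch
    assert all(
        not (r.rule == "xn_germline_fraction" and r.outcome == "fail")
        for r in res.rule_trace
    )
    assert res.category == CURATE  # lower CI at 0.5 easily exceeds 0.05
    assert any(r.rule == "above_vaf_target" and r.outcome == "warn" for r in res.rule_trace)


def test_easy_to_map_mosaic_is_curated():
    cand = candidate({"illumina": (30, 300), "pacbio": (10, 100)})  # 10% VAF
    res = classify(cand, NO_DEPTH_FILTER, CFG)
    assert res.category == CURATE
    assert res.rule_trace[-1].rule == "combined_lower_ci"


def test_lower_ci_boundary_exactly_at_include_passes():
    # construct pooled counts whose 99% lower bound is >= 0.05 barely
    for x in range(30, 60):
        ci = wilson_interval(x, 642, 0.99)
        if ci.lower >= 0.05:
            cand = candidate({"illumina": (x, 642)})
            assert classify(cand, NO_DEPTH_FILTER, CFG).category == CURATE
            break
    else:  # pragma: no cover
        pytest.fail("no boundary case found")


def test_easy_indeterminate_removes_region():
    cand = candidate({"illumina": (15, 300), "pacbio": (5, 100)})  # 5% point, lower < 0.05
    res = classify(cand, NO_DEPTH_FILTER, CFG)
    assert res.category == EXCLUDE_REMOVE_REGION


def test_hard_to_map_homopolymer_removed():
    cand = candidate({"illumina": (30, 300), "pacbio": (10, 100)},
                     easy=False, homopolymer=True)
    res = classify(cand, NO_DEPTH_FILTER, CFG)
    assert res.category == EXCLUDE_REMOVE_REGION
    assert res.rule_trace[-1].rule == "homopolymer"


def test_hard_to_map_uses_pacbio_lower_bound():
    strong = candidate({"illumina": (5, 300), "pacbio": (25, 100)}, easy=False)
    assert classify(strong, NO_DEPTH_FILTER, CFG).category == CURATE
    weak = candidate({"illumina": (30, 300), "pacbio": (3, 100)}, easy=False)
    assert classify(weak, NO_DEPTH_FILTER, CFG).category == EXCLUDE_REMOVE_REGION


def test_hard_to_map_without_pacbio_is_an_error():
    cand = candidate({"illumina": (30, 300)}, easy=False)
    with pytest.raises(ValueError, match="pacbio"):
        classify(cand, NO_DEPTH_FILTER, CFG)


def test_no_support_is_an_error():
    cand = MosaicCandidate("c", 1, "A", "T")
    with pytest.raises(ValueError, match="no read support"):
        classify(cand, NO_DEPTH_FILTER, CFG)


def test_category_invariant_to_non_terminal_rule_order():
    """A candidate passing every screen is CURATE however screens are ordered;
    the trace records all screens it passed."""
    cand = candidate({"illumina": (45, 300), "pacbio": (15, 100)})
    res = classify(cand, NO_DEPTH_FILTER, CFG)
    assert res.category == CURATE
    passed = [r.rule for r in res.rule_trace if r.outcome == "pass"]
    assert {"combined_upper_ci", "combined_depth", "pacbio_depth",
            "germline_indel_overlap", "xn_germline_fraction"} <= set(passed)


# -- funnel ----------------------------------------------------------------


def test_funnel_single_candidate_conserved():
    db = [candidate({"illumina": (30, 300), "pacbio": (10, 100)})]
    rep = run_funnel(db, CFG, NO_DEPTH_FILTER)
    assert rep.is_conserved()
    assert sum(rep.terminal_counts().values()) == 1
    assert rep.n_curate_total == 1


def test_funnel_counts_match_generation_time_expectations():
    """A cohort built from clear-cut classes yields exactly the expected
    CURATE count (truth computed analytically at generation time)."""
    config = SimulationConfig(
        n_variants=600,
        vaf_classes=(
            VafClass("mosaic", ("uniform", 0.12, 0.30), 0.25),
            VafClass("artifact", ("point", 0.001), 0.75),
        ),
        context_props={"easy_to_map": 1.0, "homopolymer": 0.0, "tandem_repeat": 0.0},
        indel_overlap_prob=0.0,
        seed=21,
    )
    db, truths = simulate_database(config)
    rep = run_funnel(db, CFG, NO_DEPTH_FILTER)
    expected_curate = sum(1 for t in truths if t.expected_category == CURATE)
    assert rep.n_curate_total == expected_curate
    assert rep.is_conserved()
    # every expectation matches the realized category for clear-cut classes
    for t in truths:
        assert rep.results[t.key].category == t.expected_category


def test_funnel_partition_sums():
    config = SimulationConfig(n_variants=800, seed=31)
    db, _ = simulate_database(config)
    rep = run_funnel(db, CFG)
    assert rep.n_after_upper == rep.n_input - rep.n_upper_excluded
    assert rep.n_easy + rep.n_not_easy == rep.n_after_germline
    assert rep.n_easy_curate + rep.n_easy_excluded == rep.n_easy
    assert rep.n_homopolymer + rep.n_not_easy_nonhp == rep.n_not_easy
    assert rep.n_pacbio_curate + rep.n_pacbio_excluded == rep.n_not_easy_nonhp
    assert rep.n_curate_total == rep.n_easy_curate + rep.n_pacbio_curate
    assert rep.is_conserved()


# -- curation --------------------------------------------------------------


def make_classified(n_curate=3, n_keep=2, n_remove=1):
    out = {}
    i = 0
    for cat, count in [(CURATE, n_curate), (EXCLUDE_KEEP_REGION, n_keep),
                       (EXCLUDE_REMOVE_REGION, n_remove)]:
        for _ in range(count):
            cand = candidate({"illumina": (30, 300)})
            key = ("c", 1000 + i, "A", "T")
            from mosaicbench.decision_tree import ClassificationResult, RuleOutcome
            out[key] = ClassificationResult(cat, (RuleOutcome("stub", 0, 0, "fail"),))
            i += 1
    return out


def test_apply_curation_routes_labels():
    classified = make_classified(n_curate=3)
    keys = [k for k, r in classified.items() if r.category == CURATE]
    labels = dict(zip(keys, ["include", "exclude_remove_region", "exclude_keep_region"]))
    benchmark, removals = apply_curation(classified, labels)
    assert benchmark == [keys[0]]
    assert removals == [keys[1]]


def test_apply_curation_empty():
    assert apply_curation({}, {}) == ([], [])


def test_apply_curation_indeterminate_only_in_removals():
    classified = make_classified(n_curate=1, n_keep=0, n_remove=0)
    key = next(iter(classified))
    benchmark, removals = apply_curation(classified, {key: "exclude_remove_region"})
    assert benchmark == [] and removals == [key]


def test_apply_curation_missing_label_errors():
    classified = make_classified(n_curate=2)
    keys = [k for k, r in classified.items() if r.category == CURATE]
    with pytest.raises(ValueError, match="missing"):
        apply_curation(classified, {keys[0]: "include"})


def test_apply_curation_rejects_labels_on_non_curate():
    classified = make_classified(n_curate=1, n_keep=1)
    curate = [k for k, r in classified.items() if r.category == CURATE]
    keep = [k for k, r in classified.items() if r.category == EXCLUDE_KEEP_REGION]
    with pytest.raises(ValueError, match="non-CURATE"):
        apply_curation(classified, {curate[0]: "include", keep[0]: "include"})


def test_apply_curation_appends_post_hoc_removals():
    classified = make_classified(n_curate=1)
    key = next(iter(classified))
    extra = ("c", 9999, "G", "A")
    _, removals = apply_curation(classified, {key: "include"}, post_hoc_removals=[extra])
    assert extra in removals


def test_collect_region_removals():
    classified = make_classified(n_curate=1, n_keep=2, n_remove=3)
    removals = collect_region_removals(classified)
    assert len(removals) == 3
    assert all(classified[k].category == EXCLUDE_REMOVE_REGION for k in removals)
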