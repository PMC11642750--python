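"""Candidate filtering, allele-support counting and database assembly."""

from __future__ import annotations

import pytest

from mosaicbench.io import VariantRecord
from mosaicbench.read_support import (
    ContextFlags,
    MosaicCandidate,
    TechReadSupport,
    assemble_database,
    count_allele_support,
    exclude_germline_and_complex,
    filter_caller_output,
    read_database,
    write_database,
)
from mosaicbench.regions import RegionSet


def rec(chrom="chr1", pos=100, ref="A", alt="T", filt="PASS", tar=10):
    return VariantRecord(chrom, pos, ref, alt, filt, {"TAR": tar})


# -- filter_caller_output --------------------------------------------------


def test_normal_filter_is_dropped():
    kept = filter_caller_output([rec(filt="VARIANT_DETECTED_IN_NORMAL", tar=50)])
    assert kept == []


def test_normal_filter_dropped_even_when_combined():
    kept = filter_caller_output([rec(filt="LowEVS;VARIANT_DETECTED_IN_NORMAL", tar=50)])
    assert kept == []


def test_tar_threshold_is_strict():
    assert filter_caller_output([rec(tar=5)], min_tar=5) == []
    assert len(filter_caller_output([rec(tar=6)], min_tar=5)) == 1


def test_non_pass_filters_are_retained():
    assert len(filter_caller_output([rec(filt="LowEVS", tar=10)])) == 1


def test_empty_input():
    assert filter_caller_output([]) == []


def test_missing_tar_is_an_error():
    bad = VariantRecord("chr1", 100, "A", "T", "PASS", {})
    with pytest.raises(ValueError, match="TAR"):
        filter_caller_output([bad])


def test_tar_read_from_sample_fields_first_tier():
    # Strelka-style FORMAT TAR is (tier1, tier2); tier1 is used
    v = VariantRecord("chr1", 100, "A", "T", "PASS", {}, {"TUMOR": {"TAR": (8, 11)}})
    assert len(filter_caller_output([v], min_tar=5)) == 1
    assert filter_caller_output([v], min_tar=8) == []


def test_filter_caller_output_is_idempotent():
    records = [rec(tar=t, filt=f) for t in (3, 6, 9)
               for f in ("PASS", "LowEVS", "VARIANT_DETECTED_IN_NORMAL")]
    once = filter_caller_output(records)
    assert filter_caller_output(once) == once


# -- exclude_germline_and_complex -----------------------------------------


def test_germline_allele_exact_match_removed():
    germline = [rec(pos=100, alt="T")]
    kept = exclude_germline_and_complex([rec(pos=100, alt="T")], germline, RegionSet.empty())
    assert kept == []


def test_same_pos_different_alt_retained():
    germline = [rec(pos=100, alt="G")]
    kept = exclude_germline_and_complex([rec(pos=100, alt="T")], germline, RegionSet.empty())
    assert len(kept) == 1


def test_exclusion_region_membership():
    regions = RegionSet.from_intervals([("chr1", 90, 110)])
    kept = exclude_germline_and_complex(
        [rec(pos=100), rec(pos=111)], [], regions
    )
    assert [r.pos for r in kept] == [111]


def test_no_exclusions_is_identity_and_idempotent():
    records = [rec(pos=p) for p in (1, 2, 3)]
    out = exclude_germline_and_complex(records, [], RegionSet.empty())
    assert out == records
    germ = [rec(pos=2)]
    once = exclude_germline_and_complex(records, germ, RegionSet.empty())
    twice = exclude_germline_and_complex(once, germ, RegionSet.empty())
    assert twice == once
    assert set(r.key for r in once) <= set(r.key for r in records)


# -- count_allele_support --------------------------------------------------


def test_all_reads_below_quality_gives_zero_counts():
    reads = [("A", 10, 10)] * 5
    sup = count_allele_support(reads, "A", "T")
    assert (sup.ref_count, sup.alt_count, sup.depth) == (0, 0, 0)


def test_manual_count_under_default_thresholds():
    reads = [("A", 30, 60)] * 7 + [("T", 30, 60)] * 2 + [("T", 10, 60)]
    sup = count_allele_support(reads, "A", "T")
    assert (sup.ref_count, sup.alt_count, sup.depth) == (7, 2, 9)


def test_zero_thresholds_keep_everything():
    reads = [("A", 0, 0), ("T", 1, 1), ("G", 2, 2)]
    sup = count_allele_support(reads, "A", "T", min_base_qual=0, min_map_qual=0)
    assert sup.depth == 3
    assert (sup.ref_count, sup.alt_count) == (1, 1)  # G counted in depth only


@pytest.mark.parametrize("which", ["base", "map"])
def test_counting_monotone_in_thresholds(which, rng):
    reads = [
        (("A", "T", "G", "C")[int(rng.integers(4))],
         float(rng.integers(0, 60)), float(rng.integers(0, 60)))
        for _ in range(200)
    ]
    prev = None
    for cut in (0, 20, 40, 60):
        kwargs = {"min_base_qual": cut} if which == "base" else {"min_map_qual": cut}
        sup = count_allele_support(reads, "A", "T", **{"min_base_qual": 0, "min_map_qual": 0, **kwargs})
        if prev is not None:
            assert sup.depth <= prev.depth
            assert sup.ref_count <= prev.ref_count
            assert sup.alt_count <= prev.alt_count
        prev = sup


# -- assemble_database -----------------------------------------------------


def support_row(key, tech="pacbio", alt=5, depth=100):
    return (key, TechReadSupport(tech, depth - alt, alt, depth))


def test_low_alt_support_flagged_non_supporting():
    r = rec()
    db = assemble_database([r], [support_row(r.key, alt=1)], min_alt_support=2)
    assert db[0].support["pacbio"].supporting is False
    db2 = assemble_database([r], [support_row(r.key, alt=2)], min_alt_support=2)
    assert db2[0].support["pacbio"].supporting is True


def test_stratum_membership_sets_flags():
    r = rec(pos=100)
    strata = {
        "homopolymer": RegionSet.from_intervals([("chr1", 95, 105)]),
        "low_mappability": RegionSet.from_intervals([("chr1", 99, 100)]),
    }
    db = assemble_database([r], [support_row(r.key)], strata)
    assert db[0].flags.homopolymer is True
    assert db[0].flags.easy_to_map is False  # pos 100 (0-based 99) in low-map


def test_no_strata_means_default_flags():
    r = rec()
    db = assemble_database([r], [support_row(r.key)])
    f = db[0].flags
    assert f == ContextFlags(True, False, False, False)


def test_duplicate_support_rows_error():
    r = rec()
    with pytest.raises(ValueError, match="duplicate"):
        assemble_database([r], [support_row(r.key), support_row(r.key)])


def test_indels_dropped_with_snvs_kept():
    snv, indel = rec(), rec(pos=200, ref="AT", alt="A")
    db = assemble_database([snv, indel], [support_row(snv.key)])
    assert [c.key for c in db] == [snv.key]


def test_output_preserves_input_order():
    records = [rec(pos=p) for p in (500, 100, 300)]
    db = assemble_database(records, [support_row(r.key) for r in records])
    assert [c.pos for c in db] == [500, 100, 300]


def test_database_tsv_round_trip(tmp_path):
    records = [rec(pos=p, tar=p % 7 + 6) for p in (100, 200)]
    rows = []
    for r in records:
        for tech, alt, depth in [("illumina", 30, 300), ("pacbio", 5, 100)]:
            rows.append((r.key, TechReadSupport(tech, depth - alt, alt, depth)))
    db = assemble_database(records, rows,
                           {"homopolymer": RegionSet.from_intervals([("chr1", 150, 250)])})
    path = tmp_path / "db.tsv"
    write_database(db, path)
    again = read_database(path)
    assert [c.key for c in again] == [c.key for c in db]
    for a, b in zip(again, db):
        assert a.support == b.support
        assert a.flags == b.flags
        assert a.tar == b.tar
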