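import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import (
    consensus_oracle,
    filter_overlap_oracle,
    intersect_oracle,
    mask_of,
    merge_oracle,
    random_interval_set,
)
from regmap.errors import ParseError, ValidationError
from regmap.intervals import (
    GenomicInterval,
    IntervalSet,
    consensus,
    filter_overlapping,
    intersect_regions,
    merge,
    overlap_report,
    read_bed,
    write_bed,
)

CHROM = "chrT"
CHROM_LEN = 100_000


def iset(*triples, canonical=False):
    s = IntervalSet([GenomicInterval(*t) for t in triples])
    return s.canonicalize() if canonical else s


# ---------------------------------------------------------------------------
# GenomicInterval basics
# ---------------------------------------------------------------------------

def test_interval_rejects_zero_length():
    with pytest.raises(ValidationError):
        GenomicInterval("chr1", 100, 100)


def test_interval_rejects_negative_start():
    with pytest.raises(ValidationError):
        GenomicInterval("chr1", -5, 10)


def test_overlap_bp():
    a = GenomicInterval("chr1", 0, 100)
    assert a.overlap_bp(GenomicInterval("chr1", 99, 200)) == 1
    assert a.overlap_bp(GenomicInterval("chr1", 100, 200)) == 0
    assert a.overlap_bp(GenomicInterval("chr2", 0, 100)) == 0


# ---------------------------------------------------------------------------
# read_bed / write_bed
# ---------------------------------------------------------------------------

def test_read_bed3_row(tmp_path):
    p = tmp_path / "a.bed"
    p.write_text("chr1\t0\t100\n")
    s = read_bed(p, dialect="bed3")
    assert s.intervals == [GenomicInterval("chr1", 0, 100)]


def test_read_bed_zero_length_is_parse_error(tmp_path):
    p = tmp_path / "a.bed"
    p.write_text("chr1\t100\t100\n")
    with pytest.raises(ParseError, match="line 1"):
        read_bed(p, dialect="bed3")


def test_read_bed_malformed_row_names_line(tmp_path):
    p = tmp_path / "a.bed"
    p.write_text("chr1\t0\t100\nchr1\tnotanumber\t5\n")
    with pytest.raises(ParseError, match="line 2"):
        read_bed(p, dialect="bed3")


def test_read_narrowpeak_signal_to_score(tmp_path):
    p = tmp_path / "a.narrowPeak"
    row = "chr1\t10\t110\tpeak1\t0\t.\t7.5\t12.0\t10.0\t50\n"
    p.write_text(row)
    s = read_bed(p, dialect="narrowPeak")
    assert s[0].score == 7.5
    assert s[0].name == "peak1"


def test_roundtrip_bed3(tmp_path):
    s = iset((CHROM, 0, 100), (CHROM, 200, 300), canonical=True)
    p = tmp_path / "a.bed"
    write_bed(s, p)
    assert read_bed(p, dialect="bed3").intervals == s.intervals


def test_roundtrip_bed6_preserves_names(tmp_path):
    s = IntervalSet([GenomicInterval(CHROM, 0, 100, name="e1", score=3.0),
                     GenomicInterval(CHROM, 200, 300, name="e2", score=4.0)])
    p = tmp_path / "a.bed"
    write_bed(s, p)
    back = read_bed(p, dialect="bed6")
    assert [(iv.name, iv.score) for iv in back] == [("e1", 3.0), ("e2", 4.0)]
    assert back.intervals == s.intervals


def test_write_empty_set(tmp_path):
    p = tmp_path / "a.bed"
    write_bed(IntervalSet([]), p)
    assert p.read_text() == ""
    assert len(read_bed(p, dialect="bed3")) == 0


@settings(max_examples=50, deadline=None)
@given(st.lists(st.tuples(st.integers(0, 5_000), st.integers(1, 500)),
                min_size=0, max_size=15))
def test_roundtrip_random_canonical(tmp_path_factory, pairs):
    ivs = [GenomicInterval(CHROM, s, s + l) for s, l in pairs]
    s = IntervalSet(ivs).canonicalize()
    p = tmp_path_factory.mktemp("rt") / "a.bed"
    write_bed(s, p)
    assert read_bed(p, dialect="bed3").intervals == s.intervals


# ---------------------------------------------------------------------------
# merge
# ---------------------------------------------------------------------------

def test_merge_overlap_always_merges():
    s = iset((CHROM, 0, 100), (CHROM, 90, 200))
    assert merge(s, 0).intervals == [GenomicInterval(CHROM, 0, 200)]


def test_merge_bookended_merge_at_zero_gap():
    s = iset((CHROM, 0, 100), (CHROM, 100, 200))
    assert merge(s, 0).intervals == [GenomicInterval(CHROM, 0, 200)]


def test_merge_gap_at_threshold_merges():
    # gap = 12600 - 100 = 12500 <= 12500  (bedtools -d semantics)
    s = iset((CHROM, 0, 100), (CHROM, 12600, 12700))
    expected = merge_oracle(s, 12500, CHROM, 13_000)
    assert expected == [GenomicInterval(CHROM, 0, 12700)]
    assert merge(s, 12500).intervals == expected


def test_merge_gap_beyond_threshold_splits():
    s = iset((CHROM, 0, 100), (CHROM, 12601, 12700))
    expected = merge_oracle(s, 12500, CHROM, 13_000)
    assert len(expected) == 2
    assert merge(s, 12500).intervals == expected


def test_merge_negative_gap_rejected():
    with pytest.raises(ValidationError):
        merge(iset((CHROM, 0, 10)), -1)


def test_merge_multi_chrom_never_crosses():
    s = iset(("chr1", 0, 100), ("chr2", 50, 200))
    assert len(merge(s, 10**9)) == 2


@settings(max_examples=60, deadline=None)
@given(st.lists(st.tuples(st.integers(0, 20_000), st.integers(1, 3_000)),
                min_size=1, max_size=20),
       st.integers(0, 5_000))
def test_merge_idempotent(pairs, gap):
    s = IntervalSet([GenomicInterval(CHROM, a, a + l) for a, l in pairs])
    once = merge(s, gap)
    assert merge(once, gap).intervals == once.intervals


def test_merge_base_coverage_conservation(rng):
    for _ in range(50):
        s = random_interval_set(rng)
        merged = merge(s, 0)
        assert merged.total_bp() == int(mask_of(s, CHROM, CHROM_LEN).sum())


def test_merge_matches_oracle_randomized(rng):
    for _ in range(100):
        s = random_interval_set(rng)
        gap = int(rng.integers(0, 15_000))
        assert merge(s, gap).intervals == merge_oracle(s, gap, CHROM, CHROM_LEN)


# ---------------------------------------------------------------------------
# intersect_regions
# ---------------------------------------------------------------------------

def test_intersect_simple():
    a = iset((CHROM, 0, 100), canonical=True)
    b = iset((CHROM, 50, 150), canonical=True)
    assert intersect_regions(a, b).intervals == [GenomicInterval(CHROM, 50, 100)]


def test_intersect_disjoint_empty():
    a = iset((CHROM, 0, 100), canonical=True)
    b = iset((CHROM, 200, 300), canonical=True)
    assert len(intersect_regions(a, b)) == 0


def test_intersect_requires_canonical():
    raw = iset((CHROM, 0, 100), (CHROM, 50, 150))
    with pytest.raises(ValidationError):
        intersect_regions(raw, raw)


def test_intersect_matches_mask_oracle(rng):
    for _ in range(100):
        a = random_interval_set(rng, canonical=True)
        b = random_interval_set(rng, canonical=True)
        assert intersect_regions(a, b).intervals == \
            intersect_oracle(a, b, CHROM, CHROM_LEN)


# ---------------------------------------------------------------------------
# filter_overlapping
# ---------------------------------------------------------------------------

def test_filter_one_bp_overlap_retains():
    q = iset((CHROM, 0, 100), canonical=True)
    s = iset((CHROM, 99, 200), canonical=True)
    assert filter_overlapping(q, s).intervals == q.intervals


def test_filter_other_chromosome_empty():
    q = iset(("chr1", 0, 100), canonical=True)
    s = iset(("chr2", 0, 100), canonical=True)
    assert len(filter_overlapping(q, s)) == 0


def test_filter_min_overlap_threshold():
    q = iset((CHROM, 0, 100), canonical=True)
    s = iset((CHROM, 95, 200), canonical=True)
    assert len(filter_overlapping(q, s, min_overlap_bp=5)) == 1
    assert len(filter_overlapping(q, s, min_overlap_bp=6)) == 0


def test_filter_rejects_nonpositive_min_overlap():
    q = iset((CHROM, 0, 10), canonical=True)
    with pytest.raises(ValidationError):
        filter_overlapping(q, q, min_overlap_bp=0)


def test_filter_matches_oracle(rng):
    for _ in range(100):
        q = random_interval_set(rng, canonical=True)
        s = random_interval_set(rng, canonical=True)
        min_ov = int(rng.integers(1, 100))
        got = filter_overlapping(q, s, min_ov).intervals
        assert got == filter_overlap_oracle(q, s, min_ov)


# ---------------------------------------------------------------------------
# consensus
# ---------------------------------------------------------------------------

def test_consensus_identical_sets():
    s = iset((CHROM, 10, 50), canonical=True)
    out = consensus([s, s, s], min_samples=3)
    assert out.intervals == s.intervals


def test_consensus_two_of_three():
    a = iset((CHROM, 10, 50), canonical=True)
    b = iset((CHROM, 20, 60), canonical=True)
    c = iset((CHROM, 5_000, 5_100), canonical=True)
    assert len(consensus([a, b, c], min_samples=3)) == 0
    out = consensus([a, b, c], min_samples=2)
    assert out.intervals == [GenomicInterval(CHROM, 10, 60)]


def test_consensus_min_samples_range():
    s = iset((CHROM, 0, 10), canonical=True)
    with pytest.raises(ValidationError):
        consensus([s], min_samples=2)
    with pytest.raises(ValidationError):
        consensus([s], min_samples=0)
    with pytest.raises(ValidationError):
        consensus([], min_samples=1)


def test_consensus_min1_equals_pooled_merge(rng):
    for _ in range(30):
        sets = [random_interval_set(rng, canonical=True) for _ in range(3)]
        pooled = IntervalSet([iv for s in sets for iv in s])
        assert consensus(sets, 1).intervals == merge(pooled, 0).intervals


def test_consensus_matches_oracle(rng):
    for _ in range(60):
        sets = [random_interval_set(rng, canonical=True) for _ in range(3)]
        for k in (1, 2, 3):
            assert consensus(sets, k).intervals == \
                consensus_oracle(sets, k, CHROM, CHROM_LEN)


# ---------------------------------------------------------------------------
# overlap_report
# ---------------------------------------------------------------------------

def test_overlap_report_three_of_four():
    q = iset((CHROM, 0, 10), (CHROM, 20, 30), (CHROM, 40, 50), (CHROM, 60, 70),
             canonical=True)
    s = iset((CHROM, 5, 45), canonical=True)
    rep = overlap_report(q, s)
    assert (rep.n_query, rep.n_overlapping) == (4, 3)
    assert rep.fraction == 0.75


def test_overlap_report_superset_subject():
    q = iset((CHROM, 0, 10), (CHROM, 20, 30), canonical=True)
    s = iset((CHROM, 0, 1_000), canonical=True)
    assert overlap_report(q, s).fraction == 1.0


def test_overlap_report_empty_query_rejected():
    s = iset((CHROM, 0, 10), canonical=True)
    with pytest.raises(ValidationError):
        overlap_report(IntervalSet([], canonical=True), s)


def test_overlap_report_matches_oracle(rng):
    for _ in range(50):
        q = random_interval_set(rng, canonical=True)
        s = random_interval_set(rng, canonical=True)
        rep = overlap_report(q, s)
        assert rep.n_overlapping == len(filter_overlap_oracle(q, s))
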