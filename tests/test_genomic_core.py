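"""Interval arithmetic, reciprocal overlap, GC content, BED round-trips."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from starr_audit import (
    GenomeSpec,
    GenomicInterval,
    IntervalSet,
    gc_content,
    intersect_length,
    read_intervals,
    reciprocal_overlap,
    write_bed,
)

intervals_st = st.builds(
    lambda s, ln: GenomicInterval("chr1", s, s + ln),
    st.integers(0, 5000),
    st.integers(1, 500),
)


class TestReciprocalOverlap:
    @pytest.mark.parametrize(
        "a, b, threshold, expected",
        [
            # boundary: overlap exactly half of both lengths passes (inclusive)
            (("chr1", 100, 200), ("chr1", 150, 250), 0.5, True),
            # asymmetric lengths: only 10% of the long interval overlaps
            (("chr1", 0, 1000), ("chr1", 400, 500), 0.5, False),
            # identity
            (("chr1", 5, 50), ("chr1", 5, 50), 1.0, True),
            # different chromosomes never overlap
            (("chr1", 0, 100), ("chr2", 0, 100), 0.5, False),
            # spec worked pair: peak 200 bp vs CRM 200 bp, 50 bp overlap
            (("chr1", 250, 450), ("chr1", 100, 300), 0.5, False),
            (("chr1", 150, 350), ("chr1", 100, 300), 0.5, True),
        ],
    )
    def test_examples(self, a, b, threshold, expected):
        assert reciprocal_overlap(GenomicInterval(*a), GenomicInterval(*b), threshold) is expected

    @given(intervals_st, intervals_st, st.floats(0.01, 1.0))
    def test_symmetry(self, a, b, threshold):
        assert reciprocal_overlap(a, b, threshold) == reciprocal_overlap(b, a, threshold)

    def test_invalid_threshold(self):
        iv = GenomicInterval("chr1", 0, 10)
        with pytest.raises(ValueError):
            reciprocal_overlap(iv, iv, 0.0)


class TestIntervalSet:
    def test_intersect_examples(self):
        a = IntervalSet([GenomicInterval("chr1", 0, 100)])
        b = IntervalSet([GenomicInterval("chr1", 50, 150)])
        assert intersect_length(a, b) == 50
        assert intersect_length(a, a) == a.total_length()
        assert intersect_length(a, IntervalSet([GenomicInterval("chr2", 0, 100)])) == 0

    @given(st.lists(intervals_st, max_size=30))
    def test_merge_idempotent(self, ivs):
        s = IntervalSet(ivs)
        merged = s.merge()
        assert [(i.start, i.end) for i in merged.merge()] == [
            (i.start, i.end) for i in merged
        ]
        assert s.total_length() <= sum(iv.length() for iv in ivs)

    @given(st.lists(intervals_st, max_size=25), st.lists(intervals_st, max_size=25))
    def test_base_count_conservation(self, a_ivs, b_ivs):
        a, b = IntervalSet(a_ivs), IntervalSet(b_ivs)
        assert intersect_length(a, b) + a.subtract(b).total_length() == a.total_length()
        assert intersect_length(a, b) == intersect_length(b, a)

    @given(st.lists(intervals_st, max_size=25), st.lists(intervals_st, max_size=25))
    def test_union_matches_counting(self, a_ivs, b_ivs):
        a, b = IntervalSet(a_ivs), IntervalSet(b_ivs)
        assert (
            a.union(b).total_length()
            == a.total_length() + b.total_length() - intersect_length(a, b)
        )

    def test_overlap_bp_against_intersect(self, rng):
        ivs = [
            GenomicInterval("chr1", int(s), int(s) + int(l))
            for s, l in zip(rng.integers(0, 9000, 50), rng.integers(1, 300, 50))
        ]
        s = IntervalSet(ivs)
        for q_start, q_len in zip(rng.integers(0, 9000, 20), rng.integers(1, 500, 20)):
            q = GenomicInterval("chr1", int(q_start), int(q_start) + int(q_len))
            expected = intersect_length(s, IntervalSet([q]))
            assert s.overlap_bp(q.chrom, q.start, q.end) == expected

    def test_invalid_interval_rejected(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 20, 10)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", -5, 10)


class TestGcContent:
    @pytest.mark.parametrize(
        "seq, expected",
        [("GGCC", 1.0), ("ACGT", 0.5), ("ANGT", 1 / 3), ("acgt", 0.5)],
    )
    def test_values(self, seq, expected):
        assert gc_content(seq) == pytest.approx(expected)

    def test_all_n_is_nan(self):
        assert np.isnan(gc_content("NNNN"))
        assert np.isnan(gc_content(""))


class TestBedIo:
    def test_round_trip_exact(self, tmp_path, rng):
        ivs = IntervalSet(
            GenomicInterval(
                f"chr{int(c)}", int(s), int(s) + int(l), id=f"x{k}", score=float(k), strand="+"
            )
            for k, (c, s, l) in enumerate(
                zip(rng.integers(1, 4, 30), rng.integers(0, 10_000, 30), rng.integers(1, 900, 30))
            )
        )
        path = tmp_path / "a.bed"
        write_bed(ivs, path)
        back = read_intervals(path)
        assert [(i.chrom, i.start, i.end, i.id) for i in back] == [
            (i.chrom, i.start, i.end, i.id) for i in ivs
        ]

    def test_bed6_parse(self, tmp_path):
        p = tmp_path / "b.bed"
        p.write_text("chr1\t10\t20\tx\t0\t+\n")
        (iv,) = read_intervals(p)
        assert (iv.chrom, iv.start, iv.end, iv.id, iv.strand) == ("chr1", 10, 20, "x", "+")

    def test_invalid_coordinates_error_names_line(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t5\t9\nchr1\t20\t10\n")
        with pytest.raises(ValueError, match=":2"):
            read_intervals(p)

    def test_empty_file(self, tmp_path):
        p = tmp_path / "empty.bed"
        p.write_text("")
        assert len(read_intervals(p)) == 0

    def test_unknown_chrom_needs_alias(self, tmp_path):
        p = tmp_path / "c.bed"
        p.write_text("1\t0\t10\n")
        genome = GenomeSpec({"chr1": 1000})
        with pytest.raises(ValueError, match="unknown chromosome"):
            read_intervals(p, genome)
        s = read_intervals(p, genome, chrom_aliases={"1": "chr1"})
        assert s.intervals[0].chrom == "chr1"


def test_pyranges_agrees_on_intersection_length(rng):
    """Independent cross-check of base-level intersection against pyranges."""
    import pandas as pd
    import pyranges as pr

    def random_set(n):
        starts = rng.integers(0, 50_000, n)
        lengths = rng.integers(1, 2_000, n)
        return [
            GenomicInterval("chr1", int(s), int(s + l))
            for s, l in zip(starts, lengths)
        ]

    a_ivs, b_ivs = random_set(80), random_set(80)
    ours = intersect_length(IntervalSet(a_ivs), IntervalSet(b_ivs))

    def to_pr(ivs):
        return pr.PyRanges(
            pd.DataFrame(
                {
                    "Chromosome": [i.chrom for i in ivs],
                    "Start": [i.start for i in ivs],
                    "End": [i.end for i in ivs],
                }
            )
        ).merge()

    joined = to_pr(a_ivs).intersect(to_pr(b_ivs)).merge()
    theirs = int((joined.End - joined.Start).sum()) if len(joined) else 0
    assert ours == theirs
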