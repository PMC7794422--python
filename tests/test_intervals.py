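"""Interval model, BED parsing, merging, consensus and co-occupancy."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import (
    as_peakset,
    brute_consensus_regions,
    brute_cooccupancy_counts,
    brute_merge,
    paint,
    random_intervals,
)
from tadtargets import (
    BedParseError,
    GenomicInterval,
    Peak,
    PeakSet,
    classify_cooccupancy,
    consensus_peaks,
    merge_intervals,
    read_bed,
    write_bed,
)


class TestModel:
    def test_interval_invariants(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 200, 100)
        with pytest.raises(ValueError):
            GenomicInterval("", 0, 10)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 0, 10, "x")
        iv = GenomicInterval("chr1", 100, 200)
        assert iv.length == 100 and iv.midpoint == 150

    def test_peak_summit_bounds(self):
        iv = GenomicInterval("chr1", 100, 200)
        assert Peak(iv, summit=50).summit == 50
        with pytest.raises(ValueError):
            Peak(iv, summit=100)

    def test_peakset_requires_factor(self):
        with pytest.raises(ValueError):
            PeakSet([], {})


class TestReadBed:
    def test_basic_line(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t100\t200\n")
        (iv,) = read_bed(p)
        assert iv == GenomicInterval("chr1", 100, 200)

    def test_inverted_coordinates_name_the_line(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t200\t100\n")
        with pytest.raises(BedParseError, match="line 1"):
            read_bed(p)

    def test_track_header_tolerated(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("track name=x\nchr1\t0\t10\nchr2\t5\t15\n")
        assert len(read_bed(p)) == 2

    def test_peak_kind_round_trip(self, tmp_path):
        p = tmp_path / "a.bed"
        peaks = PeakSet(
            [Peak(GenomicInterval("chr1", 5, 50), score=3.25, name="p1")],
            {"factor": "tf"},
        )
        write_bed(peaks, p)
        back = read_bed(p, kind="peak", meta={"factor": "tf"})
        assert back.peaks == peaks.peaks


class TestMerge:
    @pytest.mark.parametrize(
        "spans,min_gap,expected",
        [
            ([(100, 200), (150, 250)], 0, [(100, 250)]),
            ([(100, 200), (300, 400)], 50, [(100, 200), (300, 400)]),
            ([], 0, []),
            ([(100, 200), (200, 300)], 0, [(100, 300)]),  # touching
            ([(100, 200), (240, 300)], 40, [(100, 300)]),  # gap == min_gap
        ],
    )
    def test_examples(self, spans, min_gap, expected):
        ivs = [GenomicInterval("chr1", s, e) for s, e in spans]
        got = merge_intervals(ivs, min_gap)
        assert [(iv.start, iv.end) for iv in got] == expected

    def test_negative_gap_rejected(self):
        with pytest.raises(ValueError):
            merge_intervals([], -1)

    def test_matches_per_base_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(300):
            ivs = random_intervals(rng)
            gap = int(rng.integers(0, 500))
            assert merge_intervals(ivs, gap) == brute_merge(ivs, gap)

    @settings(derandomize=True, max_examples=100)
    @given(
        st.lists(
            st.tuples(st.integers(0, 5_000), st.integers(1, 400)),
            max_size=30,
        ),
        st.integers(0, 100),
    )
    def test_output_disjoint_and_coverage_preserving(self, raw, gap):
        ivs = [GenomicInterval("chr1", s, s + w) for s, w in raw]
        merged = merge_intervals(ivs, gap)
        for prev, cur in zip(merged, merged[1:]):
            assert prev.end + gap < cur.start
        if ivs:
            assert (paint(ivs, 10_000) <= paint(merged, 10_000)).all()


class TestConsensus:
    def test_two_of_three_example(self):
        a = as_peakset([GenomicInterval("chr1", 100, 200)], label="A")
        b = as_peakset([GenomicInterval("chr1", 150, 250)], label="B")
        c = as_peakset([GenomicInterval("chr1", 400, 500)], label="C")
        got = consensus_peaks([a, b, c], k=2)
        assert [(p.start, p.end) for p in got] == [(150, 200)]
        assert got.peaks[0].name == "A,B"

    def test_single_set_identity(self):
        a = as_peakset(
            [GenomicInterval("chr1", 10, 20), GenomicInterval("chr1", 15, 30)]
        )
        got = consensus_peaks([a], k=1)
        assert [(p.start, p.end) for p in got] == [(10, 30)]

    def test_disjoint_sets_empty(self):
        sets = [
            as_peakset([GenomicInterval("chr1", i * 1000, i * 1000 + 100)])
            for i in range(3)
        ]
        assert len(consensus_peaks(sets, k=2)) == 0

    @pytest.mark.parametrize("k", [0, 4])
    def test_k_out_of_range(self, k):
        sets = [as_peakset([GenomicInterval("chr1", 0, 10)])] * 3
        with pytest.raises(ValueError):
            consensus_peaks(sets, k)

    def test_mixed_factor_warns(self):
        a = as_peakset([GenomicInterval("chr1", 0, 10)], factor="x")
        b = as_peakset([GenomicInterval("chr1", 0, 10)], factor="y")
        with pytest.warns(UserWarning, match="mixed factors"):
            consensus_peaks([a, b], 1)

    def test_matches_per_base_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            n = int(rng.integers(2, 5))
            sets = [random_intervals(rng, n_max=20) for _ in range(n)]
            k = int(rng.integers(1, n + 1))
            got = consensus_peaks(
                [as_peakset(ivs, label=f"S{i}") for i, ivs in enumerate(sets)], k
            )
            assert [p.interval for p in got] == brute_consensus_regions(sets, k)

    def test_monotone_in_k(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            sets = [
                as_peakset(random_intervals(rng, n_max=15), label=f"S{i}")
                for i in range(3)
            ]
            cov = {
                k: paint([p.interval for p in consensus_peaks(sets, k)])
                for k in (1, 2, 3)
            }
            assert (cov[2] <= cov[1]).all() and (cov[3] <= cov[2]).all()

    def test_identical_sets_give_merged_set_for_every_k(self):
        rng = np.random.default_rng(3)
        ivs = random_intervals(rng, n_max=15)
        if not ivs:
            ivs = [GenomicInterval("chr1", 5, 50)]
        merged = merge_intervals(ivs, 0)
        sets = [as_peakset(ivs, label=f"S{i}") for i in range(3)]
        for k in (1, 2, 3):
            assert [p.interval for p in consensus_peaks(sets, k)] == merged

    def test_union_mode_covers_depth_mode(self):
        a = as_peakset([GenomicInterval("chr1", 100, 200)], label="A")
        b = as_peakset([GenomicInterval("chr1", 150, 250)], label="B")
        depth = consensus_peaks([a, b], 2, mode="depth")
        union = consensus_peaks([a, b], 2, mode="union")
        assert [(p.start, p.end) for p in depth] == [(150, 200)]
        assert [(p.start, p.end) for p in union] == [(100, 250)]


class TestCooccupancy:
    def test_overlap_counts_from_a_side(self):
        a = as_peakset([GenomicInterval("chr1", 100, 200)], factor="A")
        b = as_peakset([GenomicInterval("chr1", 150, 250)], factor="B")
        assert classify_cooccupancy(a, b).counts == (0, 0, 1)

    def test_disjoint_singletons(self):
        a = as_peakset([GenomicInterval("chr1", 0, 10)], factor="A")
        b = as_peakset([GenomicInterval("chr1", 100, 110)], factor="B")
        assert classify_cooccupancy(a, b).counts == (1, 1, 0)

    def test_self_classification_all_shared(self):
        rng = np.random.default_rng(4)
        a = as_peakset(random_intervals(rng, n_max=20) or
                       [GenomicInterval("chr1", 0, 10)], factor="A")
        venn = classify_cooccupancy(a, a)
        assert venn.counts == (0, 0, len(a))

    def test_min_overlap_threshold(self):
        a = as_peakset([GenomicInterval("chr1", 0, 100)], factor="A")
        b = as_peakset([GenomicInterval("chr1", 95, 200)], factor="B")
        assert classify_cooccupancy(a, b, min_overlap=5).counts == (0, 0, 1)
        assert classify_cooccupancy(a, b, min_overlap=6).counts == (1, 1, 0)

    def test_partition_and_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            a_ivs = random_intervals(rng, n_max=25)
            b_ivs = random_intervals(rng, n_max=25)
            min_ov = int(rng.integers(1, 50))
            venn = classify_cooccupancy(
                as_peakset(a_ivs, factor="A"),
                as_peakset(b_ivs, factor="B"),
                min_ov,
            )
            n_a_only, n_b_only, n_shared = venn.counts
            assert n_a_only + n_shared == len(a_ivs)
            assert venn.counts == brute_cooccupancy_counts(a_ivs, b_ivs, min_ov)
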