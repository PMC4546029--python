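"""CAGE orientation, cell breadth, chromatin flags and RNA-seq support."""

from __future__ import annotations

import numpy as np
import pytest

from uest.config import FilterConfig
from uest.core import GenomicInterval
from uest.est_preprocess import UESTCluster
from uest.evidence import (
    ChromatinSegment,
    Orientation,
    TSSPeak,
    breadth_histogram,
    cell_breadth,
    chromatin_support,
    orient_by_cage,
    rnaseq_support,
    sense_antisense,
)
from uest.io_formats import CoverageTrack


def cl(s, e, cid="c1", chrom="chr1"):
    return UESTCluster(cid, GenomicInterval(chrom, s, e), ("a", "b", "c"))


def peak(s, e, strand, chrom="chr1"):
    return TSSPeak(GenomicInterval(chrom, s, e, strand))


class TestOrientByCage:
    def test_forward_peak_in_first_window(self):
        assert orient_by_cage(cl(1000, 3000), [peak(1010, 1020, "+")]) \
            is Orientation.FORWARD

    def test_both_ends_is_bidirectional(self):
        peaks = [peak(1010, 1020, "+"), peak(2990, 2995, "-")]
        assert orient_by_cage(cl(1000, 3000), peaks) is Orientation.BIDIRECTIONAL

    def test_peak_just_past_window_boundary_ignored(self):
        # forward window is [1000, 1084); a + peak at 1084 misses it
        assert orient_by_cage(cl(1000, 3000), [peak(1084, 1090, "+")]) \
            is Orientation.NONE
        assert orient_by_cage(cl(1000, 3000), [peak(1083, 1090, "+")]) \
            is Orientation.FORWARD

    def test_strand_and_end_must_agree(self):
        # a - peak at the start window orients nothing
        assert orient_by_cage(cl(1000, 3000), [peak(1010, 1020, "-")]) \
            is Orientation.NONE
        assert orient_by_cage(cl(1000, 3000), [peak(2990, 2995, "+")]) \
            is Orientation.NONE

    def test_short_cluster_windows_are_clipped(self):
        # 40-nt cluster: both windows equal the whole cluster
        assert orient_by_cage(cl(100, 140), [peak(120, 125, "+")]) \
            is Orientation.FORWARD
        assert orient_by_cage(cl(100, 140), [peak(120, 125, "-")]) \
            is Orientation.REVERSE

    def test_random_layout_matches_all_pairs_oracle(self):
        rng = np.random.default_rng(5)
        w = FilterConfig().cage_window_nt
        clusters = [
            cl(int(s), int(s) + int(rng.integers(30, 3000)), f"c{i}")
            for i, s in enumerate(rng.integers(0, 200_000, 120))
        ]
        peaks = [
            peak(int(s), int(s) + int(rng.integers(1, 30)),
                 "+" if rng.random() < 0.5 else "-")
            for s in rng.integers(0, 200_000, 300)
        ]
        for c in clusters:
            s, e = c.interval.start, c.interval.end
            fwd = any(
                p.interval.strand == "+"
                and p.interval.start < min(e, s + w) and p.interval.end > s
                for p in peaks)
            rev = any(
                p.interval.strand == "-"
                and p.interval.start < e and p.interval.end > max(s, e - w)
                for p in peaks)
            expected = (
                Orientation.BIDIRECTIONAL if fwd and rev
                else Orientation.FORWARD if fwd
                else Orientation.REVERSE if rev
                else Orientation.NONE)
            assert orient_by_cage(c, peaks) is expected

    def test_monotone_in_evidence(self):
        """Adding peaks never knocks a forward/reverse call down to none."""
        c = cl(1000, 3000)
        base = [peak(1010, 1020, "+")]
        assert orient_by_cage(c, base) is Orientation.FORWARD
        more = base + [peak(1030, 1040, "+"), peak(500, 600, "-")]
        assert orient_by_cage(c, more) is Orientation.FORWARD
        # adding an opposite-end peak can only escalate to bidirectional
        assert orient_by_cage(c, more + [peak(2990, 2999, "-")]) \
            is Orientation.BIDIRECTIONAL


class TestCellBreadth:
    def test_counts_orienting_cells_only(self):
        c = cl(1000, 3000)
        cells = {
            "cellA": [peak(1010, 1020, "+")],                      # forward
            "cellB": [peak(2990, 2995, "-")],                      # reverse
            "cellC": [peak(1010, 1020, "+"), peak(2990, 2995, "-")],  # bidir
            "cellD": [],                                           # none
        }
        assert cell_breadth(c, cells) == 2

    def test_permutation_invariance_and_histogram_total(self):
        rng = np.random.default_rng(9)
        clusters = [cl(int(s), int(s) + 500, f"c{i}")
                    for i, s in enumerate(range(0, 50_000, 1000))]
        cells = {}
        for name in ("x", "y", "z"):
            cells[name] = [
                peak(c.interval.start + 5, c.interval.start + 15, "+")
                for c in clusters if rng.random() < 0.5
            ]
        breadth, hist = breadth_histogram(clusters, cells)
        reordered = dict(reversed(list(cells.items())))
        breadth2, hist2 = breadth_histogram(clusters, reordered)
        assert breadth == breadth2 and hist == hist2
        assert sum(hist.values()) == sum(1 for b in breadth.values() if b >= 1)


class TestChromatinSupport:
    def test_single_cell_line_sets_flag(self):
        c = cl(1000, 2000)
        segs = [ChromatinSegment(GenomicInterval("chr1", 1500, 1600), "T", "K562")]
        got = chromatin_support(c, segs)
        assert got.has_t_state and not got.has_tss_state

    def test_no_overlap_means_no_flags(self):
        c = cl(1000, 2000)
        segs = [ChromatinSegment(GenomicInterval("chr1", 3000, 4000), "TSS", "a")]
        got = chromatin_support(c, segs)
        assert not got.has_t_state and not got.has_tss_state and not got.active

    def test_adding_cell_lines_never_clears_flags(self):
        c = cl(1000, 2000)
        segs = [ChromatinSegment(GenomicInterval("chr1", 1100, 1200), "TSS", "a")]
        first = chromatin_support(c, segs)
        extra = segs + [
            ChromatinSegment(GenomicInterval("chr1", 1300, 1400), "R", "b"),
            ChromatinSegment(GenomicInterval("chr1", 1500, 1700), "T", "b"),
        ]
        second = chromatin_support(c, extra)
        assert first.has_tss_state and second.has_tss_state and second.has_t_state

    def test_random_layout_matches_oracle(self):
        rng = np.random.default_rng(13)
        states = ("TSS", "PF", "E", "WE", "CTCF", "T", "R")
        segs = [
            ChromatinSegment(
                GenomicInterval("chr1", int(s), int(s) + int(rng.integers(50, 500))),
                states[int(rng.integers(len(states)))], f"cl{int(rng.integers(3))}")
            for s in rng.integers(0, 100_000, 200)
        ]
        for i, s in enumerate(rng.integers(0, 100_000, 50)):
            c = cl(int(s), int(s) + 800, f"c{i}")
            got = chromatin_support(c, segs)
            tss = any(x.state == "TSS" and x.interval.overlaps(c.interval) for x in segs)
            t = any(x.state == "T" and x.interval.overlaps(c.interval) for x in segs)
            assert (got.has_tss_state, got.has_t_state) == (tss, t)

    def test_unknown_state_rejected(self):
        with pytest.raises(ValueError, match="unknown chromatin state"):
            ChromatinSegment(GenomicInterval("chr1", 0, 10), "ENH", "a")


class TestRnaseqSupport:
    def test_exactly_ten_reads_in_one_library_supports(self):
        c = cl(1000, 2000)
        track = CoverageTrack({"chr1": [(1100, 1200, 10.0)]})
        assert rnaseq_support([c], [track]) == {"c1": True}

    def test_nine_reads_in_each_of_five_libraries_does_not(self):
        """The threshold is per library; libraries are never pooled."""
        c = cl(1000, 2000)
        tracks = [CoverageTrack({"chr1": [(1100, 1200, 9.0)]}) for _ in range(5)]
        assert rnaseq_support([c], tracks) == {"c1": False}

    def test_counts_sum_within_a_library(self):
        c = cl(1000, 2000)
        track = CoverageTrack({"chr1": [(900, 1100, 6.0), (1500, 1600, 4.0)]})
        assert rnaseq_support([c], [track]) == {"c1": True}

    def test_random_tracks_match_oracle_summation(self):
        rng = np.random.default_rng(21)
        clusters = [cl(int(s), int(s) + 700, f"c{i}")
                    for i, s in enumerate(rng.integers(0, 50_000, 40))]
        tracks = []
        for _ in range(3):
            t = CoverageTrack()
            pos = 0
            while pos < 60_000:
                length = int(rng.integers(100, 800))
                t.add("chr1", pos, pos + length, float(rng.integers(0, 8)))
                pos += length + int(rng.integers(1, 300))
            t._finalize()
            tracks.append(t)
        got = rnaseq_support(clusters, tracks)
        for c in clusters:
            expected = any(
                sum(v for s, e, v in t.runs("chr1")
                    if s < c.interval.end and e > c.interval.start) >= 10
                for t in tracks)
            assert got[c.cluster_id] == expected


def test_sense_antisense_derivation():
    assert sense_antisense(Orientation.FORWARD, "+") == "sense"
    assert sense_antisense(Orientation.FORWARD, "-") == "antisense"
    assert sense_antisense(Orientation.REVERSE, "-") == "sense"
    assert sense_antisense(Orientation.BIDIRECTIONAL, "+") == "ambiguous"
    assert sense_antisense(Orientation.NONE, "+") == "unknown"
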