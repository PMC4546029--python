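"""Chain lifting and cross-species cluster pairing."""

from __future__ import annotations

import numpy as np
import pytest

from uest.core import GenomicInterval
from uest.est_preprocess import UESTCluster
from uest.io_formats import ChainAlignment
from uest.orthology import (
    class_pair_matrix,
    conservation_summary,
    lift_interval,
    pair_orthologs,
)

from oracles import lift_oracle


def chain(blocks, src=("chrA", 10_000, 0, None), tgt=("chrB", 10_000, 0, None),
          tgt_strand="+", chain_id="1"):
    src_span = sum(b[0] + b[1] for b in blocks)
    tgt_span = sum(b[0] + b[2] for b in blocks)
    return ChainAlignment(
        chain_id=chain_id, score=100,
        src_chrom=src[0], src_size=src[1], src_strand="+",
        src_start=src[2], src_end=src[2] + src_span,
        tgt_chrom=tgt[0], tgt_size=tgt[1], tgt_strand=tgt_strand,
        tgt_start=tgt[2], tgt_end=tgt[2] + tgt_span,
        blocks=tuple(blocks),
    )


def iv(s, e, chrom="chrA"):
    return GenomicInterval(chrom, s, e)


IDENTITY = chain([(1000, 0, 0)])


class TestLiftInterval:
    def test_identity_chain_is_identity(self):
        assert lift_interval(iv(100, 200), [IDENTITY]) == iv(100, 200, "chrB")

    def test_constant_offset(self):
        c = chain([(500, 0, 0)], tgt=("chrB", 10_000, 2000, None))
        assert lift_interval(iv(100, 150), [c]) == iv(2100, 2150, "chrB")

    def test_target_gap_grows_the_span(self):
        # 50-nt target-side insertion in the middle of the interval: every
        # source base maps, but the target hull is 50 nt longer
        c = chain([(150, 0, 50), (850, 0, 0)])
        got = lift_interval(iv(100, 200), [c])
        assert got == iv(100, 250, "chrB")

    def test_interval_inside_source_gap_is_unmappable(self):
        c = chain([(100, 200, 0), (700, 0, 0)])
        assert lift_interval(iv(120, 180), [c]) is None

    def test_source_gap_fraction_threshold(self):
        # 40 of 100 bases deleted: mapped fraction 0.6
        c = chain([(130, 40, 0), (830, 0, 0)])
        assert lift_interval(iv(100, 200), [c], min_mapped_frac=0.95) is None
        assert lift_interval(iv(100, 200), [c], min_mapped_frac=0.5) is not None

    def test_multiple_qualifying_chains_rejected(self):
        chains = [IDENTITY, chain([(1000, 0, 0)], tgt=("chrC", 10_000, 5000, None),
                                  chain_id="2")]
        assert lift_interval(iv(100, 200), chains) is None

    def test_minus_strand_target_reported_forward(self):
        c = chain([(1000, 0, 0)], tgt=("chrB", 1000, 0, None), tgt_strand="-")
        got = lift_interval(iv(100, 200), [c])
        assert got == iv(800, 900, "chrB")
        assert lift_oracle(iv(100, 200), [c]) == ("chrB", 800, 900)

    @pytest.mark.parametrize("seed", range(15))
    def test_random_indel_chains_match_per_base_mapper(self, seed):
        rng = np.random.default_rng(seed)
        chains = []
        for ci in range(int(rng.integers(1, 4))):
            blocks = []
            for _ in range(int(rng.integers(1, 6))):
                blocks.append((int(rng.integers(20, 300)),
                               int(rng.integers(0, 60)),
                               int(rng.integers(0, 60))))
            blocks.append((int(rng.integers(20, 300)), 0, 0))
            chains.append(chain(
                blocks,
                src=("chrA", 50_000, int(rng.integers(0, 5000)), None),
                tgt=("chrB", 50_000, int(rng.integers(0, 5000)), None),
                tgt_strand="-" if rng.random() < 0.3 else "+",
                chain_id=str(ci)))
        for _ in range(40):
            s = int(rng.integers(0, 6000))
            interval = iv(s, s + int(rng.integers(10, 500)))
            for frac in (0.95, 0.5):
                assert lift_interval(interval, chains, frac) == (
                    lambda r: None if r is None else iv(r[1], r[2], r[0])
                )(lift_oracle(interval, chains, frac))

    def test_round_trip_through_exact_inverse_chains(self):
        fwd = chain([(200, 10, 0), (300, 0, 25), (500, 0, 0)])
        inv_blocks = [(200, 0, 10), (300, 25, 0), (500, 0, 0)]
        inv = chain(inv_blocks, src=("chrB", 10_000, 0, None),
                    tgt=("chrA", 10_000, 0, None))
        original = iv(50, 180)
        there = lift_interval(original, [fwd])
        back = lift_interval(iv(there.start, there.end, "chrB"), [inv])
        assert back is not None
        assert back.start <= original.start and original.end <= back.end


def uc(cid, s, e, chrom):
    return UESTCluster(cid, GenomicInterval(chrom, s, e), ("x", "y", "z"))


class TestPairOrthologs:
    def test_overlap_after_identity_lift(self):
        a = [uc("a1", 100, 200, "chrA")]
        b = [uc("b1", 150, 250, "chrB")]
        inv = chain([(1000, 0, 0)], src=("chrB", 10_000, 0, None),
                    tgt=("chrA", 10_000, 0, None))
        (p,) = pair_orthologs(a, b, [IDENTITY], [inv])
        assert (p.cluster_a_id, p.cluster_b_id, p.detected_by) == ("a1", "b1", "both")

    def test_pair_found_by_one_direction_only_is_kept(self):
        a = [uc("a1", 100, 200, "chrA")]
        b = [uc("b1", 150, 250, "chrB")]
        inv = chain([(1000, 0, 0)], src=("chrB", 10_000, 0, None),
                    tgt=("chrA", 10_000, 0, None))
        (p,) = pair_orthologs(a, b, [], [inv])  # no A→B chains at all
        assert p.detected_by == "B->A"

    def test_union_is_superset_of_each_direction(self):
        rng = np.random.default_rng(2)
        a = [uc(f"a{i}", int(s), int(s) + 150, "chrA")
             for i, s in enumerate(rng.integers(0, 9000, 25))]
        b = [uc(f"b{i}", int(s), int(s) + 150, "chrB")
             for i, s in enumerate(rng.integers(0, 9000, 25))]
        big = chain([(9500, 0, 0)])
        big_inv = chain([(9500, 0, 0)], src=("chrB", 10_000, 0, None),
                        tgt=("chrA", 10_000, 0, None))
        both_dirs = {(p.cluster_a_id, p.cluster_b_id)
                     for p in pair_orthologs(a, b, [big], [big_inv])}
        only_ab = {(p.cluster_a_id, p.cluster_b_id)
                   for p in pair_orthologs(a, b, [big], [])}
        only_ba = {(p.cluster_a_id, p.cluster_b_id)
                   for p in pair_orthologs(a, b, [], [big_inv])}
        assert only_ab <= both_dirs and only_ba <= both_dirs
        assert both_dirs == only_ab | only_ba

    def test_same_class_flag(self):
        a = [uc("a1", 100, 200, "chrA")]
        b = [uc("b1", 100, 200, "chrB")]
        inv = chain([(1000, 0, 0)], src=("chrB", 10_000, 0, None),
                    tgt=("chrA", 10_000, 0, None))
        (p,) = pair_orthologs(a, b, [IDENTITY], [inv],
                              classes_a={"a1": "TIN"}, classes_b={"b1": "TIN"})
        assert p.same_class is True
        (q,) = pair_orthologs(a, b, [IDENTITY], [inv],
                              classes_a={"a1": "TIN"}, classes_b={"b1": "TEX"})
        assert q.same_class is False


class TestSummaries:
    def test_distinct_and_unpaired_counts(self):
        from uest.orthology import OrthologPair
        pairs = [OrthologPair("a1", "b1", "both", True),
                 OrthologPair("a1", "b2", "A->B", False),
                 OrthologPair("a2", "b3", "B->A", True)]
        a = [uc(f"a{i}", i * 100, i * 100 + 50, "chrA") for i in range(1, 5)]
        b = [uc(f"b{i}", i * 100, i * 100 + 50, "chrB") for i in range(1, 5)]
        got = conservation_summary(pairs, a, b)
        assert got == {
            "n_pairs": 3, "n_distinct_a": 2, "n_distinct_b": 3,
            "n_same_class": 2, "n_unpaired_a": 2, "n_unpaired_b": 1,
        }
        empty = conservation_summary([], a, b)
        assert empty["n_unpaired_a"] == 4 and empty["n_unpaired_b"] == 4

    def test_class_pair_matrix(self):
        from uest.orthology import OrthologPair
        pairs = [OrthologPair("a1", "b1", "both"), OrthologPair("a2", "b2", "both")]
        m = class_pair_matrix(pairs, {"a1": "TIN", "a2": "TIN"},
                              {"b1": "TIN", "b2": "TEX"})
        assert m == {"TIN": {"TIN": 1, "TEX": 1}}
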