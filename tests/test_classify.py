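"""Cluster classification: rule table, thresholds, conflict resolution."""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pytest

from uest.classify import (
    ClusterClass,
    FLANK_CLASSES,
    GENIC_CLASSES,
    class_summary,
    classify_cluster,
    classify_vs_gene,
    resolve_classes,
)
from uest.config import FilterConfig
from uest.core import GenomicInterval
from uest.est_preprocess import UESTCluster
from uest.gene_model import GeneModel, build_components

from oracles import classify_oracle


def make_gene(exons, cds=None, strand="+", chrom="chr1", gene_id="g"):
    return build_components(GeneModel(
        gene_id, GenomicInterval(chrom, exons[0][0], exons[-1][1], strand),
        exons=tuple(exons), cds=cds))


def cl(s, e, chrom="chr1"):
    return UESTCluster("c", GenomicInterval(chrom, s, e), ("a", "b", "c"))


GENE = make_gene([(100, 200), (300, 400)], cds=(150, 350))          # + strand
GENE_MINUS = make_gene([(100, 200), (300, 400)], cds=(150, 350), strand="-")


class TestRuleTable:
    def test_cluster_inside_intron_is_tin(self):
        assert classify_vs_gene(cl(210, 290), GENE) is ClusterClass.TIN

    def test_exon_overlap_of_exactly_20_does_not_count(self):
        # exon overlap [180,200) is exactly 20 nt: NOT > 20 → intron only
        assert classify_vs_gene(cl(180, 250), GENE) is ClusterClass.TIN

    def test_two_small_exon_overlaps_still_tin(self):
        # 10 nt into each flanking exon, 100 nt of intron
        assert classify_vs_gene(cl(190, 310), GENE) is ClusterClass.TIN

    def test_exon_overlap_of_21_makes_pin(self):
        assert classify_vs_gene(cl(179, 250), GENE) is ClusterClass.PIN5

    def test_pin_sides_follow_gene_strand(self):
        # exon1 + intron: exon is 5' of the intron on +, 3' on -
        assert classify_vs_gene(cl(150, 250), GENE) is ClusterClass.PIN5
        assert classify_vs_gene(cl(150, 250), GENE_MINUS) is ClusterClass.PIN3
        assert classify_vs_gene(cl(250, 350), GENE) is ClusterClass.PIN3
        assert classify_vs_gene(cl(250, 350), GENE_MINUS) is ClusterClass.PIN5

    def test_totally_exonic_and_retained_intron(self):
        assert classify_vs_gene(cl(110, 190), GENE) is ClusterClass.TEX
        assert classify_vs_gene(cl(130, 370), GENE) is ClusterClass.RI

    def test_two_introns_is_no_class(self):
        # middle exon plus > 20 nt of both surrounding introns
        gene3 = make_gene([(100, 200), (300, 400), (500, 600)], cds=(150, 550))
        assert classify_vs_gene(cl(250, 450), gene3) is ClusterClass.NO_CLASS

    def test_flank_classes(self):
        assert classify_vs_gene(cl(20, 95), GENE) is ClusterClass.UT
        assert classify_vs_gene(cl(2000, 2200), GENE) is ClusterClass.DT
        # swapped on the minus strand gene (same geometry)
        assert classify_vs_gene(cl(20, 95), GENE_MINUS) is ClusterClass.DT
        assert classify_vs_gene(cl(2000, 2200), GENE_MINUS) is ClusterClass.UT

    def test_r_classes_and_utr_exclusions(self):
        # exon1 + upstream flank, no 3'UTR contact → 5R
        assert classify_vs_gene(cl(50, 140), GENE) is ClusterClass.R5
        # exon2 + downstream flank, no 5'UTR contact → 3R
        assert classify_vs_gene(cl(360, 450), GENE) is ClusterClass.R3
        # same geometry mirrored by strand swaps the labels
        assert classify_vs_gene(cl(50, 140), GENE_MINUS) is ClusterClass.R3
        assert classify_vs_gene(cl(360, 450), GENE_MINUS) is ClusterClass.R5
        # spanning the whole gene touches both flanks → NO_CLASS
        assert classify_vs_gene(cl(50, 450), GENE) is ClusterClass.NO_CLASS


class TestConflictResolution:
    def test_single_gene_class_passes_through(self):
        assert resolve_classes([ClusterClass.TIN]) is ClusterClass.TIN

    def test_genic_class_beats_flank_classes(self):
        assert resolve_classes([ClusterClass.TIN, ClusterClass.UT]) is ClusterClass.TIN
        assert resolve_classes(
            [ClusterClass.R3, ClusterClass.UT, ClusterClass.DT]) is ClusterClass.R3

    def test_two_genic_classes_conflict(self):
        assert resolve_classes(
            [ClusterClass.TEX, ClusterClass.TIN]) is ClusterClass.NO_CLASS

    def test_flank_only_conflict_is_unresolved(self):
        assert resolve_classes(
            [ClusterClass.UT, ClusterClass.DT]) is ClusterClass.NO_CLASS

    def test_no_gene_in_range_is_intergenic(self):
        assert classify_cluster(cl(0, 100), []) is ClusterClass.IGR

    def test_enumerated_subsets_match_stated_rule(self):
        """Exhaustive 2- and 3-element per-gene class sets resolve exactly as
        the written rule: one genic class + flank extras wins, else NO_CLASS."""
        candidates = sorted(GENIC_CLASSES | FLANK_CLASSES | {ClusterClass.NO_CLASS},
                            key=str)
        for k in (2, 3):
            for subset in combinations(candidates, k):
                got = resolve_classes(list(subset))
                genic = set(subset) & GENIC_CLASSES
                flank = set(subset) - genic
                if len(genic) == 1 and flank <= FLANK_CLASSES:
                    assert got is next(iter(genic))
                else:
                    assert got is ClusterClass.NO_CLASS


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(20))
    def test_random_layouts_match_per_base_painting(self, seed):
        rng = np.random.default_rng(seed)
        n_exons = int(rng.integers(1, 6))
        pos = int(rng.integers(6000, 7000))
        exons = []
        for _ in range(n_exons):
            length = int(rng.integers(40, 300))
            exons.append((pos, pos + length))
            pos += length + int(rng.integers(60, 400))
        strand = "+" if rng.random() < 0.5 else "-"
        cds = (exons[0][0] + 20, exons[-1][1] - 20) if rng.random() < 0.7 else None
        if cds is not None and cds[0] >= cds[1]:
            cds = None
        gene = make_gene(exons, cds=cds, strand=strand)
        lo = exons[0][0] - 5600
        hi = exons[-1][1] + 5600
        for _ in range(30):
            s = int(rng.integers(lo, hi - 30))
            c = cl(s, s + int(rng.integers(25, 900)))
            assert (
                str(classify_vs_gene(c, gene))
                == classify_oracle(c.interval.start, c.interval.end, gene)
            )

    def test_threshold_boundaries_match_oracle(self):
        """Overlaps of exactly 20 and 21 nt on both exon and flank sides."""
        for span in [(180, 250), (179, 250), (250, 321), (250, 320),
                     (80, 121), (80, 120), (380, 421), (380, 420)]:
            c = cl(*span)
            assert (
                str(classify_vs_gene(c, GENE))
                == classify_oracle(c.interval.start, c.interval.end, GENE)
            )


def test_class_summary_partitions():
    classes = {
        "c1": ClusterClass.TIN, "c2": ClusterClass.TEX, "c3": ClusterClass.IGR,
    }
    table = class_summary(classes)
    assert table[ClusterClass.TIN] == 1
    assert table[ClusterClass.TEX] == 1
    assert table[ClusterClass.IGR] == 1
    assert sum(table.values()) == len(classes)


def test_serialized_names():
    assert [str(c) for c in ClusterClass] == [
        "TEX", "TIN", "5PIN", "3PIN", "rI", "5R", "3R", "UT", "DT", "IGR",
        "NO_CLASS",
    ]
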