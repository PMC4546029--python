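"""Positional classification of unspliced EST clusters against gene models.

Each cluster is placed into exactly one of eleven classes by the set of gene
components it overlaps by more than 20 nt:

========  ==========================================================
TEX       exclusively exonic (UTR and non-coding exons count as exon)
TIN       exclusively intronic
5PIN      one adjoining exon–intron pair, exon on the 5' side
3PIN      one adjoining exon–intron pair, exon on the 3' side
rI        one complete intron plus both adjacent exons
5R        exon plus upstream flank (no downstream/3'UTR contact)
3R        exon plus downstream flank (no upstream/5'UTR contact)
UT / DT   exclusively within the 5-kb upstream / downstream flank
IGR       no gene within 5 kb at all
NO_CLASS  anything else, and unresolvable multi-gene conflicts
========  ==========================================================

When several genes are in range the per-gene classes must agree, except that
a conflict between one genic class and UT/DT is resolved in favor of the
genic class (the extra flank contact of a neighbouring gene is ignored —
otherwise dense regions would be unclassifiable).
"""

from __future__ import annotations

from collections import Counter
from enum import Enum

from .config import FilterConfig
from .core import overlap_len
from .est_preprocess import UESTCluster
from .gene_model import GeneModel


class ClusterClass(str, Enum):
    TEX = "TEX"
    TIN = "TIN"
    PIN5 = "5PIN"
    PIN3 = "3PIN"
    RI = "rI"
    R5 = "5R"
    R3 = "3R"
    UT = "UT"
    DT = "DT"
    IGR = "IGR"
    NO_CLASS = "NO_CLASS"

    def __str__(self) -> str:  # serialized exactly as the field labels
        return self.value


GENIC_CLASSES = frozenset(
    {
        ClusterClass.TEX, ClusterClass.TIN, ClusterClass.PIN5, ClusterClass.PIN3,
        ClusterClass.RI, ClusterClass.R5, ClusterClass.R3,
    }
)
FLANK_CLASSES = frozenset({ClusterClass.UT, ClusterClass.DT})
REAL_CLASSES = (  # every class a cluster can genuinely belong to, fixed order
    ClusterClass.TEX, ClusterClass.TIN, ClusterClass.PIN5, ClusterClass.PIN3,
    ClusterClass.RI, ClusterClass.R5, ClusterClass.R3, ClusterClass.UT,
    ClusterClass.DT, ClusterClass.IGR,
)


def _hit_indices(cluster: UESTCluster, spans, thr: int) -> list[int]:
    s, e = cluster.interval.start, cluster.interval.end
    return [i for i, (a, b) in enumerate(spans) if overlap_len(a, b, s, e) > thr]


def _any_hit(cluster: UESTCluster, spans, thr: int) -> bool:
    return bool(_hit_indices(cluster, spans, thr))


def classify_vs_gene(
    cluster: UESTCluster, gene: GeneModel, config: FilterConfig | None = None
) -> ClusterClass:
    """Class of ``cluster`` with respect to one in-range gene.

    The overlap threshold (> ``min_component_overlap_nt``, strictly) is
    applied per component instance — to each exon, each intron and each
    flank — before instances are collapsed into the set of component kinds
    that drives the rule table.
    """
    config = config or FilterConfig()
    thr = config.min_component_overlap_nt

    exon_hits = _hit_indices(cluster, gene.exons, thr)
    # introns carry the index of their 5'-in-genome neighbouring exon, so
    # adjacency stays correct even if some exon pairs abut with no gap
    introns = [
        (i, (a[1], b[0]))
        for i, (a, b) in enumerate(zip(gene.exons, gene.exons[1:]))
        if a[1] < b[0]
    ]
    intron_hits = [
        left
        for left, span in introns
        if overlap_len(span[0], span[1], cluster.interval.start, cluster.interval.end) > thr
    ]
    up = _any_hit(cluster, gene.upstream_flank, thr)
    down = _any_hit(cluster, gene.downstream_flank, thr)
    u5 = _any_hit(cluster, gene.utr5, thr)
    u3 = _any_hit(cluster, gene.utr3, thr)

    kinds = frozenset(
        k
        for k, present in (
            ("exon", bool(exon_hits)),
            ("intron", bool(intron_hits)),
            ("up", up),
            ("down", down),
        )
        if present
    )

    if kinds == {"exon"}:
        return ClusterClass.TEX
    if kinds == {"intron"}:
        return ClusterClass.TIN
    if kinds == {"exon", "intron"}:
        if len(intron_hits) == 1:
            j = intron_hits[0]
            adjacent = {j, j + 1}  # intron j sits between exons j and j+1
            if len(exon_hits) == 1 and exon_hits[0] in adjacent:
                # which adjoining exon is on the transcript's 5' side?
                five_prime_exon = j if gene.strand == "+" else j + 1
                return (
                    ClusterClass.PIN5
                    if exon_hits[0] == five_prime_exon
                    else ClusterClass.PIN3
                )
            if len(exon_hits) == 2 and set(exon_hits) == adjacent:
                return ClusterClass.RI
        return ClusterClass.NO_CLASS
    if kinds == {"exon", "up"}:
        return ClusterClass.R5 if not u3 else ClusterClass.NO_CLASS
    if kinds == {"exon", "down"}:
        return ClusterClass.R3 if not u5 else ClusterClass.NO_CLASS
    if kinds == {"up"}:
        return ClusterClass.UT
    if kinds == {"down"}:
        return ClusterClass.DT
    return ClusterClass.NO_CLASS


def resolve_classes(per_gene_classes) -> ClusterClass:
    """Combine per-gene classes of one cluster into its final label.

    Identical labels pass through; one genic class plus any mixture of UT/DT
    resolves to the genic class; everything else is NO_CLASS.  An empty input
    means no gene in range → IGR.
    """
    distinct = set(per_gene_classes)
    if not distinct:
        return ClusterClass.IGR
    if len(distinct) == 1:
        return next(iter(distinct))
    genic = distinct & GENIC_CLASSES
    if len(genic) == 1 and distinct <= (genic | FLANK_CLASSES):
        return next(iter(genic))
    return ClusterClass.NO_CLASS


def classify_cluster(
    cluster: UESTCluster,
    in_range_genes: list[GeneModel],
    config: FilterConfig | None = None,
) -> ClusterClass:
    """Final class of ``cluster`` given every gene in its 5-kb range."""
    return resolve_classes(
        classify_vs_gene(cluster, g, config) for g in in_range_genes
    )


def classify_all(
    clusters: list[UESTCluster],
    in_range: dict[str, list[GeneModel]],
    config: FilterConfig | None = None,
) -> dict[str, ClusterClass]:
    """Classify every cluster; ``in_range`` comes from ``genes_in_range``."""
    return {
        c.cluster_id: classify_cluster(c, in_range.get(c.cluster_id, ()), config)
        for c in clusters
    }


def class_summary(classes) -> dict[ClusterClass, int]:
    """Per-class cluster counts over all eleven labels (zeros included).

    ``classes`` is an iterable of ClusterClass or a cluster_id → class
    mapping.  NO_CLASS is tallied like the others but is conventionally
    excluded from class-specific downstream analyses.
    """
    values = classes.values() if isinstance(classes, dict) else classes
    counts = Counter(values)
    return {cls: counts.get(cls, 0) for cls in ClusterClass}
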