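"""Transcript models decomposed into the components the classifier consumes.

A :class:`GeneModel` is one transcript (genePred semantics): strand, exon
list, optional CDS.  :func:`build_components` derives the labeled pieces —
introns, 5'/3' UTR exonic segments, and the 5-kb upstream/downstream flanks —
all in forward-genome coordinates but assigned strand-awarely (on a minus
strand gene the 5' UTR is the rightmost UTR segment and the upstream flank
sits right of the transcript end).
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field, replace

from .config import FilterConfig
from .core import GenomicInterval, overlap_len

Span = tuple[int, int]


class ModelError(ValueError):
    """Inconsistent gene structure (exon outside transcript span, etc.)."""


@dataclass(frozen=True)
class GeneModel:
    """One transcript with its derived, labeled components.

    ``exons`` are sorted, non-overlapping ``(start, end)`` spans in genome
    coordinates; ``cds`` is ``None`` for non-coding transcripts (genePred
    encodes these as ``cdsStart == cdsEnd``).  Derived fields are empty until
    :func:`build_components` is applied.
    """

    gene_id: str
    interval: GenomicInterval  # strand is "+" or "-"
    exons: tuple[Span, ...]
    cds: Span | None = None
    introns: tuple[Span, ...] = ()
    utr5: tuple[Span, ...] = ()
    utr3: tuple[Span, ...] = ()
    upstream_flank: tuple[Span, ...] = ()
    downstream_flank: tuple[Span, ...] = ()

    def __post_init__(self) -> None:
        if self.interval.strand not in ("+", "-"):
            raise ModelError(f"{self.gene_id}: gene strand must be + or -")
        if not self.exons:
            raise ModelError(f"{self.gene_id}: transcript needs at least one exon")
        prev_end = None
        for s, e in self.exons:
            if not (self.interval.start <= s < e <= self.interval.end):
                raise ModelError(
                    f"{self.gene_id}: exon [{s},{e}) outside transcript span"
                )
            if prev_end is not None and s < prev_end:
                raise ModelError(f"{self.gene_id}: exons overlap or are unsorted")
            prev_end = e
        if self.exons[0][0] != self.interval.start or self.exons[-1][1] != self.interval.end:
            raise ModelError(f"{self.gene_id}: exons must cover the transcript ends")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def is_coding(self) -> bool:
        return self.cds is not None

    def span_with_flanks(self) -> Span:
        """Transcript span extended by whatever flanks have been built."""
        pieces = [self.interval.start, self.interval.end]
        for span_list in (self.upstream_flank, self.downstream_flank):
            for s, e in span_list:
                pieces.extend((s, e))
        return min(pieces), max(pieces)


def _exonic_portion(exons: tuple[Span, ...], lo: int, hi: int) -> tuple[Span, ...]:
    out = []
    for s, e in exons:
        cs, ce = max(s, lo), min(e, hi)
        if cs < ce:
            out.append((cs, ce))
    return tuple(out)


def build_components(
    gene: GeneModel,
    config: FilterConfig | None = None,
    chrom_sizes: dict[str, int] | None = None,
) -> GeneModel:
    """Populate introns, UTRs and flanks of ``gene``.

    Flanks have length ``config.flank_nt`` and are clipped to
    ``[0, chrom_size)``; a flank entirely off the chromosome is empty.  For a
    non-coding transcript both UTR lists are empty and every exonic base is
    plain "exon".
    """
    config = config or FilterConfig()
    flank = config.flank_nt
    introns = tuple(
        (a[1], b[0]) for a, b in zip(gene.exons, gene.exons[1:]) if a[1] < b[0]
    )

    if gene.cds is not None:
        cs, ce = gene.cds
        if not (gene.interval.start <= cs < ce <= gene.interval.end):
            raise ModelError(f"{gene.gene_id}: CDS outside transcript span")
        left = _exonic_portion(gene.exons, gene.interval.start, cs)
        right = _exonic_portion(gene.exons, ce, gene.interval.end)
        utr5, utr3 = (left, right) if gene.strand == "+" else (right, left)
    else:
        utr5 = utr3 = ()

    size = None if chrom_sizes is None else chrom_sizes.get(gene.chrom)
    hi = size if size is not None else None

    def _flank(start: int, end: int) -> tuple[Span, ...]:
        s = max(0, start)
        e = end if hi is None else min(end, hi)
        return ((s, e),) if s < e else ()

    left_flank = _flank(gene.interval.start - flank, gene.interval.start)
    right_flank = _flank(gene.interval.end, gene.interval.end + flank)
    if gene.strand == "+":
        upstream, downstream = left_flank, right_flank
    else:
        upstream, downstream = right_flank, left_flank

    return replace(
        gene,
        introns=introns,
        utr5=utr5,
        utr3=utr3,
        upstream_flank=upstream,
        downstream_flank=downstream,
    )


@dataclass
class _RangeIndex:
    """Sorted gene index supporting 'which extended spans overlap [s,e)'."""

    starts: list[int] = field(default_factory=list)
    ends: list[int] = field(default_factory=list)
    cummax_end: list[int] = field(default_factory=list)
    genes: list[GeneModel] = field(default_factory=list)


def _build_index(genes: list[GeneModel]) -> dict[str, _RangeIndex]:
    by_chrom: dict[str, list[tuple[int, int, GeneModel]]] = {}
    for g in genes:
        s, e = g.span_with_flanks()
        by_chrom.setdefault(g.chrom, []).append((s, e, g))
    index: dict[str, _RangeIndex] = {}
    for chrom, rows in by_chrom.items():
        rows.sort(key=lambda r: (r[0], r[1], r[2].gene_id))
        idx = _RangeIndex()
        running = 0
        for s, e, g in rows:
            idx.starts.append(s)
            idx.ends.append(e)
            running = max(running, e)
            idx.cummax_end.append(running)
            idx.genes.append(g)
        index[chrom] = idx
    return index


def genes_in_range(clusters, genes: list[GeneModel], config: FilterConfig | None = None):
    """Map each cluster to the genes whose span ∪ flanks it overlaps by ≥1 nt.

    ``clusters`` is any iterable of objects exposing ``cluster_id`` and
    ``interval``; flanks must already be built on the genes (a gene without
    flanks is matched on its transcript span alone).  Returns
    ``{cluster_id: [GeneModel, ...]}`` with gene lists in deterministic
    (position, id) order; clusters with no gene in range map to ``[]``.
    """
    del config  # range is defined by the flanks already on the genes
    index = _build_index(genes)
    out: dict[str, list[GeneModel]] = {}
    for cluster in clusters:
        iv = cluster.interval
        hits: list[GeneModel] = []
        idx = index.get(iv.chrom)
        if idx is not None:
            # candidates have ext_start < iv.end; walk left while any span
            # to the left can still reach iv.start (cummax_end > iv.start)
            i = bisect.bisect_left(idx.starts, iv.end) - 1
            while i >= 0 and idx.cummax_end[i] > iv.start:
                if idx.ends[i] > iv.start:
                    hits.append(idx.genes[i])
                i -= 1
            hits.reverse()
        out[cluster.cluster_id] = hits
    return out
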