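"""Chain-based coordinate lifting and cross-species cluster pairing.

`lift_interval` reimplements the core of UCSC liftOver: an interval is
projected through the aligned blocks of a chain, base ranges falling into
chain gaps are dropped, and the call succeeds only when at least
``min_mapped_frac`` of the interval's bases map through exactly one chain
(matching liftOver's default minMatch of 0.95 and its rejection of intervals
that split over multiple chains).  Mapped coordinates are always reported on
the forward strand of the target genome.

Orthologous cluster pairs are the union of the A→B and B→A lift runs; the
two directions can genuinely disagree because the chain sets are not exact
inverses of each other.
"""

from __future__ import annotations

from dataclasses import dataclass

from .core import GenomicInterval, overlap_len
from .est_preprocess import UESTCluster
from .io_formats import ChainAlignment


@dataclass(frozen=True)
class OrthologPair:
    cluster_a_id: str
    cluster_b_id: str
    detected_by: str  # "A->B", "B->A" or "both"
    same_class: bool | None = None


def _mapped_ranges(
    interval: GenomicInterval, chain: ChainAlignment
) -> tuple[int, list[tuple[int, int]]]:
    """Bases of ``interval`` mapped through one chain.

    Returns ``(n_mapped_bases, target_ranges)`` with target ranges on the
    chain's stated target strand (converted to forward later).
    """
    if chain.src_chrom != interval.chrom or chain.src_strand != "+":
        return 0, []
    s_pos, t_pos = chain.src_start, chain.tgt_start
    mapped = 0
    ranges: list[tuple[int, int]] = []
    for size, d_src, d_tgt in chain.blocks:
        ov = overlap_len(s_pos, s_pos + size, interval.start, interval.end)
        if ov:
            off = max(interval.start, s_pos) - s_pos
            ranges.append((t_pos + off, t_pos + off + ov))
            mapped += ov
        s_pos += size + d_src
        t_pos += size + d_tgt
        if s_pos >= interval.end:
            break
    return mapped, ranges


def lift_interval(
    interval: GenomicInterval,
    chains: list[ChainAlignment],
    min_mapped_frac: float = 0.95,
) -> GenomicInterval | None:
    """Map ``interval`` to the target genome, or ``None`` if unmappable.

    A chain qualifies when it maps at least ``min_mapped_frac`` of the
    interval's bases; with zero or more than one qualifying chain the lift
    is rejected.  The result is the hull of the mapped bases on the single
    qualifying chain, in forward coordinates of the target chromosome.
    """
    if not (0.0 < min_mapped_frac <= 1.0):
        raise ValueError("min_mapped_frac must lie in (0, 1]")
    n = len(interval)
    hits: list[tuple[ChainAlignment, list[tuple[int, int]]]] = []
    for chain in chains:
        mapped, ranges = _mapped_ranges(interval, chain)
        if mapped / n >= min_mapped_frac:
            hits.append((chain, ranges))
    if len(hits) != 1:
        return None
    chain, ranges = hits[0]
    lo = min(s for s, _ in ranges)
    hi = max(e for _, e in ranges)
    if chain.tgt_strand == "-":
        lo, hi = chain.tgt_size - hi, chain.tgt_size - lo
    return GenomicInterval(chain.tgt_chrom, lo, hi, ".")


def _overlapping_pairs(lifted: dict[str, GenomicInterval], clusters: list[UESTCluster]):
    """(source_id, target_id) for every >= 1 nt overlap, via a sorted sweep."""
    by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for c in clusters:
        by_chrom.setdefault(c.interval.chrom, []).append(
            (c.interval.start, c.interval.end, c.cluster_id)
        )
    for spans in by_chrom.values():
        spans.sort()
    pairs = set()
    for src_id, iv in lifted.items():
        for s, e, tgt_id in by_chrom.get(iv.chrom, ()):
            if s >= iv.end:
                break
            if e > iv.start:
                pairs.add((src_id, tgt_id))
    return pairs


def pair_orthologs(
    clusters_a: list[UESTCluster],
    clusters_b: list[UESTCluster],
    chains_ab: list[ChainAlignment],
    chains_ba: list[ChainAlignment],
    min_mapped_frac: float = 0.95,
    classes_a: dict[str, object] | None = None,
    classes_b: dict[str, object] | None = None,
) -> list[OrthologPair]:
    """Union of the two directional lift runs, with per-pair provenance.

    ``classes_a``/``classes_b`` (cluster_id → class) are optional; when both
    are given each pair carries ``same_class``.
    """
    lifted_a = {}
    for c in clusters_a:
        m = lift_interval(c.interval, chains_ab, min_mapped_frac)
        if m is not None:
            lifted_a[c.cluster_id] = m
    lifted_b = {}
    for c in clusters_b:
        m = lift_interval(c.interval, chains_ba, min_mapped_frac)
        if m is not None:
            lifted_b[c.cluster_id] = m

    ab = _overlapping_pairs(lifted_a, clusters_b)
    ba = {(a, b) for b, a in _overlapping_pairs(lifted_b, clusters_a)}

    pairs: list[OrthologPair] = []
    for a_id, b_id in sorted(ab | ba):
        in_ab, in_ba = (a_id, b_id) in ab, (a_id, b_id) in ba
        detected_by = "both" if (in_ab and in_ba) else ("A->B" if in_ab else "B->A")
        same_class = None
        if classes_a is not None and classes_b is not None:
            same_class = classes_a.get(a_id) == classes_b.get(b_id)
        pairs.append(OrthologPair(a_id, b_id, detected_by, same_class))
    return pairs


def conservation_summary(
    pairs: list[OrthologPair],
    clusters_a: list[UESTCluster],
    clusters_b: list[UESTCluster],
) -> dict[str, int]:
    """Headline counts: pairs, distinct members per genome, unpaired rest."""
    distinct_a = {p.cluster_a_id for p in pairs}
    distinct_b = {p.cluster_b_id for p in pairs}
    return {
        "n_pairs": len(pairs),
        "n_distinct_a": len(distinct_a),
        "n_distinct_b": len(distinct_b),
        "n_same_class": sum(1 for p in pairs if p.same_class),
        "n_unpaired_a": len(clusters_a) - len(distinct_a),
        "n_unpaired_b": len(clusters_b) - len(distinct_b),
    }


def class_pair_matrix(pairs: list[OrthologPair], classes_a, classes_b):
    """Class-vs-class pair counts as a nested dict (A class → B class → n)."""
    matrix: dict[str, dict[str, int]] = {}
    for p in pairs:
        ca = str(classes_a.get(p.cluster_a_id))
        cb = str(classes_b.get(p.cluster_b_id))
        matrix.setdefault(ca, {}).setdefault(cb, 0)
        matrix[ca][cb] += 1
    return matrix
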