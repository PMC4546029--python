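"""Independent brute-force oracles used to cross-check the pipeline.

Each oracle re-derives a result from first principles — per-base painting,
all-pairs graph components, per-base coordinate mapping — deliberately
avoiding the interval arithmetic of the implementation it checks.
"""

from __future__ import annotations

from collections import Counter, defaultdict

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components


# ---------------------------------------------------------------------------
# classification: per-base painting + rule table
# ---------------------------------------------------------------------------

def paint_gene(gene) -> dict[int, set[str]]:
    """Label every base influenced by the gene with its component tags."""
    paint: dict[int, set[str]] = defaultdict(set)
    for i, (s, e) in enumerate(gene.exons):
        for p in range(s, e):
            paint[p].add(f"exon{i}")
    for a, b in zip(gene.exons, gene.exons[1:]):
        # paint introns with the index of the exon to their genomic left
        left_index = gene.exons.index(a)
        for p in range(a[1], b[0]):
            paint[p].add(f"intron{left_index}")
    for kind, spans in (("up", gene.upstream_flank), ("down", gene.downstream_flank),
                        ("utr5", gene.utr5), ("utr3", gene.utr3)):
        for s, e in spans:
            for p in range(s, e):
                paint[p].add(kind)
    return paint


def classify_oracle(cluster_start: int, cluster_end: int, gene, thr: int = 20) -> str:
    """Class label derived from the painted multiset of cluster bases."""
    paint = paint_gene(gene)
    counts: Counter[str] = Counter()
    for p in range(cluster_start, cluster_end):
        for tag in paint.get(p, ()):
            counts[tag] += 1

    exon_idx = sorted(
        int(t[4:]) for t, n in counts.items() if t.startswith("exon") and n > thr
    )
    intron_idx = sorted(
        int(t[6:]) for t, n in counts.items() if t.startswith("intron") and n > thr
    )
    up = counts.get("up", 0) > thr
    down = counts.get("down", 0) > thr
    u5 = counts.get("utr5", 0) > thr
    u3 = counts.get("utr3", 0) > thr

    has_exon, has_intron = bool(exon_idx), bool(intron_idx)
    if has_exon and not has_intron and not up and not down:
        return "TEX"
    if has_intron and not has_exon and not up and not down:
        return "TIN"
    if has_exon and has_intron and not up and not down:
        if len(intron_idx) == 1 and len(exon_idx) == 1:
            j = intron_idx[0]
            if exon_idx[0] in (j, j + 1):
                five = j if gene.strand == "+" else j + 1
                return "5PIN" if exon_idx[0] == five else "3PIN"
        if len(intron_idx) == 1 and exon_idx == [intron_idx[0], intron_idx[0] + 1]:
            return "rI"
        return "NO_CLASS"
    if has_exon and up and not has_intron and not down:
        return "5R" if not u3 else "NO_CLASS"
    if has_exon and down and not has_intron and not up:
        return "3R" if not u5 else "NO_CLASS"
    if up and not (has_exon or has_intron or down):
        return "UT"
    if down and not (has_exon or has_intron or up):
        return "DT"
    return "NO_CLASS"


def component_paint_oracle(gene, flank_nt: int = 5000, chrom_size=None) -> dict[int, str]:
    """Single-label per-base painting derived from raw transcript fields only
    (exons, cds, strand) — never from the built component lists.

    Labels: upstream/downstream flank, intron, utr5/utr3, exon (any exonic
    base outside a UTR, coding or not).
    """
    out: dict[int, str] = {}
    tx_s, tx_e = gene.interval.start, gene.interval.end
    left = range(max(0, tx_s - flank_nt), tx_s)
    hi = tx_e + flank_nt if chrom_size is None else min(tx_e + flank_nt, chrom_size)
    right = range(tx_e, hi)
    if gene.strand == "+":
        up_bases, down_bases = left, right
    else:
        up_bases, down_bases = right, left
    for p in up_bases:
        out[p] = "upstream"
    for p in down_bases:
        out[p] = "downstream"
    exonic = set()
    for s, e in gene.exons:
        exonic.update(range(s, e))
    for p in range(tx_s, tx_e):
        out[p] = "exon" if p in exonic else "intron"
    if gene.cds is not None:
        cs, ce = gene.cds
        for p in exonic:
            if p < cs:
                out[p] = "utr5" if gene.strand == "+" else "utr3"
            elif p >= ce:
                out[p] = "utr3" if gene.strand == "+" else "utr5"
    return out


# ---------------------------------------------------------------------------
# clustering: all-pairs adjacency + library graph components
# ---------------------------------------------------------------------------

def cluster_oracle(
    intervals: list[tuple[str, int, int, str]], join: int = 30, min_size: int = 3
):
    """Connected components of the all-pairs gap<=join graph, per chromosome.

    ``intervals`` rows are (chrom, start, end, est_id).  Returns a sorted
    list of (chrom, hull_start, hull_end, sorted member ids).
    """
    out = []
    by_chrom: dict[str, list[tuple[int, int, str]]] = defaultdict(list)
    for chrom, s, e, name in intervals:
        by_chrom[chrom].append((s, e, name))
    for chrom in sorted(by_chrom):
        rows = by_chrom[chrom]
        starts = np.array([r[0] for r in rows])
        ends = np.array([r[1] for r in rows])
        gaps = np.maximum(starts[:, None], starts[None, :]) - np.minimum(
            ends[:, None], ends[None, :]
        )
        adj = sp.csr_matrix(gaps <= join)
        n_comp, labels = connected_components(adj, directed=False)
        for comp in range(n_comp):
            mask = labels == comp
            if mask.sum() < min_size:
                continue
            members = sorted(rows[i][2] for i in np.flatnonzero(mask))
            out.append((chrom, int(starts[mask].min()), int(ends[mask].max()), members))
    out.sort()
    return out


# ---------------------------------------------------------------------------
# filtering: independent per-alignment re-check
# ---------------------------------------------------------------------------

def filter_oracle(alignments, numts, excluded_patterns, cfg):
    """Re-evaluate each filter independently; first violation (in funnel
    order) claims the alignment."""
    import fnmatch

    numt_spans = defaultdict(list)
    for chrom, s, e in numts:
        numt_spans[chrom].append((s, e))
    removed = Counter()
    survivors = []
    for a in alignments:
        gaps = [b[0] - (x[0] + x[1]) for x, b in zip(a.blocks, a.blocks[1:])]
        biggest = max(gaps) if gaps else 0
        denom = a.matches + a.rep_matches + a.mismatches
        frac = a.mismatches / denom if denom else 0.0
        on_numt = any(
            s < a.interval.end and e > a.interval.start
            for s, e in numt_spans.get(a.interval.chrom, ())
        )
        if any(fnmatch.fnmatchcase(a.interval.chrom, p) for p in excluded_patterns):
            removed["haplotype"] += 1
        elif biggest > cfg.max_gap_nt:
            removed["gap"] += 1
        elif frac > cfg.max_mismatch_frac:
            removed["mismatch"] += 1
        elif on_numt:
            removed["numt"] += 1
        else:
            survivors.append(a)
    return survivors, dict(removed)


# ---------------------------------------------------------------------------
# lifting: per-base mapping
# ---------------------------------------------------------------------------

def lift_oracle(interval, chains, min_frac: float = 0.95):
    """Map every base independently; same accept/reject contract as liftOver."""
    n = interval.end - interval.start
    candidates = []
    for ch in chains:
        if ch.src_chrom != interval.chrom or ch.src_strand != "+":
            continue
        mapped = {}
        s, t = ch.src_start, ch.tgt_start
        for size, d_src, d_tgt in ch.blocks:
            for k in range(size):
                mapped[s + k] = t + k
            s += size + d_src
            t += size + d_tgt
        hits = [mapped[p] for p in range(interval.start, interval.end) if p in mapped]
        if hits and len(hits) / n >= min_frac:
            lo, hi = min(hits), max(hits) + 1
            if ch.tgt_strand == "-":
                lo, hi = ch.tgt_size - hi, ch.tgt_size - lo
            candidates.append((ch.tgt_chrom, lo, hi))
    return candidates[0] if len(candidates) == 1 else None


# ---------------------------------------------------------------------------
# track averaging: per-base loop
# ---------------------------------------------------------------------------

def mean_score_oracle(interval, track):
    """Per-base mean over scored bases; (None, 0) when nothing is scored."""
    values = []
    for s, e, v in track.runs(interval.chrom):
        for p in range(s, e):
            if interval.start <= p < interval.end:
                values.append(v)
    if not values:
        return None, 0
    return sum(values) / len(values), len(values)


# ---------------------------------------------------------------------------
# in-range assignment: all pairs
# ---------------------------------------------------------------------------

def in_range_oracle(clusters, genes):
    out = {}
    for c in clusters:
        hits = []
        for g in genes:
            lo, hi = g.span_with_flanks()
            if g.chrom == c.interval.chrom and lo < c.interval.end and hi > c.interval.start:
                hits.append(g.gene_id)
        out[c.cluster_id] = sorted(hits)
    return out
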