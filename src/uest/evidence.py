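"""Orthogonal evidence overlays: CAGE orientation, cell breadth, chromatin
state support and RNA-seq read support.

EST clusters are intrinsically unstranded; a stranded CAGE TSS peak falling
into the terminal 84-nt window of a cluster orients it (a forward peak near
the left end reads rightward, a reverse peak near the right end reads
leftward).  Clusters with peaks at both ends look bidirectionally
transcribed and are flagged so they can be excluded downstream.
"""

from __future__ import annotations

import bisect
from collections import Counter
from dataclasses import dataclass
from enum import Enum

from .config import FilterConfig
from .core import GenomicInterval, overlap_len
from .est_preprocess import UESTCluster
from .io_formats import CoverageTrack

CHROMATIN_STATES = ("TSS", "PF", "E", "WE", "CTCF", "T", "R")


class Orientation(str, Enum):
    FORWARD = "forward"
    REVERSE = "reverse"
    BIDIRECTIONAL = "bidirectional"
    NONE = "none"

    def __str__(self) -> str:
        return self.value


@dataclass(frozen=True)
class TSSPeak:
    interval: GenomicInterval  # strand must be + or -
    cell_type: str | None = None

    def __post_init__(self) -> None:
        if self.interval.strand not in ("+", "-"):
            raise ValueError("TSS peaks must be stranded")


@dataclass(frozen=True)
class ChromatinSegment:
    interval: GenomicInterval
    state: str
    cell_line: str = ""

    def __post_init__(self) -> None:
        if self.state not in CHROMATIN_STATES:
            raise ValueError(
                f"unknown chromatin state {self.state!r}; expected one of "
                f"{CHROMATIN_STATES}"
            )


class _StrandedPeakIndex:
    """Per (chrom, strand) sorted peak index for window queries."""

    def __init__(self, peaks) -> None:
        by_key: dict[tuple[str, str], list[tuple[int, int]]] = {}
        for p in peaks:
            iv = p.interval
            by_key.setdefault((iv.chrom, iv.strand), []).append((iv.start, iv.end))
        self._starts: dict[tuple[str, str], list[int]] = {}
        self._cummax: dict[tuple[str, str], list[int]] = {}
        self._spans: dict[tuple[str, str], list[tuple[int, int]]] = {}
        for key, spans in by_key.items():
            spans.sort()
            self._spans[key] = spans
            self._starts[key] = [s for s, _ in spans]
            running, cm = 0, []
            for _, e in spans:
                running = max(running, e)
                cm.append(running)
            self._cummax[key] = cm

    def max_overlap(self, chrom: str, strand: str, start: int, end: int) -> int:
        key = (chrom, strand)
        if key not in self._starts:
            return 0
        starts, cm, spans = self._starts[key], self._cummax[key], self._spans[key]
        best = 0
        i = bisect.bisect_left(starts, end) - 1
        while i >= 0 and cm[i] > start:
            s, e = spans[i]
            best = max(best, overlap_len(s, e, start, end))
            i -= 1
        return best


def orient_by_cage(
    cluster: UESTCluster, peaks, config: FilterConfig | None = None
) -> Orientation:
    """Orientation call from stranded TSS peaks in the terminal windows.

    Forward evidence: a ``+`` peak overlapping the first ``cage_window_nt``
    of the cluster by at least ``tss_overlap_nt``; reverse evidence: a ``-``
    peak in the last window.  Windows are clipped to the cluster when it is
    shorter than the window.
    """
    config = config or FilterConfig()
    index = peaks if isinstance(peaks, _StrandedPeakIndex) else _StrandedPeakIndex(peaks)
    iv = cluster.interval
    w = config.cage_window_nt
    need = config.tss_overlap_nt
    fwd_win = (iv.start, min(iv.end, iv.start + w))
    rev_win = (max(iv.start, iv.end - w), iv.end)
    fwd = index.max_overlap(iv.chrom, "+", *fwd_win) >= need
    rev = index.max_overlap(iv.chrom, "-", *rev_win) >= need
    if fwd and rev:
        return Orientation.BIDIRECTIONAL
    if fwd:
        return Orientation.FORWARD
    if rev:
        return Orientation.REVERSE
    return Orientation.NONE


def orient_all(clusters, peaks, config: FilterConfig | None = None):
    """Orientation for every cluster; shares one peak index."""
    index = _StrandedPeakIndex(peaks)
    return {
        c.cluster_id: orient_by_cage(c, index, config) for c in clusters
    }


def cell_breadth(
    cluster: UESTCluster,
    per_cell_peak_sets: dict[str, list],
    config: FilterConfig | None = None,
) -> int:
    """Number of cell types whose peaks orient the cluster unambiguously.

    A cell type counts when its peak set yields a forward or reverse call
    (bidirectional and none do not count).  Invariant to cell-type order.
    """
    return sum(
        orient_by_cage(cluster, peaks, config)
        in (Orientation.FORWARD, Orientation.REVERSE)
        for peaks in per_cell_peak_sets.values()
    )


def breadth_histogram(
    clusters, per_cell_peak_sets, config: FilterConfig | None = None
) -> tuple[dict[str, int], dict[int, int]]:
    """Per-cluster breadth and the breadth histogram over clusters.

    The histogram covers breadth >= 1 only, so its total equals the number
    of clusters orientable in at least one cell type.
    """
    indexed = {
        cell: _StrandedPeakIndex(peaks)
        for cell, peaks in per_cell_peak_sets.items()
    }
    breadth = {
        c.cluster_id: cell_breadth(c, indexed, config) for c in clusters
    }
    hist = Counter(b for b in breadth.values() if b >= 1)
    return breadth, dict(sorted(hist.items()))


@dataclass(frozen=True)
class ChromatinSupport:
    has_tss_state: bool
    has_t_state: bool
    state_counts: tuple[tuple[str, int], ...]  # full multiset, sorted by state

    @property
    def active(self) -> bool:
        """Transcriptionally active: a TSS or Transcribed segment overlaps."""
        return self.has_tss_state or self.has_t_state


def chromatin_support(
    cluster: UESTCluster, segments, config: FilterConfig | None = None
) -> ChromatinSupport:
    """Chromatin-state flags pooled over all cell lines.

    A state counts when any segment of that state, from any cell line,
    overlaps the cluster by at least ``tss_overlap_nt``; adding cell lines
    can only set flags, never clear them.
    """
    config = config or FilterConfig()
    need = config.tss_overlap_nt
    counts: Counter[str] = Counter()
    iv = cluster.interval
    for seg in segments:
        if seg.interval.chrom != iv.chrom:
            continue
        if overlap_len(seg.interval.start, seg.interval.end, iv.start, iv.end) >= need:
            counts[seg.state] += 1
    return ChromatinSupport(
        has_tss_state=counts.get("TSS", 0) > 0,
        has_t_state=counts.get("T", 0) > 0,
        state_counts=tuple(sorted(counts.items())),
    )


def rnaseq_support(
    clusters, coverage_tracks: list[CoverageTrack], config: FilterConfig | None = None
) -> dict[str, bool]:
    """Per-cluster flag: >= ``min_rnaseq_reads`` reads in at least one library.

    Each track is one library of per-interval read counts; counts are summed
    over the intervals intersecting the cluster within that library only —
    libraries are never pooled.
    """
    config = config or FilterConfig()
    out: dict[str, bool] = {}
    for c in clusters:
        out[c.cluster_id] = any(
            t.sum_intersecting(c.interval) >= config.min_rnaseq_reads
            for t in coverage_tracks
        )
    return out


def sense_antisense(orientation: Orientation, host_strand: str) -> str:
    """Derived orientation of a cluster relative to its host gene.

    ``sense`` when the CAGE orientation matches the host strand,
    ``antisense`` when opposite, ``ambiguous`` for bidirectional calls and
    ``unknown`` when the cluster could not be oriented.
    """
    if orientation is Orientation.BIDIRECTIONAL:
        return "ambiguous"
    if orientation is Orientation.NONE:
        return "unknown"
    cluster_strand = "+" if orientation is Orientation.FORWARD else "-"
    return "sense" if cluster_strand == host_strand else "antisense"
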