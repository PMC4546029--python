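"""Successive EST filters and merging of surviving ESTs into clusters.

The filter funnel removes, in order: alignments on excluded (haplotype)
chromosomes, spliced alignments (largest genomic gap > 30 nt), noisy
alignments (> 5 % mismatches per aligned base), and alignments touching a
NUMT region (nuclear copies of mitochondrial DNA, an unavoidable source of
unspliced contamination).  Survivors are merged per chromosome into clusters
of ESTs that overlap or lie within 30 nt of each other; only clusters with at
least three members are reported.
"""

from __future__ import annotations

import bisect
import fnmatch
from dataclasses import dataclass, field

from .config import FilterConfig
from .core import GenomicInterval
from .io_formats import ESTAlignment

FILTER_STAGES = ("haplotype", "gap", "mismatch", "numt")


@dataclass
class FilterReport:
    """Counts surviving (and removed at) each successive filter stage."""

    n_input: int = 0
    removed: dict[str, int] = field(default_factory=lambda: dict.fromkeys(FILTER_STAGES, 0))
    n_unspliced: int = 0
    n_clusters: int | None = None

    def surviving(self) -> dict[str, int]:
        """Survivor count after each stage, in filter order."""
        out = {}
        n = self.n_input
        for stage in FILTER_STAGES:
            n -= self.removed[stage]
            out[stage] = n
        return out

    def check(self) -> None:
        n = self.n_input
        for stage, surv in self.surviving().items():
            if surv < 0 or surv > n:
                raise ValueError(f"funnel not monotone at stage {stage}")
            n = surv
        if n != self.n_unspliced:
            raise ValueError("unspliced count inconsistent with removals")

    def to_rows(self) -> list[tuple[str, int]]:
        rows = [("input", self.n_input)]
        rows += [
            (f"removed_{stage}", self.removed[stage]) for stage in FILTER_STAGES
        ]
        rows.append(("unspliced_ests", self.n_unspliced))
        if self.n_clusters is not None:
            rows.append(("clusters", self.n_clusters))
        return rows


@dataclass(frozen=True)
class UESTCluster:
    """A merged genomic interval of >= 3 unspliced ESTs (unstranded)."""

    cluster_id: str
    interval: GenomicInterval
    member_est_ids: tuple[str, ...]

    @property
    def n_members(self) -> int:
        return len(self.member_est_ids)


class _NumtIndex:
    """Sorted-interval index answering 'does [s,e) touch any NUMT?'."""

    def __init__(self, numts) -> None:
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for iv in numts:
            chrom, s, e = _as_span(iv)
            by_chrom.setdefault(chrom, []).append((s, e))
        self._starts: dict[str, list[int]] = {}
        self._cummax: dict[str, list[int]] = {}
        self._ends: dict[str, list[int]] = {}
        for chrom, spans in by_chrom.items():
            spans.sort()
            self._starts[chrom] = [s for s, _ in spans]
            self._ends[chrom] = [e for _, e in spans]
            running, cm = 0, []
            for _, e in spans:
                running = max(running, e)
                cm.append(running)
            self._cummax[chrom] = cm

    def overlaps(self, interval: GenomicInterval) -> bool:
        starts = self._starts.get(interval.chrom)
        if not starts:
            return False
        cm = self._cummax[interval.chrom]
        ends = self._ends[interval.chrom]
        i = bisect.bisect_left(starts, interval.end) - 1
        while i >= 0 and cm[i] > interval.start:
            if ends[i] > interval.start:
                return True
            i -= 1
        return False


def _as_span(iv) -> tuple[str, int, int]:
    if isinstance(iv, GenomicInterval):
        return iv.chrom, iv.start, iv.end
    if hasattr(iv, "interval"):  # BedRecord and friends
        return iv.interval.chrom, iv.interval.start, iv.interval.end
    chrom, s, e = iv[:3]
    return chrom, int(s), int(e)


def _chrom_excluded(chrom: str, patterns) -> bool:
    return any(fnmatch.fnmatchcase(chrom, p) for p in patterns)


def _alignment_gap(a: ESTAlignment, mode: str) -> int:
    return a.max_target_gap if mode == "max" else a.sum_target_gap


def filter_unspliced(
    alignments: list[ESTAlignment],
    numts=(),
    excluded_chroms=(),
    config: FilterConfig | None = None,
) -> tuple[list[ESTAlignment], FilterReport]:
    """Apply the successive filters; returns survivors and the funnel report.

    ``excluded_chroms`` are shell-style patterns (e.g. ``chr6_*hap*``)
    matched exactly against chromosome names.  An alignment removed by an
    earlier stage is not re-counted by a later one, so the removal counts sum
    to ``n_input - n_unspliced``.
    """
    config = config or FilterConfig()
    numt_index = _NumtIndex(numts)
    report = FilterReport(n_input=len(alignments))
    survivors: list[ESTAlignment] = []
    for a in alignments:
        if _chrom_excluded(a.interval.chrom, excluded_chroms):
            report.removed["haplotype"] += 1
        elif _alignment_gap(a, config.gap_mode) > config.max_gap_nt:
            report.removed["gap"] += 1
        elif a.mismatch_frac > config.max_mismatch_frac:
            report.removed["mismatch"] += 1
        elif numt_index.overlaps(a.interval):
            report.removed["numt"] += 1
        else:
            survivors.append(a)
    report.n_unspliced = len(survivors)
    report.check()
    return survivors, report


def cluster_ests(
    ests: list[ESTAlignment], config: FilterConfig | None = None
) -> list[UESTCluster]:
    """Merge ESTs into clusters: connected components of the ≤30-nt-gap graph.

    Because the join relation ``gap(a, b) <= cluster_join_nt`` is an interval
    proximity relation, the components are exactly the maximal runs found by
    a sorted left-to-right sweep per chromosome.  Components smaller than
    ``min_cluster_size`` are discarded.  Cluster ids are deterministic,
    numbered in (chrom, start) order; the result is independent of the input
    order of ``ests``.
    """
    config = config or FilterConfig()
    join = config.cluster_join_nt
    by_chrom: dict[str, list[ESTAlignment]] = {}
    for a in ests:
        by_chrom.setdefault(a.interval.chrom, []).append(a)

    raw: list[tuple[str, int, int, list[str]]] = []
    for chrom in sorted(by_chrom):
        members = sorted(
            by_chrom[chrom], key=lambda a: (a.interval.start, a.interval.end, a.est_id)
        )
        cur_start = cur_end = None
        cur_ids: list[str] = []
        for a in members:
            s, e = a.interval.start, a.interval.end
            if cur_end is None or s - cur_end > join:
                if cur_ids:
                    raw.append((chrom, cur_start, cur_end, cur_ids))
                cur_start, cur_end, cur_ids = s, e, [a.est_id]
            else:
                cur_end = max(cur_end, e)
                cur_ids.append(a.est_id)
        if cur_ids:
            raw.append((chrom, cur_start, cur_end, cur_ids))

    clusters: list[UESTCluster] = []
    idx = 0
    for chrom, start, end, ids in raw:
        if len(ids) < config.min_cluster_size:
            continue
        idx += 1
        clusters.append(
            UESTCluster(
                cluster_id=f"uc{idx:06d}",
                interval=GenomicInterval(chrom, start, end, "."),
                member_est_ids=tuple(ids),
            )
        )
    return clusters
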