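"""Calling UTR-associated RNAs (uaRNAs).

A uaRNA candidate is an unspliced EST cluster that looks like an independent
transcript embedded in a gene's 3'UTR: it overlaps the 3'UTR of an in-range
gene (by more than the 20-nt component threshold), overlaps no in-range
gene's 5'UTR, and carries its own TSS evidence — either an orienting CAGE
peak in a terminal window, or overlap with a promoter-state ("TSS") chromatin
segment.  5'-side uaRNAs are not called: a TSS inside a 5'UTR cannot be told
apart from the host gene's own (alternative) start sites.
"""

from __future__ import annotations

from dataclasses import dataclass

from .config import FilterConfig
from .core import overlap_len
from .est_preprocess import UESTCluster
from .evidence import Orientation, orient_by_cage, _StrandedPeakIndex
from .gene_model import GeneModel

EVIDENCE_SOURCES = ("cage", "chromatin")


@dataclass(frozen=True)
class UaRNACall:
    cluster_id: str
    host_gene_ids: tuple[str, ...]  # genes whose 3'UTR the cluster overlaps
    evidence_source: str            # "cage" or "chromatin"
    orientation: Orientation        # NONE for chromatin-only evidence


def _utr_overlap(cluster: UESTCluster, spans, thr: int) -> bool:
    s, e = cluster.interval.start, cluster.interval.end
    return any(overlap_len(a, b, s, e) > thr for a, b in spans)


def call_uarnas(
    clusters: list[UESTCluster],
    in_range: dict[str, list[GeneModel]],
    evidence_source: str,
    cage_peaks=None,
    chromatin_segments=None,
    config: FilterConfig | None = None,
) -> list[UaRNACall]:
    """uaRNA candidates from classified clusters plus TSS evidence.

    ``in_range`` maps cluster_id to in-range genes with built components.
    The 5'UTR exclusion is applied against *every* in-range gene, not only
    the 3'UTR host — the stricter reading.
    """
    config = config or FilterConfig()
    thr = config.min_component_overlap_nt
    if evidence_source not in EVIDENCE_SOURCES:
        raise ValueError(
            f"unknown evidence source {evidence_source!r}; expected one of "
            f"{EVIDENCE_SOURCES}"
        )
    if evidence_source == "cage":
        if cage_peaks is None:
            raise ValueError("cage evidence requested but no peaks given")
        peak_index = _StrandedPeakIndex(cage_peaks)
    elif chromatin_segments is None:
        raise ValueError("chromatin evidence requested but no segments given")

    calls: list[UaRNACall] = []
    for cluster in clusters:
        genes = in_range.get(cluster.cluster_id, ())
        if not genes:
            continue
        hosts = tuple(
            g.gene_id for g in genes if _utr_overlap(cluster, g.utr3, thr)
        )
        if not hosts:
            continue
        if any(_utr_overlap(cluster, g.utr5, thr) for g in genes):
            continue
        if evidence_source == "cage":
            orientation = orient_by_cage(cluster, peak_index, config)
            if orientation not in (Orientation.FORWARD, Orientation.REVERSE):
                continue
        else:
            orientation = Orientation.NONE
            iv = cluster.interval
            has_tss = any(
                seg.state == "TSS"
                and seg.interval.chrom == iv.chrom
                and overlap_len(seg.interval.start, seg.interval.end, iv.start, iv.end)
                >= config.tss_overlap_nt
                for seg in chromatin_segments
            )
            if not has_tss:
                continue
        calls.append(
            UaRNACall(
                cluster_id=cluster.cluster_id,
                host_gene_ids=hosts,
                evidence_source=evidence_source,
                orientation=orientation,
            )
        )
    return calls


def intersect_calls(cage_calls, chromatin_calls):
    """Split call sets into (cage_only, chromatin_only, both) cluster ids."""
    cage_ids = {c.cluster_id for c in cage_calls}
    chrom_ids = {c.cluster_id for c in chromatin_calls}
    both = cage_ids & chrom_ids
    return (
        sorted(cage_ids - both),
        sorted(chrom_ids - both),
        sorted(both),
    )
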