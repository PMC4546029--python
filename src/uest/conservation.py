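"""Per-cluster and per-class conservation-score summaries.

The score track holds per-base posterior probabilities of negative selection
(phastCons semantics, values in [0, 1]).  Each cluster gets the mean score
over its *scored* bases — unscored bases are excluded from the denominator
rather than imputed as zero — and each class gets the unweighted mean over
its clusters' means.  Background sets (introns, exons, genome windows, the
genes hosting clusters) are summarized the same way for comparison.
"""

from __future__ import annotations

import math
import warnings

from .classify import ClusterClass, REAL_CLASSES
from .core import GenomicInterval
from .io_formats import CoverageTrack


def validate_track(track: CoverageTrack) -> None:
    """Warn (not fail) when values stray outside [0, 1] — real tracks round."""
    for chrom in track.chroms:
        for s, e, v in track.runs(chrom):
            if not (0.0 <= v <= 1.0):
                warnings.warn(
                    f"conservation value {v} outside [0,1] at {chrom}:{s}-{e}",
                    stacklevel=2,
                )
                return


def mean_score(
    interval: GenomicInterval, track: CoverageTrack
) -> tuple[float, int]:
    """Mean score over the scored bases of ``interval``.

    Returns ``(mean, n_scored_bases)``; with zero scored bases the mean is
    ``nan`` and such intervals are excluded from class means.
    """
    m, covered = track.mean(interval)
    if m is None:
        return math.nan, 0
    return m, covered


def interval_set_mean(intervals, track: CoverageTrack) -> float:
    """Mean over per-interval means (each interval weighted equally)."""
    means = [m for m, n in (mean_score(iv, track) for iv in intervals) if n > 0]
    return sum(means) / len(means) if means else math.nan


def class_conservation(
    clusters,
    classes: dict[str, ClusterClass],
    track: CoverageTrack,
    backgrounds: dict[str, list[GenomicInterval]] | None = None,
    excluded_cluster_ids=(),
    tex_cds: dict[str, list[GenomicInterval]] | None = None,
) -> dict[str, float]:
    """Per-class mean of per-cluster means, plus background rows.

    ``excluded_cluster_ids`` supports masking (e.g. intergenic clusters with
    a significant protein-coding signal from an external hit list).
    ``tex_cds`` optionally maps the subdivision labels
    ``TEX_cds`` / ``TEX_partial_cds`` / ``TEX_noncoding`` to interval lists
    for the heterogeneous totally-exonic class.  The ``AVG`` row is the
    unweighted mean over the per-class means of the real cluster classes.
    """
    validate_track(track)
    excluded = set(excluded_cluster_ids)
    per_class: dict[ClusterClass, list[float]] = {cls: [] for cls in ClusterClass}
    for c in clusters:
        if c.cluster_id in excluded:
            continue
        cls = classes.get(c.cluster_id)
        if cls is None:
            continue
        m, n = mean_score(c.interval, track)
        if n > 0:
            per_class[cls].append(m)

    table: dict[str, float] = {}
    for cls in ClusterClass:
        vals = per_class[cls]
        table[str(cls)] = sum(vals) / len(vals) if vals else math.nan
    real_means = [table[str(cls)] for cls in REAL_CLASSES]
    finite = [m for m in real_means if not math.isnan(m)]
    table["AVG"] = sum(finite) / len(finite) if finite else math.nan

    if tex_cds:
        for label, ivs in tex_cds.items():
            table[label] = interval_set_mean(ivs, track)
    if backgrounds:
        for label, ivs in backgrounds.items():
            table[f"bg_{label}"] = interval_set_mean(ivs, track)
    return table


def genome_windows(chrom_sizes: dict[str, int], window: int = 1000):
    """Tile every chromosome into fixed windows (last partial window kept)."""
    out = []
    for chrom in sorted(chrom_sizes):
        size = chrom_sizes[chrom]
        for s in range(0, size, window):
            out.append(GenomicInterval(chrom, s, min(s + window, size), "."))
    return out
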