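"""Numeric parameters of the pipeline, with the study's published defaults.

Every threshold that the analysis depends on lives here so that a single
object can be logged, serialized into a run manifest, and overridden from the
CLI or a config file.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, fields


@dataclass(frozen=True)
class FilterConfig:
    """Tunable thresholds for EST filtering, clustering and annotation.

    Attributes
    ----------
    max_gap_nt:
        An EST alignment whose largest single genomic (target-side) gap
        exceeds this is treated as spliced and removed.  Introns shorter than
        ~30 nt are essentially unknown, so 30 separates alignment slippage
        from real splicing.
    max_mismatch_frac:
        Maximum tolerated mismatch fraction per aligned base,
        mismatches / (matches + rep_matches + mismatches).
    min_cluster_size:
        Minimum number of member ESTs for a cluster to be reported.
    cluster_join_nt:
        Two ESTs are co-clustered when they overlap or are separated by at
        most this many nt (gap ≤ cluster_join_nt joins).
    flank_nt:
        Length of the upstream/downstream flanking region attached to each
        gene; also the "in range" distance for cluster-to-gene assignment.
    min_component_overlap_nt:
        A cluster must overlap a gene component by MORE than this many nt for
        the component to count in classification (guards against small
        annotation-border errors).
    cage_window_nt:
        Length of the window at each cluster end searched for an orienting
        TSS peak.
    min_rnaseq_reads:
        Minimum read count, within a single library, for a cluster to count
        as RNA-seq supported.
    gap_mode:
        "max" (default) uses the largest single target-side gap for the
        spliced-EST filter; "sum" uses the summed inserted bases instead.
    tss_overlap_nt:
        Minimum overlap (in nt, ≥ this) with a TSS peak or chromatin segment;
        1 means any overlap counts.
    """

    max_gap_nt: int = 30
    max_mismatch_frac: float = 0.05
    min_cluster_size: int = 3
    cluster_join_nt: int = 30
    flank_nt: int = 5000
    min_component_overlap_nt: int = 20
    cage_window_nt: int = 84
    min_rnaseq_reads: int = 10
    gap_mode: str = "max"
    tss_overlap_nt: int = 1

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, (int, float)) and v <= 0:
                raise ValueError(f"{f.name} must be positive, got {v}")
        if not (0.0 < self.max_mismatch_frac < 1.0):
            raise ValueError("max_mismatch_frac must lie in (0, 1)")
        if self.gap_mode not in ("max", "sum"):
            raise ValueError("gap_mode must be 'max' or 'sum'")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "FilterConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown FilterConfig keys: {sorted(unknown)}")
        return cls(**d)
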