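"""Basic genomic-interval primitives shared by every pipeline stage.

All coordinates are 0-based half-open (BED convention) on the forward strand
of the chromosome they live on.  Strand is one of ``"+"``, ``"-"`` or ``"."``
(unknown); EST clusters are created unstranded because EST strand information
is generally unreliable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

STRANDS = ("+", "-", ".")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open interval ``[start, end)`` on a named sequence."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap_len(self, other: "GenomicInterval") -> int:
        """Number of shared bases; 0 when on different chromosomes."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.overlap_len(other) > 0

    def gap_to(self, other: "GenomicInterval") -> int | None:
        """Gap in nt between two intervals on the same chromosome.

        Overlapping or abutting intervals have gap 0.  ``None`` across
        chromosomes.
        """
        if self.chrom != other.chrom:
            return None
        if self.start <= other.start:
            return max(0, other.start - self.end)
        return max(0, self.start - other.end)

    def hull(self, other: "GenomicInterval") -> "GenomicInterval":
        if self.chrom != other.chrom:
            raise ValueError("hull requires intervals on the same chromosome")
        return GenomicInterval(
            self.chrom, min(self.start, other.start), max(self.end, other.end), "."
        )

    def shifted(self, delta: int) -> "GenomicInterval":
        return replace(self, start=self.start + delta, end=self.end + delta)


def clip(start: int, end: int, lo: int, hi: int) -> tuple[int, int] | None:
    """Clip ``[start, end)`` to ``[lo, hi)``; ``None`` when empty."""
    s, e = max(start, lo), min(end, hi)
    if s >= e:
        return None
    return s, e


def overlap_len(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start))
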