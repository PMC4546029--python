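"""Readers and writers for the UCSC text formats the pipeline touches.

Everything is normalized to 0-based half-open coordinates on entry (genePred,
PSL target coordinates and bedGraph already are; wiggle positions are 1-based
and converted).  Writers emit LF line endings and tab separation, and every
reader/writer pair round-trips byte-identically on files the writer produced.

Chromosome names are matched by exact string equality throughout; no ``chr``
prefix aliasing is applied, so mixed naming in the inputs surfaces as empty
overlaps rather than being silently hidden.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field

from .core import GenomicInterval, overlap_len
from .gene_model import GeneModel

PSL_HEADER_PREFIX = "psLayout"
PSL_N_COLUMNS = 21


class FormatError(ValueError):
    """A malformed input file; the message names the file line or record."""


# ---------------------------------------------------------------------------
# PSL (EST-to-genome alignments)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ESTAlignment:
    """One EST aligned to the genome, with PSL block structure and counts.

    ``blocks`` are ``(target_start, size)`` pairs in forward genome
    coordinates regardless of the query strand (PSL target starts are
    already genome-forward for nucleotide alignments).
    """

    est_id: str
    interval: GenomicInterval
    blocks: tuple[tuple[int, int], ...]
    matches: int
    mismatches: int
    rep_matches: int = 0
    n_count: int = 0
    q_num_insert: int = 0
    q_base_insert: int = 0
    t_num_insert: int = 0
    t_base_insert: int = 0
    strand: str = "+"
    q_size: int = 0
    q_start: int = 0
    q_end: int = 0
    t_size: int = 0
    q_starts: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        prev_end = None
        total = 0
        for s, size in self.blocks:
            if size <= 0:
                raise FormatError(f"{self.est_id}: non-positive block size")
            if not (self.interval.start <= s and s + size <= self.interval.end):
                raise FormatError(f"{self.est_id}: block outside alignment span")
            if prev_end is not None and s < prev_end:
                raise FormatError(f"{self.est_id}: blocks overlap or are unsorted")
            prev_end = s + size
            total += size
        if total > len(self.interval):
            raise FormatError(f"{self.est_id}: block sizes exceed alignment span")
        for name in ("matches", "mismatches", "rep_matches", "n_count",
                     "t_base_insert", "q_base_insert"):
            if getattr(self, name) < 0:
                raise FormatError(f"{self.est_id}: negative {name}")

    @property
    def aligned_bases(self) -> int:
        return self.matches + self.rep_matches + self.mismatches

    @property
    def mismatch_frac(self) -> float:
        denom = self.aligned_bases
        return self.mismatches / denom if denom else 0.0

    def target_gaps(self) -> list[int]:
        """Genomic gap lengths between consecutive aligned blocks."""
        return [
            b[0] - (a[0] + a[1]) for a, b in zip(self.blocks, self.blocks[1:])
        ]

    @property
    def max_target_gap(self) -> int:
        gaps = self.target_gaps()
        return max(gaps) if gaps else 0

    @property
    def sum_target_gap(self) -> int:
        return sum(self.target_gaps())


def _split_list_field(text: str, what: str, line_no: int) -> tuple[int, ...]:
    try:
        return tuple(int(x) for x in text.rstrip(",").split(",") if x != "")
    except ValueError as exc:
        raise FormatError(f"line {line_no}: non-numeric {what} field") from exc


def read_psl(path) -> list[ESTAlignment]:
    """Parse a 21-column PSL file, with or without the 5-line header."""
    out: list[ESTAlignment] = []
    with open(path, "rt", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    start = 0
    if lines and lines[0].startswith(PSL_HEADER_PREFIX):
        # header is 5 lines, the last of which is a dashed rule
        for i, line in enumerate(lines[:6]):
            if set(line) == {"-"}:
                start = i + 1
                break
        else:
            raise FormatError("PSL header present but no dashed rule found")
    for line_no, line in enumerate(lines[start:], start + 1):
        if not line.strip():
            continue
        cols = line.split("\t")
        if len(cols) != PSL_N_COLUMNS:
            raise FormatError(
                f"line {line_no}: expected {PSL_N_COLUMNS} PSL columns, got {len(cols)}"
            )
        try:
            (matches, mismatches, rep_matches, n_count, q_num_insert,
             q_base_insert, t_num_insert, t_base_insert) = map(int, cols[:8])
            strand = cols[8]
            q_name = cols[9]
            q_size, q_start, q_end = map(int, cols[10:13])
            t_name = cols[13]
            t_size, t_start, t_end = map(int, cols[14:17])
            block_count = int(cols[17])
        except ValueError as exc:
            raise FormatError(f"line {line_no}: non-numeric coordinate") from exc
        block_sizes = _split_list_field(cols[18], "blockSizes", line_no)
        q_starts = _split_list_field(cols[19], "qStarts", line_no)
        t_starts = _split_list_field(cols[20], "tStarts", line_no)
        if not (len(block_sizes) == len(q_starts) == len(t_starts) == block_count):
            raise FormatError(f"line {line_no}: blockCount mismatch with lists")
        out.append(
            ESTAlignment(
                est_id=q_name,
                interval=GenomicInterval(t_name, t_start, t_end, "."),
                blocks=tuple(zip(t_starts, block_sizes)),
                matches=matches,
                mismatches=mismatches,
                rep_matches=rep_matches,
                n_count=n_count,
                q_num_insert=q_num_insert,
                q_base_insert=q_base_insert,
                t_num_insert=t_num_insert,
                t_base_insert=t_base_insert,
                strand=strand,
                q_size=q_size,
                q_start=q_start,
                q_end=q_end,
                t_size=t_size,
                q_starts=q_starts,
            )
        )
    return out


def write_psl(alignments, path) -> None:
    with open(path, "wt", encoding="utf-8", newline="\n") as fh:
        for a in alignments:
            sizes = ",".join(str(size) for _, size in a.blocks) + ","
            q_starts = ",".join(map(str, a.q_starts)) + ","
            t_starts = ",".join(str(s) for s, _ in a.blocks) + ","
            fh.write(
                "\t".join(
                    map(
                        str,
                        (
                            a.matches, a.mismatches, a.rep_matches, a.n_count,
                            a.q_num_insert, a.q_base_insert, a.t_num_insert,
                            a.t_base_insert, a.strand, a.est_id, a.q_size,
                            a.q_start, a.q_end, a.interval.chrom, a.t_size,
                            a.interval.start, a.interval.end, len(a.blocks),
                            sizes, q_starts, t_starts,
                        ),
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# genePred (gene models)
# ---------------------------------------------------------------------------

def read_genepred(path) -> list[GeneModel]:
    """Parse UCSC genePred (10+ columns); ``cdsStart == cdsEnd`` → non-coding."""
    out: list[GeneModel] = []
    with open(path, "rt", encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 10:
                raise FormatError(f"line {line_no}: genePred needs >= 10 columns")
            name, chrom, strand = cols[0], cols[1], cols[2]
            try:
                tx_start, tx_end, cds_start, cds_end = map(int, cols[3:7])
                exon_count = int(cols[7])
            except ValueError as exc:
                raise FormatError(f"line {line_no}: non-numeric coordinate") from exc
            exon_starts = _split_list_field(cols[8], "exonStarts", line_no)
            exon_ends = _split_list_field(cols[9], "exonEnds", line_no)
            if not (len(exon_starts) == len(exon_ends) == exon_count):
                raise FormatError(f"line {line_no}: exonCount mismatch with lists")
            cds = None if cds_start == cds_end else (cds_start, cds_end)
            out.append(
                GeneModel(
                    gene_id=name,
                    interval=GenomicInterval(chrom, tx_start, tx_end, strand),
                    exons=tuple(zip(exon_starts, exon_ends)),
                    cds=cds,
                )
            )
    return out


def write_genepred(genes, path) -> None:
    with open(path, "wt", encoding="utf-8", newline="\n") as fh:
        for g in genes:
            cds = g.cds if g.cds is not None else (g.interval.end, g.interval.end)
            fh.write(
                "\t".join(
                    map(
                        str,
                        (
                            g.gene_id, g.chrom, g.strand,
                            g.interval.start, g.interval.end, cds[0], cds[1],
                            len(g.exons),
                            ",".join(str(s) for s, _ in g.exons) + ",",
                            ",".join(str(e) for _, e in g.exons) + ",",
                        ),
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BedRecord:
    interval: GenomicInterval
    name: str = "."
    score: str = "0"
    extra: tuple[str, ...] = ()

    @property
    def chrom(self) -> str:
        return self.interval.chrom


def read_bed(path, min_fields: int = 3) -> list[BedRecord]:
    """Read BED3/4/6+; strand (field 6) is attached to the interval."""
    out: list[BedRecord] = []
    with open(path, "rt", encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < min_fields or len(cols) < 3:
                raise FormatError(f"line {line_no}: expected >= {min_fields} BED fields")
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError as exc:
                raise FormatError(f"line {line_no}: non-numeric coordinate") from exc
            strand = cols[5] if len(cols) >= 6 and cols[5] in ("+", "-") else "."
            out.append(
                BedRecord(
                    interval=GenomicInterval(cols[0], start, end, strand),
                    name=cols[3] if len(cols) >= 4 else ".",
                    score=cols[4] if len(cols) >= 5 else "0",
                    extra=tuple(cols[6:]),
                )
            )
    return out


def write_bed(records, path) -> None:
    with open(path, "wt", encoding="utf-8", newline="\n") as fh:
        for r in records:
            cols = [
                r.interval.chrom, str(r.interval.start), str(r.interval.end),
                r.name, r.score, r.interval.strand,
            ]
            cols.extend(r.extra)
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# UCSC chain
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChainAlignment:
    """A colinear gapped alignment between a source and a target genome.

    Follows the UCSC chain header order where the first-named sequence is the
    reference the chain was built on; we call it the *source* and the second
    the *target* (``liftOver`` maps source coordinates to target
    coordinates).  ``blocks`` are ``(aligned_size, source_gap_after,
    target_gap_after)``; the last block has zero gaps.  Start/end coordinates
    are on the stated strand of each sequence, as in the file format.
    """

    chain_id: str
    score: int
    src_chrom: str
    src_size: int
    src_strand: str
    src_start: int
    src_end: int
    tgt_chrom: str
    tgt_size: int
    tgt_strand: str
    tgt_start: int
    tgt_end: int
    blocks: tuple[tuple[int, int, int], ...]

    def __post_init__(self) -> None:
        if not self.blocks:
            raise FormatError(f"chain {self.chain_id}: no blocks")
        if self.blocks[-1][1] != 0 or self.blocks[-1][2] != 0:
            raise FormatError(f"chain {self.chain_id}: last block must have zero gaps")
        src_total = tgt_total = 0
        for size, dsrc, dtgt in self.blocks:
            if size <= 0 or dsrc < 0 or dtgt < 0:
                raise FormatError(f"chain {self.chain_id}: invalid block sizes")
            src_total += size + dsrc
            tgt_total += size + dtgt
        if src_total != self.src_end - self.src_start:
            raise FormatError(
                f"chain {self.chain_id}: block arithmetic does not reconstruct "
                f"the source span ({src_total} vs {self.src_end - self.src_start})"
            )
        if tgt_total != self.tgt_end - self.tgt_start:
            raise FormatError(
                f"chain {self.chain_id}: block arithmetic does not reconstruct "
                f"the target span ({tgt_total} vs {self.tgt_end - self.tgt_start})"
            )


def read_chain(path) -> list[ChainAlignment]:
    out: list[ChainAlignment] = []
    with open(path, "rt", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        i += 1
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if parts[0] != "chain" or len(parts) != 13:
            raise FormatError(f"line {i}: expected 13-field chain header")
        (score, s_chrom, s_size, s_strand, s_start, s_end,
         t_chrom, t_size, t_strand, t_start, t_end, chain_id) = parts[1:]
        blocks: list[tuple[int, int, int]] = []
        while i < len(lines):
            row = lines[i].strip()
            i += 1
            if not row:
                break
            nums = row.split()
            if len(nums) == 1:
                blocks.append((int(nums[0]), 0, 0))
                break
            if len(nums) != 3:
                raise FormatError(f"chain {chain_id}: malformed block line {row!r}")
            blocks.append((int(nums[0]), int(nums[1]), int(nums[2])))
        out.append(
            ChainAlignment(
                chain_id=chain_id,
                score=int(score),
                src_chrom=s_chrom, src_size=int(s_size), src_strand=s_strand,
                src_start=int(s_start), src_end=int(s_end),
                tgt_chrom=t_chrom, tgt_size=int(t_size), tgt_strand=t_strand,
                tgt_start=int(t_start), tgt_end=int(t_end),
                blocks=tuple(blocks),
            )
        )
    return out


def write_chain(chains, path) -> None:
    with open(path, "wt", encoding="utf-8", newline="\n") as fh:
        for c in chains:
            fh.write(
                " ".join(
                    map(
                        str,
                        (
                            "chain", c.score, c.src_chrom, c.src_size,
                            c.src_strand, c.src_start, c.src_end,
                            c.tgt_chrom, c.tgt_size, c.tgt_strand,
                            c.tgt_start, c.tgt_end, c.chain_id,
                        ),
                    )
                )
                + "\n"
            )
            for size, dsrc, dtgt in c.blocks[:-1]:
                fh.write(f"{size} {dsrc} {dtgt}\n")
            fh.write(f"{c.blocks[-1][0]}\n\n")


# ---------------------------------------------------------------------------
# Coverage tracks (bedGraph / wiggle)
# ---------------------------------------------------------------------------

class CoverageTrack:
    """Per-chromosome sorted, non-overlapping ``(start, end, value)`` runs."""

    def __init__(self, data: dict[str, list[tuple[int, int, float]]] | None = None):
        self._data: dict[str, list[tuple[int, int, float]]] = {}
        self._starts: dict[str, list[int]] = {}
        if data:
            for chrom, runs in data.items():
                for run in runs:
                    self.add(chrom, *run)
            self._finalize()

    def add(self, chrom: str, start: int, end: int, value: float) -> None:
        if start >= end:
            raise FormatError(f"{chrom}:{start}-{end}: empty coverage interval")
        value = float(value)
        if value != value or value in (float("inf"), float("-inf")):
            raise FormatError(f"{chrom}:{start}-{end}: non-finite value")
        self._data.setdefault(chrom, []).append((start, end, value))

    def _finalize(self) -> None:
        for chrom, runs in self._data.items():
            runs.sort()
            for a, b in zip(runs, runs[1:]):
                if b[0] < a[1]:
                    raise FormatError(
                        f"{chrom}: overlapping coverage intervals at {b[0]}"
                    )
            self._starts[chrom] = [r[0] for r in runs]

    @property
    def chroms(self) -> list[str]:
        return sorted(self._data)

    def runs(self, chrom: str) -> list[tuple[int, int, float]]:
        return self._data.get(chrom, [])

    def _intersecting(self, interval: GenomicInterval):
        runs = self._data.get(interval.chrom)
        if not runs:
            return
        starts = self._starts[interval.chrom]
        i = bisect.bisect_right(starts, interval.start) - 1
        if i < 0:
            i = 0
        while i < len(runs) and runs[i][0] < interval.end:
            s, e, v = runs[i]
            if e > interval.start:
                yield s, e, v
            i += 1

    def mean(self, interval: GenomicInterval) -> tuple[float | None, int]:
        """Coverage-weighted mean over the scored bases inside ``interval``.

        Returns ``(mean, n_scored_bases)``; mean is ``None`` when no base of
        the interval is scored.
        """
        total = 0.0
        covered = 0
        for s, e, v in self._intersecting(interval):
            n = overlap_len(s, e, interval.start, interval.end)
            total += v * n
            covered += n
        if covered == 0:
            return None, 0
        return total / covered, covered

    def sum_intersecting(self, interval: GenomicInterval) -> float:
        """Sum of the (whole-interval) values of runs touching ``interval``.

        Used for read-count tracks where each run's value is a count that
        should not be prorated by the overlapped fraction.
        """
        return sum(v for _, _, v in self._intersecting(interval))


def read_bedgraph(path) -> CoverageTrack:
    track = CoverageTrack()
    with open(path, "rt", encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 4:
                raise FormatError(f"line {line_no}: bedGraph needs 4 columns")
            try:
                track.add(cols[0], int(cols[1]), int(cols[2]), float(cols[3]))
            except ValueError as exc:
                raise FormatError(f"line {line_no}: malformed bedGraph row") from exc
    track._finalize()
    return track


def _format_value(v: float) -> str:
    return str(int(v)) if float(v).is_integer() else repr(float(v))


def write_bedgraph(track: CoverageTrack, path) -> None:
    with open(path, "wt", encoding="utf-8", newline="\n") as fh:
        for chrom in track.chroms:
            for s, e, v in track.runs(chrom):
                fh.write(f"{chrom}\t{s}\t{e}\t{_format_value(v)}\n")


def read_wiggle(path) -> CoverageTrack:
    """Read fixedStep/variableStep wiggle; positions are 1-based in the file."""
    track = CoverageTrack()
    mode = None
    chrom = ""
    step = span = 1
    pos = 0  # 0-based position of the next fixedStep value
    with open(path, "rt", encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            if line.startswith(("fixedStep", "variableStep")):
                fieldsets = dict(
                    kv.split("=", 1) for kv in line.split()[1:] if "=" in kv
                )
                mode = line.split()[0]
                chrom = fieldsets.get("chrom", "")
                if not chrom:
                    raise FormatError(f"line {line_no}: wiggle header without chrom")
                span = int(fieldsets.get("span", 1))
                if mode == "fixedStep":
                    step = int(fieldsets.get("step", 1))
                    pos = int(fieldsets["start"]) - 1
                continue
            if mode is None:
                raise FormatError(f"line {line_no}: data before wiggle header")
            parts = line.split()
            try:
                if mode == "fixedStep":
                    track.add(chrom, pos, pos + span, float(parts[0]))
                    pos += step
                else:
                    p = int(parts[0]) - 1
                    track.add(chrom, p, p + span, float(parts[1]))
            except (ValueError, IndexError) as exc:
                raise FormatError(f"line {line_no}: malformed wiggle row") from exc
    track._finalize()
    return track


def write_wiggle(track: CoverageTrack, path, span: int = 1) -> None:
    """Write as variableStep with a uniform ``span``.

    Every run in the track must have length exactly ``span``; tracks with
    ragged runs belong in bedGraph instead.
    """
    with open(path, "wt", encoding="utf-8", newline="\n") as fh:
        for chrom in track.chroms:
            fh.write(f"variableStep chrom={chrom} span={span}\n")
            for s, e, v in track.runs(chrom):
                if e - s != span:
                    raise FormatError(
                        f"{chrom}:{s}-{e}: run length {e - s} != span {span}"
                    )
                fh.write(f"{s + 1} {_format_value(v)}\n")
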