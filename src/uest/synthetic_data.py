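"""Synthetic genome bundles with planted ground truth for every stage.

The generator lays out gene "zones" along each chromosome.  Every zone hosts
one six-exon gene (400-nt exons, 1500-nt introns, 200-nt UTRs) plus one
planted EST cluster per requested class, positioned so the class is
geometrically unambiguous: deciding overlaps exceed the 20-nt component
threshold by a wide margin, distinct clusters are separated by more than the
30-nt join distance, and intergenic plants sit more than 5 kb from any gene.
Each planted cluster is realized as >= 3 overlapping unspliced EST
alignments whose union is exactly the planted interval.  Decoy alignments
violating exactly one filter each (spliced gap, mismatch rate, NUMT overlap,
haplotype chromosome) are mixed in at configured counts.

For two-genome scenarios, genome B is genome A pushed through an explicit
chain map (small indels between zones, plus one large B-only insertion that
hosts genome-B-specific genes), so a subset of planted clusters has an exact
orthologous partner and everything else is genuinely lineage-specific.

Only coordinates and counts are simulated — the pipeline never looks at
sequence content.  All randomness flows from one seeded generator.
"""

from __future__ import annotations

import bisect
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .config import FilterConfig
from .core import GenomicInterval
from .gene_model import GeneModel
from .io_formats import (
    BedRecord,
    ChainAlignment,
    CoverageTrack,
    ESTAlignment,
    write_bed,
    write_bedgraph,
    write_chain,
    write_genepred,
    write_psl,
)

# -- fixed gene architecture ------------------------------------------------
EXON_LEN = 400
INTRON_LEN = 1500
N_EXONS = 6
GENE_SPAN = N_EXONS * EXON_LEN + (N_EXONS - 1) * INTRON_LEN  # 9900
UTR_LEN = 200

# planted-cluster placements for a plus-strand gene, as (start, end) offsets
# relative to txStart; a minus-strand gene uses the mirror image (the gene
# architecture is symmetric, so mirrored geometry realizes the same class)
_PLUS_TEMPLATE: dict[str, tuple[int, int]] = {
    "5R": (-150, 100),
    "5PIN": (350, 550),
    "3PIN": (1750, 1950),
    "TEX": (2000, 2200),
    "TIN": (2950, 3150),
    "rI": (4150, 5750),
    "NO_CLASS": (7550, 8050),
    "3R": (9800, 10050),
    "UT": (-2500, -2300),
    "DT": (12200, 12400),
}
_IGR_OFFSET = (20000, 20200)       # relative to txStart, outside the 5-kb range
_NUMT_OFFSET = (16000, 16500)
_SMALL_INDEL_OFFSET = 18500        # chain indels go here: outside all features
_DECOY_SPLICED_OFFSET = 23000
_DECOY_MISMATCH_OFFSET = 26000

DEFAULT_CLASSES = ("TEX", "TIN", "5PIN", "3PIN", "rI", "5R", "3R", "UT", "DT")
ORIENT_CHOICES = ("forward", "reverse", "none", "bidirectional")
ORIENT_PROBS = (0.3, 0.3, 0.3, 0.1)


@dataclass(frozen=True)
class ScenarioConfig:
    """Everything that determines a generated bundle, seed included."""

    seed: int = 0
    n_chromosomes: int = 2
    chrom_length_nt: int = 2_000_000
    genes_per_chrom: int = 30
    gene_pitch_nt: int = 32_000
    first_gene_offset_nt: int = 10_000
    classes_per_gene: tuple[str, ...] = DEFAULT_CLASSES
    igr_per_zone: int = 1
    ests_per_cluster_min: int = 3
    ests_per_cluster_max: int = 6
    est_two_block_frac: float = 0.3
    est_internal_gap_nt: int = 10
    est_mismatch_rate: float = 0.01
    n_decoy_spliced: int = 200
    n_decoy_mismatch: int = 100
    n_decoy_numt: int = 50
    n_decoy_haplotype: int = 30
    haplotype_chrom: str = "chr6_synthetic_hap1"
    decoy_mismatch_rate: float = 0.08
    uarna_count: int = 50
    cage_peak_width_nt: int = 10
    cage_jitter_nt: int = 0
    n_cell_types: int = 3
    rnaseq_supported_frac: float = 0.95
    n_rnaseq_libraries: int = 2
    chromatin_t_frac: float = 0.5
    conservation_base: float = 0.10
    conservation_exon_elevation: float = 0.30
    conservation_noise_sd: float = 0.005
    two_genomes: bool = True
    b_only_genes_per_chrom: int = 25
    n_conserved: int = 100
    small_indel_nt: int = 40

    def __post_init__(self) -> None:
        if self.ests_per_cluster_min < 3:
            raise ValueError("clusters need at least three member ESTs")
        for name in ("est_two_block_frac", "est_mismatch_rate",
                     "rnaseq_supported_frac", "chromatin_t_frac"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        # the intergenic plant must stay > 5 kb from both neighbouring genes
        min_pitch = _IGR_OFFSET[1] + self.igr_per_zone * 400 + FilterConfig().flank_nt
        if self.gene_pitch_nt < min_pitch:
            raise ValueError("gene_pitch_nt too small for the zone layout")
        last_zone_end = (
            self.first_gene_offset_nt
            + (self.genes_per_chrom - 1) * self.gene_pitch_nt
            + _DECOY_MISMATCH_OFFSET + 2000 + 1000
        )
        if last_zone_end > self.chrom_length_nt:
            raise ValueError(
                "infeasible packing: too many genes for the chromosome length"
            )


@dataclass
class Plant:
    """One planted cluster with its full intended truth."""

    key: str
    chrom: str
    start: int
    end: int
    cls: str
    orientation: str = "none"
    uarna: bool = False
    rnaseq_supported: bool = True
    has_tss_state: bool = False
    has_t_state: bool = False
    breadth: int = 0
    partner: str = ""


@dataclass
class GroundTruth:
    clusters: pd.DataFrame  # one row per plant
    ests: pd.DataFrame      # est_id, survives, violation


@dataclass
class Scenario:
    config: ScenarioConfig
    root: Path
    paths: dict
    truth_a: GroundTruth
    truth_b: GroundTruth | None = None


# ---------------------------------------------------------------------------
# layout helpers
# ---------------------------------------------------------------------------

def _gene_exons(tx_start: int) -> tuple[tuple[int, int], ...]:
    return tuple(
        (tx_start + k * (EXON_LEN + INTRON_LEN),
         tx_start + k * (EXON_LEN + INTRON_LEN) + EXON_LEN)
        for k in range(N_EXONS)
    )


def _make_gene(gene_id: str, chrom: str, tx_start: int, strand: str) -> GeneModel:
    return GeneModel(
        gene_id=gene_id,
        interval=GenomicInterval(chrom, tx_start, tx_start + GENE_SPAN, strand),
        exons=_gene_exons(tx_start),
        cds=(tx_start + UTR_LEN, tx_start + GENE_SPAN - UTR_LEN),
    )


def _template_interval(tx_start: int, strand: str, cls: str) -> tuple[int, int]:
    off_s, off_e = _PLUS_TEMPLATE[cls]
    if strand == "+":
        return tx_start + off_s, tx_start + off_e
    return tx_start + GENE_SPAN - off_e, tx_start + GENE_SPAN - off_s


# ---------------------------------------------------------------------------
# chain map between genome A and genome B
# ---------------------------------------------------------------------------

@dataclass
class _ChainMap:
    """Piecewise A→B coordinate map plus the chain pair realizing it."""

    segments: list[tuple[int, int, int]]  # (a_start, a_end, delta) aligned runs
    src_len: int
    tgt_len: int
    _starts: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._starts = [s for s, _, _ in self.segments]

    def map_pos(self, a_pos: int) -> int:
        i = bisect.bisect_right(self._starts, a_pos) - 1
        if i < 0:
            raise ValueError(f"position {a_pos} before first aligned segment")
        s, e, delta = self.segments[i]
        if not (s <= a_pos < e):
            raise ValueError(f"position {a_pos} falls in a chain gap")
        return a_pos + delta

    def map_span(self, start: int, end: int) -> tuple[int, int]:
        b = self.map_pos(start)
        # spans planted by the generator never cross an indel
        assert self.map_pos(end - 1) == b + (end - start) - 1
        return b, b + (end - start)


def _build_chain_map(
    length: int, events: list[tuple[int, int, int]]
) -> _ChainMap:
    """``events`` are (a_pos, a_only_nt, b_only_nt), sorted, non-adjacent."""
    segments = []
    a = 0
    delta = 0
    for pos, d_a, d_b in events:
        if pos > a:
            segments.append((a, pos, delta))
        a = pos + d_a
        delta += d_b - d_a
    if a < length:
        segments.append((a, length, delta))
    tgt_len = length + sum(e[2] - e[1] for e in events)
    return _ChainMap(segments=segments, src_len=length, tgt_len=tgt_len)


def _chains_from_map(
    cmap: _ChainMap,
    events: list[tuple[int, int, int]],
    src_chrom: str,
    tgt_chrom: str,
    chain_id: str,
) -> tuple[ChainAlignment, ChainAlignment]:
    """Forward (A→B) and inverse (B→A) chains covering the whole chromosome."""
    blocks_fwd: list[tuple[int, int, int]] = []
    prev = 0
    for pos, d_a, d_b in events:
        blocks_fwd.append((pos - prev, d_a, d_b))
        prev = pos + d_a
    blocks_fwd.append((cmap.src_len - prev, 0, 0))
    blocks_inv = [(size, d_b, d_a) for size, d_a, d_b in blocks_fwd]
    fwd = ChainAlignment(
        chain_id=chain_id, score=1000,
        src_chrom=src_chrom, src_size=cmap.src_len, src_strand="+",
        src_start=0, src_end=cmap.src_len,
        tgt_chrom=tgt_chrom, tgt_size=cmap.tgt_len, tgt_strand="+",
        tgt_start=0, tgt_end=cmap.tgt_len,
        blocks=tuple(blocks_fwd),
    )
    inv = ChainAlignment(
        chain_id=chain_id, score=1000,
        src_chrom=tgt_chrom, src_size=cmap.tgt_len, src_strand="+",
        src_start=0, src_end=cmap.tgt_len,
        tgt_chrom=src_chrom, tgt_size=cmap.src_len, tgt_strand="+",
        tgt_start=0, tgt_end=cmap.src_len,
        blocks=tuple(blocks_inv),
    )
    return fwd, inv


# ---------------------------------------------------------------------------
# per-genome emission
# ---------------------------------------------------------------------------

def _plant_ests(
    plant: Plant, cfg: ScenarioConfig, rng: np.random.Generator,
    chrom_size: int, est_counter: list[int], prefix: str,
) -> list[ESTAlignment]:
    """>= 3 overlapping unspliced alignments whose union is the plant hull."""
    n = int(rng.integers(cfg.ests_per_cluster_min, cfg.ests_per_cluster_max + 1))
    s, e = plant.start, plant.end
    length = e - s
    cuts = [s + round(k * length / n) for k in range(n + 1)]
    out = []
    for k in range(n):
        a_start = cuts[k] - (5 if k > 0 else 0)
        a_end = cuts[k + 1]
        est_counter[0] += 1
        est_id = f"{prefix}{est_counter[0]:07d}"
        span = a_end - a_start
        gap = cfg.est_internal_gap_nt
        if span >= 3 * gap and rng.random() < cfg.est_two_block_frac:
            half = (span - gap) // 2
            blocks = ((a_start, half), (a_start + half + gap, span - gap - half))
        else:
            blocks = ((a_start, span),)
        aligned = sum(size for _, size in blocks)
        mism = int(round(cfg.est_mismatch_rate * aligned))
        out.append(_alignment(est_id, plant.chrom, chrom_size, blocks, aligned, mism))
    return out


def _alignment(est_id, chrom, chrom_size, blocks, aligned, mism) -> ESTAlignment:
    t_start = blocks[0][0]
    t_end = blocks[-1][0] + blocks[-1][1]
    gaps = [b[0] - (a[0] + a[1]) for a, b in zip(blocks, blocks[1:])]
    q_starts = []
    q = 0
    for _, size in blocks:
        q_starts.append(q)
        q += size
    return ESTAlignment(
        est_id=est_id,
        interval=GenomicInterval(chrom, t_start, t_end, "."),
        blocks=tuple(blocks),
        matches=aligned - mism,
        mismatches=mism,
        t_num_insert=len(blocks) - 1,
        t_base_insert=sum(gaps),
        strand="+",
        q_size=aligned,
        q_start=0,
        q_end=aligned,
        t_size=chrom_size,
        q_starts=tuple(q_starts),
    )


def _emit_genome(
    out_dir: Path,
    genes: list[GeneModel],
    plants: list[Plant],
    numts: list[tuple[str, int, int]],
    chrom_sizes: dict[str, int],
    cfg: ScenarioConfig,
    rng: np.random.Generator,
    est_prefix: str,
) -> tuple[dict, GroundTruth]:
    """Write one genome's input files; returns paths and ground truth."""
    out_dir.mkdir(parents=True, exist_ok=True)
    plants = sorted(plants, key=lambda p: (p.chrom, p.start, p.end))
    est_counter = [0]
    alignments: list[ESTAlignment] = []
    est_rows: list[tuple[str, bool, str]] = []

    for plant in plants:
        for a in _plant_ests(plant, cfg, rng, chrom_sizes[plant.chrom],
                             est_counter, est_prefix):
            alignments.append(a)
            est_rows.append((a.est_id, True, ""))

    # --- decoys: each violates exactly one filter ---
    zone_anchors = [
        (g.chrom, g.interval.start) for g in genes
    ] or [(sorted(chrom_sizes)[0], cfg.first_gene_offset_nt)]

    def _anchor() -> tuple[str, int]:
        chrom, tx = zone_anchors[int(rng.integers(len(zone_anchors)))]
        return chrom, tx

    for _ in range(cfg.n_decoy_spliced):
        chrom, tx = _anchor()
        pos = tx + _DECOY_SPLICED_OFFSET + int(rng.integers(0, 2000))
        gap = int(rng.integers(100, 1000))
        blocks = ((pos, 80), (pos + 80 + gap, 80))
        est_counter[0] += 1
        a = _alignment(f"{est_prefix}{est_counter[0]:07d}", chrom,
                       chrom_sizes[chrom], blocks, 160,
                       int(round(cfg.est_mismatch_rate * 160)))
        alignments.append(a)
        est_rows.append((a.est_id, False, "gap"))
    for _ in range(cfg.n_decoy_mismatch):
        chrom, tx = _anchor()
        pos = tx + _DECOY_MISMATCH_OFFSET + int(rng.integers(0, 2000))
        est_counter[0] += 1
        a = _alignment(f"{est_prefix}{est_counter[0]:07d}", chrom,
                       chrom_sizes[chrom], ((pos, 150),), 150,
                       int(round(cfg.decoy_mismatch_rate * 150)))
        alignments.append(a)
        est_rows.append((a.est_id, False, "mismatch"))
    numt_list = list(numts)
    for i in range(cfg.n_decoy_numt):
        chrom, ns, ne = numt_list[i % len(numt_list)]
        pos = ns + int(rng.integers(0, max(1, (ne - ns) - 120)))
        est_counter[0] += 1
        a = _alignment(f"{est_prefix}{est_counter[0]:07d}", chrom,
                       chrom_sizes[chrom], ((pos, 100),), 100, 1)
        alignments.append(a)
        est_rows.append((a.est_id, False, "numt"))
    for _ in range(cfg.n_decoy_haplotype):
        pos = int(rng.integers(0, 100_000))
        est_counter[0] += 1
        a = _alignment(f"{est_prefix}{est_counter[0]:07d}",
                       cfg.haplotype_chrom, 200_000, ((pos, 120),), 120, 1)
        alignments.append(a)
        est_rows.append((a.est_id, False, "haplotype"))

    # --- CAGE peaks (pooled set + per-cell sets) ---
    w = cfg.cage_peak_width_nt
    peaks: list[BedRecord] = []
    cells: dict[str, list[BedRecord]] = {
        f"cell_{i + 1:02d}": [] for i in range(cfg.n_cell_types)
    }
    cell_names = sorted(cells)
    for plant in plants:
        plant_peaks: list[BedRecord] = []
        jitter = (
            int(rng.integers(-cfg.cage_jitter_nt, cfg.cage_jitter_nt + 1))
            if cfg.cage_jitter_nt else 0
        )
        if plant.orientation in ("forward", "bidirectional"):
            s = plant.start + 10 + jitter
            plant_peaks.append(BedRecord(
                GenomicInterval(plant.chrom, s, s + w, "+"), f"p_{plant.key}_f", "1"))
        if plant.orientation in ("reverse", "bidirectional"):
            e = plant.end - 10 - jitter
            plant_peaks.append(BedRecord(
                GenomicInterval(plant.chrom, e - w, e, "-"), f"p_{plant.key}_r", "1"))
        peaks.extend(plant_peaks)
        if plant.orientation in ("forward", "reverse"):
            plant.breadth = int(rng.integers(0, cfg.n_cell_types + 1))
            for cell in cell_names[: plant.breadth]:
                cells[cell].extend(plant_peaks)

    # --- chromatin segments ---
    segments: list[BedRecord] = []
    window = FilterConfig().cage_window_nt
    for plant in plants:
        if plant.orientation in ("forward", "reverse"):
            if plant.orientation == "forward":
                seg = (plant.start, min(plant.end, plant.start + window))
            else:
                seg = (max(plant.start, plant.end - window), plant.end)
            segments.append(BedRecord(
                GenomicInterval(plant.chrom, seg[0], seg[1], "."),
                "TSS", "0", extra=("cl1",)))
            plant.has_tss_state = True
        if rng.random() < cfg.chromatin_t_frac:
            segments.append(BedRecord(
                GenomicInterval(plant.chrom, plant.start, plant.end, "."),
                "T", "0", extra=("cl2",)))
            plant.has_t_state = True
    # inert background segments, away from every plant
    for g in genes:
        s = g.interval.start + 28_000
        if s + 500 < chrom_sizes[g.chrom]:
            segments.append(BedRecord(
                GenomicInterval(g.chrom, s, s + 500, "."), "R", "0", extra=("cl1",)))

    # --- RNA-seq read-count tracks ---
    libs: list[CoverageTrack] = [CoverageTrack() for _ in range(cfg.n_rnaseq_libraries)]
    for plant in plants:
        plant.rnaseq_supported = bool(rng.random() < cfg.rnaseq_supported_frac)
        if plant.rnaseq_supported:
            libs[0].add(plant.chrom, plant.start, plant.end, 12)
            if len(libs) > 1:
                libs[1].add(plant.chrom, plant.start, plant.end, 2)
        else:
            libs[0].add(plant.chrom, plant.start, plant.end, 4)
            if len(libs) > 1:
                libs[1].add(plant.chrom, plant.start, plant.end, 3)
    for t in libs:
        t._finalize()

    # --- conservation track: exons elevated over a flat background ---
    cons = CoverageTrack()
    exons_by_chrom: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_sizes}
    for g in genes:
        exons_by_chrom[g.chrom].extend(g.exons)

    def _noise() -> float:
        return float(rng.normal(0.0, cfg.conservation_noise_sd))

    for chrom in sorted(chrom_sizes):
        pos = 0
        for s, e in sorted(exons_by_chrom[chrom]):
            if pos < s:
                cons.add(chrom, pos, s,
                         round(min(1.0, max(0.0, cfg.conservation_base + _noise())), 4))
            cons.add(chrom, s, e,
                     round(min(1.0, max(0.0, cfg.conservation_base
                                        + cfg.conservation_exon_elevation + _noise())), 4))
            pos = e
        if pos < chrom_sizes[chrom]:
            cons.add(chrom, pos, chrom_sizes[chrom],
                     round(min(1.0, max(0.0, cfg.conservation_base + _noise())), 4))
    cons._finalize()

    # --- write everything ---
    paths = {
        "psl": out_dir / "ests.psl",
        "genepred": out_dir / "genes.genePred",
        "numts": out_dir / "numts.bed",
        "cage": out_dir / "cage_peaks.bed",
        "cells_dir": out_dir / "cells",
        "chromatin": out_dir / "chromatin.bed",
        "rnaseq_dir": out_dir / "rnaseq",
        "conservation": out_dir / "conservation.bedgraph",
        "chrom_sizes": out_dir / "chrom.sizes",
        "truth_clusters": out_dir / "ground_truth_clusters.tsv",
        "truth_ests": out_dir / "ground_truth_ests.tsv",
    }
    alignments.sort(key=lambda a: (a.interval.chrom, a.interval.start, a.est_id))
    write_psl(alignments, paths["psl"])
    write_genepred(sorted(genes, key=lambda g: (g.chrom, g.interval.start)),
                   paths["genepred"])
    write_bed(
        [BedRecord(GenomicInterval(c, s, e, "."), f"numt_{i + 1}", "0")
         for i, (c, s, e) in enumerate(sorted(numts))],
        paths["numts"],
    )
    peaks.sort(key=lambda r: (r.interval.chrom, r.interval.start, r.interval.strand))
    write_bed(peaks, paths["cage"])
    paths["cells_dir"].mkdir(exist_ok=True)
    for cell in cell_names:
        rows = sorted(cells[cell],
                      key=lambda r: (r.interval.chrom, r.interval.start, r.interval.strand))
        write_bed(rows, paths["cells_dir"] / f"{cell}.bed")
    segments.sort(key=lambda r: (r.interval.chrom, r.interval.start, r.name))
    write_bed(segments, paths["chromatin"])
    paths["rnaseq_dir"].mkdir(exist_ok=True)
    for i, t in enumerate(libs):
        write_bedgraph(t, paths["rnaseq_dir"] / f"lib_{i + 1:02d}.bedgraph")
    write_bedgraph(cons, paths["conservation"])
    with open(paths["chrom_sizes"], "wt", encoding="utf-8", newline="\n") as fh:
        for chrom in sorted(chrom_sizes):
            fh.write(f"{chrom}\t{chrom_sizes[chrom]}\n")

    truth_clusters = pd.DataFrame([asdict(p) for p in plants])
    truth_ests = pd.DataFrame(est_rows, columns=["est_id", "survives", "violation"])
    truth_clusters.to_csv(paths["truth_clusters"], sep="\t", index=False)
    truth_ests.to_csv(paths["truth_ests"], sep="\t", index=False)
    return paths, GroundTruth(clusters=truth_clusters, ests=truth_ests)


# ---------------------------------------------------------------------------
# scenario assembly
# ---------------------------------------------------------------------------

def _layout_zone_plants(
    chrom: str, tx_start: int, strand: str, cfg: ScenarioConfig, key_prefix: str,
) -> list[Plant]:
    plants = []
    for cls in cfg.classes_per_gene:
        s, e = _template_interval(tx_start, strand, cls)
        plants.append(Plant(key=f"{key_prefix}_{cls}", chrom=chrom,
                            start=s, end=e, cls=cls))
    for j in range(cfg.igr_per_zone):
        s = tx_start + _IGR_OFFSET[0] + j * 400
        plants.append(Plant(key=f"{key_prefix}_IGR{j}", chrom=chrom,
                            start=s, end=s + (_IGR_OFFSET[1] - _IGR_OFFSET[0]),
                            cls="IGR"))
    return plants


def _assign_orientations(
    plants: list[Plant], cfg: ScenarioConfig, rng: np.random.Generator
) -> None:
    """3R plants: the first ``uarna_count`` (genomic order) become oriented
    uaRNAs; remaining 3R plants stay unoriented.  Everything else draws from
    the orientation mixture."""
    plants_sorted = sorted(plants, key=lambda p: (p.chrom, p.start))
    n_uarna = 0
    for p in plants_sorted:
        if p.cls == "3R":
            if n_uarna < cfg.uarna_count:
                p.orientation = "forward"
                p.uarna = True
                n_uarna += 1
            else:
                p.orientation = "none"
        else:
            p.orientation = str(rng.choice(ORIENT_CHOICES, p=ORIENT_PROBS))


def generate_scenario(config: ScenarioConfig, out_dir) -> Scenario:
    """Generate the full bundle under ``out_dir``; deterministic in the seed."""
    cfg = config
    out_dir = Path(out_dir)
    ss = np.random.SeedSequence(cfg.seed)
    rng_layout, rng_a, rng_b = (np.random.default_rng(s) for s in ss.spawn(3))

    chroms_a = [f"chrA{i + 1}" for i in range(cfg.n_chromosomes)]
    sizes_a = {c: cfg.chrom_length_nt for c in chroms_a}

    genes_a: list[GeneModel] = []
    plants_a: list[Plant] = []
    numts_a: list[tuple[str, int, int]] = []
    zone_info: list[tuple[str, int, str, str]] = []  # chrom, tx_start, strand, id
    for chrom in chroms_a:
        for i in range(cfg.genes_per_chrom):
            tx = cfg.first_gene_offset_nt + i * cfg.gene_pitch_nt
            strand = "+" if rng_layout.random() < 0.5 else "-"
            gid = f"gA_{chrom}_{i:03d}"
            genes_a.append(_make_gene(gid, chrom, tx, strand))
            zone_info.append((chrom, tx, strand, gid))
            plants_a.extend(_layout_zone_plants(chrom, tx, strand, cfg, f"A_{gid}"))
            if len(numts_a) < max(1, cfg.n_decoy_numt // 5):
                numts_a.append((chrom, tx + _NUMT_OFFSET[0], tx + _NUMT_OFFSET[1]))
    _assign_orientations(plants_a, cfg, rng_layout)

    chains_fwd: list[ChainAlignment] = []
    chains_inv: list[ChainAlignment] = []
    truth_b = None
    paths: dict = {}

    if cfg.two_genomes:
        chroms_b = [f"chrB{i + 1}" for i in range(cfg.n_chromosomes)]
        sizes_b: dict[str, int] = {}
        maps: dict[str, _ChainMap] = {}
        b_extra = (
            cfg.b_only_genes_per_chrom * cfg.gene_pitch_nt + 20_000
            if cfg.b_only_genes_per_chrom else 0
        )
        ins_anchor = cfg.chrom_length_nt - 1000
        for ca, cb in zip(chroms_a, chroms_b):
            events = []
            for chrom, tx, _, _ in zone_info:
                if chrom != ca:
                    continue
                pos = tx + _SMALL_INDEL_OFFSET
                if (tx // cfg.gene_pitch_nt) % 2 == 0:
                    events.append((pos, cfg.small_indel_nt, 0))
                else:
                    events.append((pos, 0, cfg.small_indel_nt))
            if b_extra:
                events.append((ins_anchor, 0, b_extra))
            events.sort()
            cmap = _build_chain_map(cfg.chrom_length_nt, events)
            maps[ca] = cmap
            sizes_b[cb] = cmap.tgt_len
            fwd, inv = _chains_from_map(cmap, events, ca, cb, str(len(chains_fwd) + 1))
            chains_fwd.append(fwd)
            chains_inv.append(inv)

        b_of_a = dict(zip(chroms_a, chroms_b))
        genes_b: list[GeneModel] = []
        plants_b: list[Plant] = []
        numts_b: list[tuple[str, int, int]] = []

        # images of every A gene
        for g in genes_a:
            cmap = maps[g.chrom]
            b_tx, _ = cmap.map_span(g.interval.start, g.interval.end)
            genes_b.append(_make_gene(g.gene_id.replace("gA_", "gB_", 1)
                                      .replace("chrA", "chrB"),
                                      b_of_a[g.chrom], b_tx, g.strand))
        for c, s, e in numts_a:
            bs, be = maps[c].map_span(s, e)
            numts_b.append((b_of_a[c], bs, be))

        # conserved plants: first n_conserved in genomic order
        ordered = sorted(plants_a, key=lambda p: (p.chrom, p.start))
        conserved = ordered[: cfg.n_conserved]
        for p in conserved:
            bs, be = maps[p.chrom].map_span(p.start, p.end)
            bkey = p.key.replace("A_", "B_", 1)
            plants_b.append(Plant(
                key=bkey, chrom=b_of_a[p.chrom], start=bs, end=be, cls=p.cls,
                orientation=p.orientation, uarna=p.uarna, partner=p.key,
            ))
            p.partner = bkey

        # genome-B-only genes inside the big insertion
        if cfg.b_only_genes_per_chrom:
            for ca, cb in zip(chroms_a, chroms_b):
                cmap = maps[ca]
                seg_i = bisect.bisect_right(cmap._starts, ins_anchor - 1) - 1
                delta_before = cmap.segments[seg_i][2]
                ins_b_start = ins_anchor + delta_before
                b_only_plants: list[Plant] = []
                for j in range(cfg.b_only_genes_per_chrom):
                    tx = ins_b_start + 10_000 + j * cfg.gene_pitch_nt
                    strand = "+" if rng_layout.random() < 0.5 else "-"
                    gid = f"gBonly_{cb}_{j:03d}"
                    genes_b.append(_make_gene(gid, cb, tx, strand))
                    b_only_plants.extend(
                        _layout_zone_plants(cb, tx, strand, cfg, f"B_{gid}"))
                    if len(numts_b) < 2 * max(1, cfg.n_decoy_numt // 5):
                        numts_b.append((cb, tx + _NUMT_OFFSET[0], tx + _NUMT_OFFSET[1]))
                _assign_orientations(b_only_plants, cfg, rng_layout)
                for p in b_only_plants:
                    p.uarna = p.cls == "3R" and p.orientation in ("forward", "reverse")
                plants_b.extend(b_only_plants)

        paths["genome_b"], truth_b = _emit_genome(
            out_dir / "genomeB", genes_b, plants_b, numts_b, sizes_b,
            cfg, rng_b, "estB")

    paths["genome_a"], truth_a = _emit_genome(
        out_dir / "genomeA", genes_a, plants_a, numts_a, sizes_a,
        cfg, rng_a, "estA")

    if cfg.two_genomes:
        chain_dir = out_dir / "chains"
        chain_dir.mkdir(parents=True, exist_ok=True)
        paths["chains_ab"] = chain_dir / "a_to_b.chain"
        paths["chains_ba"] = chain_dir / "b_to_a.chain"
        write_chain(chains_fwd, paths["chains_ab"])
        write_chain(chains_inv, paths["chains_ba"])

    return Scenario(config=cfg, root=out_dir, paths=paths,
                    truth_a=truth_a, truth_b=truth_b)


def toy_config(seed: int = 7) -> ScenarioConfig:
    """Configuration of the worked-toy bundle: one gene hosting one cluster
    of every class (NO_CLASS included), one intergenic cluster, one uaRNA and
    one conserved ortholog pair, on a ~50-kb chromosome."""
    return ScenarioConfig(
        seed=seed,
        n_chromosomes=1,
        chrom_length_nt=60_000,
        genes_per_chrom=1,
        classes_per_gene=DEFAULT_CLASSES + ("NO_CLASS",),
        igr_per_zone=1,
        n_decoy_spliced=2,
        n_decoy_mismatch=2,
        n_decoy_numt=2,
        n_decoy_haplotype=2,
        uarna_count=1,
        n_cell_types=2,
        rnaseq_supported_frac=1.0,
        two_genomes=True,
        b_only_genes_per_chrom=0,
        n_conserved=1,
    )


def generate_worked_toy(out_dir) -> Scenario:
    """The fixed documentation walkthrough bundle (seed is part of the toy)."""
    return generate_scenario(toy_config(), out_dir)
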