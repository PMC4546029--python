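"""End-to-end orchestration: filter → cluster → classify → evidence →
uaRNA → orthology → conservation, each stage writing one flat file.

Outputs carry no timestamps, and every iteration order is fixed, so a rerun
on identical inputs is byte-identical.  Orthology and conservation are
optional stages: when their inputs are absent they are marked ``skipped`` in
the MANIFEST and the rest of the run proceeds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .classify import ClusterClass, classify_all, class_summary
from .config import FilterConfig
from .conservation import class_conservation, genome_windows, mean_score
from .core import GenomicInterval, overlap_len
from .est_preprocess import FilterReport, UESTCluster, cluster_ests, filter_unspliced
from .evidence import (
    TSSPeak,
    ChromatinSegment,
    breadth_histogram,
    chromatin_support,
    orient_all,
    rnaseq_support,
    sense_antisense,
)
from .gene_model import build_components, genes_in_range
from .io_formats import (
    BedRecord,
    read_bed,
    read_bedgraph,
    read_chain,
    read_genepred,
    read_psl,
    write_bed,
)
from .orthology import conservation_summary, pair_orthologs
from .uarna import call_uarnas, intersect_calls

STAGES = (
    "filter", "cluster", "classify", "evidence", "uarna", "orthology",
    "conservation",
)


@dataclass
class GenomeInputs:
    """Input files of one genome; only psl + genepred are mandatory."""

    psl: Path
    genepred: Path
    numts: Path | None = None
    exclude_chroms: tuple[str, ...] = ()
    cage: Path | None = None
    cells_dir: Path | None = None
    chromatin: Path | None = None
    rnaseq: tuple[Path, ...] = ()
    conservation: Path | None = None
    chrom_sizes: Path | None = None


@dataclass
class RunInputs:
    genome_a: GenomeInputs
    genome_b: GenomeInputs | None = None
    chains_ab: Path | None = None
    chains_ba: Path | None = None
    min_mapped_frac: float = 0.95


def _read_chrom_sizes(path) -> dict[str, int]:
    sizes = {}
    with open(path, "rt", encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                chrom, size = line.split("\t")[:2]
                sizes[chrom] = int(size)
    return sizes


def _read_peaks(path) -> list[TSSPeak]:
    return [TSSPeak(interval=r.interval) for r in read_bed(path, min_fields=6)]


def _read_segments(path) -> list[ChromatinSegment]:
    return [
        ChromatinSegment(
            interval=r.interval,
            state=r.name,
            cell_line=r.extra[0] if r.extra else "",
        )
        for r in read_bed(path, min_fields=4)
    ]


def cluster_stage(
    inputs: GenomeInputs, config: FilterConfig
) -> tuple[list[UESTCluster], FilterReport]:
    """Filter + cluster, shared by the main run and the orthology sub-run."""
    alignments = read_psl(inputs.psl)
    numts = read_bed(inputs.numts) if inputs.numts else []
    survivors, report = filter_unspliced(
        alignments, numts, inputs.exclude_chroms, config
    )
    clusters = cluster_ests(survivors, config)
    report.n_clusters = len(clusters)
    return clusters, report


def classify_stage(inputs: GenomeInputs, clusters, config: FilterConfig):
    """Build gene components, map clusters to in-range genes, classify."""
    genes = read_genepred(inputs.genepred)
    sizes = _read_chrom_sizes(inputs.chrom_sizes) if inputs.chrom_sizes else None
    genes = [build_components(g, config, sizes) for g in genes]
    in_range = genes_in_range(clusters, genes, config)
    classes = classify_all(clusters, in_range, config)
    return genes, in_range, classes


def _clusters_to_bed(clusters) -> list[BedRecord]:
    return [
        BedRecord(c.interval, c.cluster_id, str(c.n_members)) for c in clusters
    ]


def _tex_subdivision(clusters, classes, in_range):
    """Split totally-exonic clusters by CDS content (full / partial / none)."""
    out = {"TEX_cds": [], "TEX_partial_cds": [], "TEX_noncoding": []}
    for c in clusters:
        if classes.get(c.cluster_id) is not ClusterClass.TEX:
            continue
        cds_overlap = 0
        for g in in_range.get(c.cluster_id, ()):
            if g.cds is None:
                continue
            lo, hi = g.cds
            for es, ee in g.exons:
                cds_overlap = max(
                    cds_overlap,
                    overlap_len(max(es, lo), min(ee, hi),
                                c.interval.start, c.interval.end)
                    if max(es, lo) < min(ee, hi) else 0,
                )
        # compare against the cluster's own length for the full/none calls
        if cds_overlap == 0:
            out["TEX_noncoding"].append(c.interval)
        elif cds_overlap >= len(c.interval):
            out["TEX_cds"].append(c.interval)
        else:
            out["TEX_partial_cds"].append(c.interval)
    return out


def run_all(
    inputs: RunInputs,
    out_dir,
    config: FilterConfig | None = None,
) -> dict[str, str]:
    """Run every stage, writing flat files plus a MANIFEST; returns the
    stage → status mapping ("completed" / "skipped" / "failed")."""
    config = config or FilterConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    status = {stage: "pending" for stage in STAGES}

    def _write_manifest() -> None:
        with open(out / "MANIFEST", "wt", encoding="utf-8", newline="\n") as fh:
            for stage in STAGES:
                fh.write(f"{stage}\t{status[stage]}\n")
            fh.write("params\t" + ";".join(
                f"{k}={v}" for k, v in sorted(config.to_dict().items())) + "\n")

    ga = inputs.genome_a
    try:
        # -- filter + cluster -------------------------------------------------
        clusters, report = cluster_stage(ga, config)
        pd.DataFrame(report.to_rows(), columns=["stage", "count"]).to_csv(
            out / "funnel.tsv", sep="\t", index=False)
        status["filter"] = "completed"
        write_bed(_clusters_to_bed(clusters), out / "clusters.bed")
        status["cluster"] = "completed"

        # -- classify ---------------------------------------------------------
        genes, in_range, classes = classify_stage(ga, clusters, config)
        rows = [
            (c.cluster_id, str(classes[c.cluster_id]),
             ",".join(g.gene_id for g in in_range.get(c.cluster_id, ())))
            for c in clusters
        ]
        pd.DataFrame(rows, columns=["cluster_id", "class", "genes"]).to_csv(
            out / "classes.tsv", sep="\t", index=False)
        summary = class_summary(classes)
        pd.DataFrame(
            [(str(k), v) for k, v in summary.items()],
            columns=["class", "n_clusters"],
        ).to_csv(out / "class_summary.tsv", sep="\t", index=False)
        status["classify"] = "completed"

        # -- evidence ---------------------------------------------------------
        peaks = _read_peaks(ga.cage) if ga.cage else []
        orientations = orient_all(clusters, peaks, config)
        breadth: dict[str, int] = {}
        if ga.cells_dir:
            per_cell = {
                p.stem: _read_peaks(p)
                for p in sorted(Path(ga.cells_dir).glob("*.bed"))
            }
            breadth, _ = breadth_histogram(clusters, per_cell, config)
        segments = _read_segments(ga.chromatin) if ga.chromatin else []
        chrom_flags = {
            c.cluster_id: chromatin_support(c, segments, config) for c in clusters
        }
        tracks = [read_bedgraph(p) for p in ga.rnaseq]
        supported = (
            rnaseq_support(clusters, tracks, config)
            if tracks else {c.cluster_id: False for c in clusters}
        )
        thr = config.min_component_overlap_nt
        ev_rows = []
        for c in clusters:
            cid = c.cluster_id
            host_strands = {g.strand for g in in_range.get(cid, ())}
            sense = (
                sense_antisense(orientations[cid], next(iter(host_strands)))
                if len(host_strands) == 1 else "NA"
            )
            touches_utr5 = any(
                overlap_len(s, e, c.interval.start, c.interval.end) > thr
                for g in in_range.get(cid, ()) for s, e in g.utr5
            )
            refseq_tss = touches_utr5 or classes[cid] is ClusterClass.UT
            ev_rows.append((
                cid, str(orientations[cid]), breadth.get(cid, 0),
                chrom_flags[cid].has_tss_state, chrom_flags[cid].has_t_state,
                supported[cid], sense, refseq_tss,
            ))
        pd.DataFrame(
            ev_rows,
            columns=["cluster_id", "orientation", "cell_breadth",
                     "has_tss_state", "has_t_state", "rnaseq_supported",
                     "sense_antisense", "refseq_tss"],
        ).to_csv(out / "evidence.tsv", sep="\t", index=False)
        status["evidence"] = "completed"

        # -- uaRNA ------------------------------------------------------------
        cage_calls = (
            call_uarnas(clusters, in_range, "cage", cage_peaks=peaks, config=config)
            if peaks else []
        )
        chromatin_calls = (
            call_uarnas(clusters, in_range, "chromatin",
                        chromatin_segments=segments, config=config)
            if segments else []
        )
        cage_only, chromatin_only, both = intersect_calls(cage_calls, chromatin_calls)
        ua_rows = [
            (call.cluster_id, call.evidence_source,
             ",".join(call.host_gene_ids), str(call.orientation))
            for call in sorted(cage_calls + chromatin_calls,
                               key=lambda u: (u.cluster_id, u.evidence_source))
        ]
        pd.DataFrame(
            ua_rows, columns=["cluster_id", "evidence", "host_genes", "orientation"]
        ).to_csv(out / "uarna.tsv", sep="\t", index=False)
        pd.DataFrame(
            [("cage_only", len(cage_only)), ("chromatin_only", len(chromatin_only)),
             ("both", len(both))],
            columns=["set", "n"],
        ).to_csv(out / "uarna_intersection.tsv", sep="\t", index=False)
        status["uarna"] = "completed"

        # -- orthology (optional) ----------------------------------------------
        gb = inputs.genome_b
        if gb and inputs.chains_ab and inputs.chains_ba:
            clusters_b, _ = cluster_stage(gb, config)
            _, _, classes_b = classify_stage(gb, clusters_b, config)
            pairs = pair_orthologs(
                clusters, clusters_b,
                read_chain(inputs.chains_ab), read_chain(inputs.chains_ba),
                inputs.min_mapped_frac, classes, classes_b,
            )
            pd.DataFrame(
                [(p.cluster_a_id, p.cluster_b_id, p.detected_by, p.same_class)
                 for p in pairs],
                columns=["cluster_a", "cluster_b", "detected_by", "same_class"],
            ).to_csv(out / "ortholog_pairs.tsv", sep="\t", index=False)
            counts = conservation_summary(pairs, clusters, clusters_b)
            pd.DataFrame(sorted(counts.items()), columns=["metric", "n"]).to_csv(
                out / "ortholog_summary.tsv", sep="\t", index=False)
            status["orthology"] = "completed"
        else:
            status["orthology"] = "skipped"

        # -- conservation (optional) --------------------------------------------
        if ga.conservation:
            track = read_bedgraph(ga.conservation)
            per_cluster = [
                (c.cluster_id, *mean_score(c.interval, track)) for c in clusters
            ]
            pd.DataFrame(
                per_cluster, columns=["cluster_id", "mean_score", "scored_bases"]
            ).to_csv(out / "cluster_conservation.tsv", sep="\t", index=False,
                     float_format="%.6f")
            backgrounds = {
                "introns": [GenomicInterval(g.chrom, s, e, ".")
                            for g in genes for s, e in g.introns],
                "exons": [GenomicInterval(g.chrom, s, e, ".")
                          for g in genes for s, e in g.exons],
            }
            hosts = sorted(
                {g.gene_id for gl in in_range.values() for g in gl}
            )
            host_set = set(hosts)
            backgrounds["genes_with_clusters"] = [
                g.interval for g in genes if g.gene_id in host_set
            ]
            if ga.chrom_sizes:
                backgrounds["genome"] = genome_windows(
                    _read_chrom_sizes(ga.chrom_sizes))
            table = class_conservation(
                clusters, classes, track, backgrounds,
                tex_cds=_tex_subdivision(clusters, classes, in_range),
            )
            pd.DataFrame(
                [(k, v) for k, v in table.items()], columns=["set", "mean_score"]
            ).to_csv(out / "class_conservation.tsv", sep="\t", index=False,
                     float_format="%.6f")
            status["conservation"] = "completed"
        else:
            status["conservation"] = "skipped"
    except Exception:
        for stage in STAGES:
            if status[stage] == "pending":
                status[stage] = "failed"
                break
        _write_manifest()
        raise

    _write_manifest()
    return status
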