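# uest — annotation of unspliced EST clusters

A large part of mammalian transcription escapes splicing, and single-pass
cDNA reads (ESTs) that align to the genome without intron-sized gaps are a
rich, under-used record of it. `uest` turns raw EST-to-genome alignments
into an annotated catalogue of *unspliced EST clusters*: candidate
unspliced/intronic transcripts, UTR extensions, promoter- and
terminator-associated RNAs, and novel intergenic loci. It is aimed at
transcriptomics and regulatory-genomics researchers who want this analysis
reproducible on their own alignment sets instead of a chain of one-off
browser operations.

## What the pipeline computes

1. **Filtering** (PSL alignments): drop alignments on excluded haplotype
   chromosomes, alignments whose largest genomic gap exceeds 30 nt
   (spliced), alignments with > 5 % mismatches per aligned base, and
   alignments touching NUMTs (nuclear copies of mitochondrial DNA). The
   funnel counts are reported at every stage.
2. **Clustering**: surviving ESTs that overlap or lie within 30 nt of each
   other merge into clusters; clusters need ≥ 3 member ESTs.
3. **Classification** against gene models (genePred), using component
   overlaps of > 20 nt. Each cluster gets exactly one label:

   | label | meaning |
   |-------|---------|
   | TEX | totally exonic (UTR and non-coding exons included) |
   | TIN | totally intronic |
   | 5PIN / 3PIN | one adjoining exon–intron pair, exon on the 5'/3' side |
   | rI  | one complete intron plus both neighbouring exons (retained intron) |
   | 5R / 3R | exon plus 5-kb upstream/downstream flank (UTR extension) |
   | UT / DT | entirely within the 5-kb upstream/downstream flank |
   | IGR | more than 5 kb from every gene |
   | NO_CLASS | conflicting or unresolvable geometry |

   Conflicts across several in-range genes resolve to NO_CLASS, except that
   one genic class plus UT/DT contacts of neighbouring genes keeps the
   genic class.
4. **Evidence overlays**: transcription direction from stranded CAGE TSS
   peaks in the terminal 84-nt windows (forward / reverse / bidirectional /
   none), expression breadth across per-cell-type peak sets, chromatin-state
   support (promoter "TSS" and transcribed "T" segments, pooled over cell
   lines), and RNA-seq support (≥ 10 reads in at least one library).
5. **uaRNA calling**: clusters overlapping a host gene's 3'UTR (but no
   5'UTR) that carry their own TSS evidence — an independent transcript
   embedded in the UTR.
6. **Orthology**: a from-scratch liftOver over UCSC chain files maps
   clusters between two genomes (≥ 95 % of bases through exactly one
   chain); pairs are the union of both lift directions, flagged for
   same-class conservation.
7. **Conservation**: per-cluster mean of a per-base conservation score
   track (phastCons-style, values in [0, 1]) and per-class mean-of-means
   against intron / exon / genome-window backgrounds.

A fully seeded synthetic-data generator (`uest.synthetic_data`) emulates
every input format with planted ground truth, so the whole system is
testable end to end without downloads.

## Worked example

Generate the small walkthrough bundle (one gene, one cluster of every
class, one uaRNA, one conserved ortholog pair) and run everything:

```bash
uest simulate --toy --out toy/
uest run-all --config run.toml --out out/   # run.toml points at toy/ files
```

`out/class_summary.tsv` — one cluster per class, as planted:

```
class	n_clusters
TEX	1
TIN	1
5PIN	1
3PIN	1
rI	1
5R	1
3R	1
UT	1
DT	1
IGR	1
NO_CLASS	1
```

`out/funnel.tsv` — 53 alignments in, 8 decoys removed (2 per filter), 45
unspliced ESTs forming 11 clusters:

```
stage	count
input	53
removed_haplotype	2
removed_gap	2
removed_mismatch	2
removed_numt	2
unspliced_ests	45
clusters	11
```

`out/uarna.tsv` — the planted 3'UTR-associated RNA, found independently by
CAGE and by chromatin promoter state:

```
cluster_id	evidence	host_genes	orientation
uc000002	cage	gA_chrA1_000	forward
uc000002	chromatin	gA_chrA1_000	none
```

`out/ortholog_pairs.tsv` — the one conserved cluster, detected by both
lift directions and with the same class in both genomes:

```
cluster_a	cluster_b	detected_by	same_class
uc000001	uc000001	both	True
```

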