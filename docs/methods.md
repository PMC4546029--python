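# Methods

## The object of analysis

An *unspliced EST cluster* is a maximal group of ≥ 3 EST-to-genome
alignments, none of which contains an intron-sized gap, that mutually
overlap or lie within 30 nt of one another. Clusters are treated as
unstranded: EST library protocols rarely preserve strand reliably, so
direction is inferred later from independent CAGE evidence rather than from
the alignments. All coordinates are 0-based half-open (BED convention)
throughout; 1-based inputs (wiggle) are converted on read. Chromosome names
are compared by exact string equality — no `chr` aliasing — so naming
mismatches surface as empty results instead of silent misjoins.

## Filtering model

Four successive filters are applied in a fixed order (haplotype → gap →
mismatch → NUMT), and each removed alignment is attributed to the first
filter it fails, which makes the funnel counts additive:

* **Haplotype exclusion.** Alternative haplotype contigs carry duplicates
  of primary-assembly ESTs; matching chromosome names against user glob
  patterns (e.g. `chr6_*hap*`) removes them.
* **Gap filter.** "Unspliced" is operationalized as: the largest single
  target-side (genomic) gap of the alignment is ≤ 30 nt. Introns shorter
  than ~30 nt are essentially unobserved in mammals, so anything larger is
  treated as splicing or an intron-like artifact. The alternative reading —
  the *sum* of gap bases ≤ 30 — is available as `gap_mode="sum"`; the
  per-largest-gap reading is the default because a single large gap is the
  actual splicing signature, while several tiny gaps are alignment noise.
* **Mismatch filter.** Mismatch fraction is computed per aligned base,
  `mismatches / (matches + rep_matches + mismatches)`, the standard PSL
  reading; alignments above 5 % are dropped. Query N bases are not counted.
* **NUMT filter.** Mitochondrial transcripts are unspliced, so an EST
  mapping onto a nuclear copy of mtDNA cannot be told apart from genuine
  nuclear unspliced transcription; any overlap (≥ 1 nt) with a NUMT region
  removes the alignment before clustering.

## Clustering

Joining is a proximity relation (gap ≤ 30 nt, where abutting or overlapping
intervals have gap 0), so connected components coincide with maximal runs
in a per-chromosome sorted sweep — an O(n log n) equivalent of the all-pairs
graph, which the test suite verifies against an explicit all-pairs
connected-components oracle. The boundary is inclusive: end 100 and next
start 130 (gap 30) join; start 131 does not. Cluster hulls are the exact
union of member intervals, ids are assigned in (chromosome, start) order,
and the result is invariant under permutation of the input.

## Classification

Each gene model is decomposed into exons, introns, 5'/3'UTR exonic
segments, and 5-kb upstream/downstream flanks (strand-aware, clipped at
chromosome bounds). A gene is *in range* of a cluster when the cluster
overlaps the gene span or a flank by ≥ 1 nt.

Against one gene, the cluster's class is driven by the set of component
*kinds* it overlaps by **more than 20 nt** — the margin guards against
small errors in annotated component borders. The threshold is applied per
component instance (each exon, each intron, each flank) before instances
collapse into kinds; it is applied uniformly, including to the flank
overlaps behind UT/DT. Consequences worth knowing:

* UTR bases count as exon for TEX ("totally exonic" includes UTR and
  non-coding exons); the UTR sub-labels are consulted only by the 5R/3R
  exclusions and the uaRNA caller.
* A cluster touching two introns of one gene above threshold (crossing the
  intervening exon by ≤ 20 nt) is intron-only → TIN; two instances of a
  kind do not create a new kind.
* 5PIN/3PIN require exactly one exon and one adjoining intron above
  threshold; which side is 5' follows the gene's strand. rI requires one
  intron plus exactly its two neighbouring exons.
* 5R excludes clusters touching the 3'UTR; 3R excludes the 5'UTR and the
  upstream flank (both taken literally from the class definitions).
* A cluster in range of a gene but above no component threshold has no
  applicable rule and is NO_CLASS.

With several genes in range, per-gene classes are computed first and the
distinct set reduced: identical labels pass through; exactly one genic
class (TEX, TIN, 5PIN, 3PIN, rI, 5R, 3R) plus any mixture of UT/DT resolves
to the genic class (otherwise dense regions would be unclassifiable);
everything else — including {UT, DT} and any set containing a per-gene
NO_CLASS — is NO_CLASS. IGR requires zero genes in range. Overlapping
transcript isoforms are kept as independent gene models and handled by this
same reduction; identical duplicated transcripts are not merged.

The classifier is verified against an independent per-base painting oracle
(every base labeled, rule table applied to the painted multiset), including
constructed 20/21-nt boundary cases.

## Evidence

* **Orientation.** A cluster is forward-oriented when a `+`-strand TSS peak
  overlaps its first 84 nt and no `-`-strand peak overlaps its last 84 nt;
  reverse symmetrically; both → bidirectional (reported, excluded from
  orientation-dependent analyses); neither → none. Windows are clipped for
  clusters shorter than 84 nt rather than skipped, so short clusters can
  still be oriented. Peak overlap is ≥ 1 nt by default (`tss_overlap_nt`) —
  the 20-nt margin is a statement about gene-component borders, not about
  peak calls.
* **Cell breadth** counts the cell types whose own peak set yields a
  forward or reverse (not bidirectional) call; it is invariant to cell-type
  order.
* **Chromatin support** pools segments over all cell lines: a flag is set
  when any segment of that state overlaps the cluster in at least one cell
  line, so adding cell lines can only add support. The state vocabulary is
  the fixed seven-label set TSS, PF, E, WE, CTCF, T, R.
* **RNA-seq support** interprets each bedGraph interval value as a read
  count and sums counts over intervals intersecting the cluster *within one
  library*; a cluster is supported at ≥ 10 reads in at least one library.
  Libraries are never pooled. The exact intersect semantics of the original
  browser tooling are not recoverable; the summed-count reading is explicit
  and configurable.

## uaRNA calling

A candidate must (a) overlap the 3'UTR of an in-range gene by > 20 nt,
(b) overlap no in-range gene's 5'UTR by > 20 nt — applied against *all*
in-range genes, the stricter of the two possible readings — and (c) carry
TSS evidence: an orienting CAGE call (forward/reverse via the 84-nt
windows) or ≥ 1 nt overlap with a promoter-state chromatin segment.
5'-side uaRNAs are not called because a TSS inside a 5'UTR cannot be
distinguished from the host gene's own start sites. CAGE-based and
chromatin-based call sets are intersected and reported separately.

## Orthology

`lift_interval` reimplements the core of UCSC liftOver: bases are projected
through a chain's aligned blocks; a chain qualifies when ≥ `min_mapped_frac`
of the interval's bases map through it (default 0.95, liftOver's minMatch
default — the original setting is unstated); zero or multiple qualifying
chains reject the lift, mirroring liftOver's "multiple output regions"
behaviour. Minus-strand targets are converted to forward coordinates before
the hull is taken, so outputs are BED-comparable. Cluster pairs are the
union of the A→B and B→A runs (the two chain sets need not be inverses, so
the directions can genuinely differ), each pair flagged with its detection
direction and whether both clusters share a class. No post-hoc coordinate
correction is applied.

## Conservation

Per-cluster score is the coverage-weighted mean over *scored* bases;
unscored bases are excluded from the denominator rather than imputed as 0
(browser-style averaging; the alternative is a one-line change). Clusters
with no scored base are excluded from class means. Per-class values are
unweighted means over cluster means, and the AVG row is the unweighted mean
over the ten real class means — not the pooled per-cluster mean. The
totally-exonic class can be subdivided by CDS content (fully / partially /
not in CDS), and an external coding-signal hit list can mask intergenic
clusters. Score values outside [0, 1] produce a warning, not an error,
since real tracks contain rounding.

## The synthetic-data generator

The generator lays out "zones" of one six-exon gene each (400-nt exons,
1500-nt introns, 200-nt UTRs, random strand) at a 32-kb pitch, and plants
one cluster per requested class at fixed strand-mirrored offsets chosen so
every deciding overlap clears the 20-nt threshold by ≥ 30 nt, distinct
plants are ≥ 50 nt apart (no accidental joins under the 30-nt rule), and
intergenic plants sit > 10 kb from gene spans. Each plant becomes 3–6
overlapping single- or double-block alignments (internal gaps ≤ 10 nt,
1 % mismatches) whose union is exactly the planted interval. Decoys violate
exactly one filter each: two-block alignments with 100–1000-nt gaps,
8 %-mismatch alignments, clean alignments inside planted NUMTs, and
alignments on a fake haplotype contig — so the funnel equals the decoy
ledger exactly. CAGE peaks, chromatin segments, read-count tracks and a
conservation track (exons elevated +0.30 over a 0.10 background, Gaussian
segment noise σ = 0.005) are emitted per plant according to drawn truth
values. Genome B is genome A pushed through an explicit chain map: 40-nt
indels between zones and one large genome-B-only insertion hosting B-only
genes; the first 100 plants (in genomic order) get exact B images, giving
100 ortholog pairs with identical classes, while B-only plants live in
chain-gap territory and can never pair.

Defaults are the study-scale conditions: 2 chromosomes × 2 Mb per genome,
30 genes per chromosome (60 per genome), 9 gene-relative classes + 1
intergenic plant per zone (600 clusters), 50 oriented uaRNA plants among
the 60 3R plants, 100 conserved pairs, and 200/100/50/30 decoys per filter.
All randomness flows from one `numpy` seeded generator; the same seed gives
byte-identical bundles.

What the generator does *not* emulate: sequence content (only coordinates
and counts matter to the pipeline), overlapping or nested real gene
architectures, ragged exon/intron length distributions, CAGE peak
mis-placement (jitter defaults to 0), EST 5'/3' truncation biases, and
chain rearrangements (inversions, translocations). Passing the recovery
tests therefore demonstrates correctness of the interval logic under
unambiguous geometry, not robustness to messy annotation — the per-base
oracle tests on random (including ambiguous) layouts carry that burden.

## Numerical and engineering choices

* Problem sizes in the test suite: 200 random gene/cluster layouts for the
  classification oracle, 50 layouts up to 5,000 intervals for the
  clustering oracle, > 100 random indel chains for the lifting oracle, and
  one full-scale two-genome scenario for end-to-end recovery; these sizes
  give well over 10⁴ individually checked cases while keeping the suite
  fast to run.
* Writers emit LF line endings and canonical number formatting, and every
  collection is iterated in sorted order, so reruns are byte-identical and
  independent of hash randomization or thread count (`--threads` is
  accepted for interface stability; all stages are single sorted sweeps).
* The worked-toy bundle is fixed (seed 7 is part of its definition) and its
  expected outputs are committed, giving a byte-exact regression anchor.
* Degenerate inputs: empty alignment sets produce zeroed reports; clusters
  shorter than the CAGE window use clipped windows; genes with abutting
  exons produce no zero-length introns and keep exon–intron adjacency
  indexing correct; zero scored conservation bases give NaN, never 0.

## Known limitations

* Classification is transcript-based, not locus-based; heavily overlapping
  isoform annotations inflate NO_CLASS via genuine per-isoform conflicts.
* The lift step handles colinear chains only (as chain files encode);
  paralogous multi-chain hits are rejected rather than scored.
* bigWig/bigBed are out of scope; inputs arrive as text (bedGraph, wiggle,
  BED, PSL, genePred, chain).
* Retrogene masks, structured-RNA and coding-signal hit lists are consumed
  as external inputs when provided, never computed.
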