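# Methods

## Mapping model

`seedsplice` treats a single-end read as a sequence over {A,C,G,T,N} with
optional Phred qualities and aligns it under an edit-distance budget `E`:
mismatches, inserted bases and deleted bases each count one. This per-base
edit semantics (rather than counting an indel run as one event) is chosen
because the target platforms are indel-dominated, so the budget must bound
the total number of corrupted positions the aligner may absorb.

The pipeline is staged. A read is consumed by the first stage that places
it: (1) contiguous alignment to annotated mRNA sequences, projected to the
genome through the exon table (annotated introns crossed by the alignment
become `N` gaps, and placements that project to identical genomic blocks
via different isoforms count as one locus); (2) contiguous alignment to the
genome; (3) de novo spliced alignment. A read that aligns equally well at
two distinct loci at any stage is non-unique: it is retained in the tallies
but contributes neither junctions nor counts.

### Seeding and verification

Reads are split into consecutive non-overlapping seeds of length `S`
(default 14 nt); when the length is not a multiple of `S` one extra seed
covering the final `S` bases is appended, so seeds always cover the whole
read. Seeds are looked up exactly in a hash index of the forward reference
strand; the reverse strand is searched by querying the reverse-complemented
read. k-mers containing N are never indexed or queried, and k-mers
occurring more than `occurrence_cap` (default 1000) times are ignored as
repeats. Each candidate diagonal voted for by a seed hit is verified once
by banded alignment of the full read (edlib) inside a window of ±`E` around
the diagonal; verified placements closer than `E` on one sequence collapse
to their best representative before uniqueness is judged.

### De novo spliced stage

Seed matches sharing (contig, strand, diagonal) merge into hotspots when
their read offsets are within `2·S` of each other — one sequencing error
destroys at most one seed, and this slack bridges a single destroyed seed
without joining unrelated matches. Hotspot pairs in read order whose
diagonal difference (the implied intron length) lies in `[N, X]`
(defaults 50 and 500 000 nt) are scored by the summed seed counts of the
two hotspots and examined in descending score order, ties going to the
shorter genomic gap.

For one pair with left diagonal `d_L` and right diagonal `d_R`, the left
exon block is anchored to start at `d_L` and the right block to end at
`d_R + |read|`. Two dynamic-programming matrices are filled: prefix edit
distances of every read prefix against the reference downstream of `d_L`,
and suffix edit distances of every read suffix against the reference
upstream of `d_R + |read|`. Rows are vectorised with the prefix-minimum
identity `D[i,j] = min_k≤j (V[k] + j − k)`, making the fill O(read ×
window) with numpy row operations. Every breakpoint `b` (read coordinate,
at least `min_anchor` = `S` bases from each read end) combined with up to
`E` nt of slack on each induced intron end is scored as prefix cost +
suffix cost. The minimal-cost placement wins; among equal costs the intron
whose terminal dinucleotides form a canonical splice signal is preferred
(GT-AG, then GC-AG, then AT-AC, then non-canonical, checking both genomic
strands), and remaining ties resolve to the smallest donor coordinate.
Placements are rejected when the cost exceeds `E`, the intron leaves
`[N, X]`, either block would be shorter than `min_anchor`, or
(`--canonical-only`) the motif is non-canonical. Exactly one intron per
read is modelled; reads needing two junctions stay unmapped — a deliberate
scope limit matching the hotspot-pair design.

All candidate pairs are resolved so that a second distinct placement with
an equally good error count marks the read non-unique. The reported
junction strand follows the motif; non-canonical junctions inherit the
mapping orientation.

## Junction calling and quantification

Junctions are keyed by (contig, strand, intron) with support = number of
distinct uniquely mapped reads spanning the intron, pooling transcriptome-
projected and de novo evidence. Classification: `known` if the intron is
annotated; `novel_I` if it overlaps any annotated gene's genomic span
(union of the gene's transcript spans, introns included, strand-agnostic —
the annotation's strandedness is often unreliable for this purpose);
`novel_II` otherwise. `flag_known_equivalents` additionally marks
novel-labelled junctions whose coordinates match an annotated intron of
another transcript within a configurable tolerance.

For quantification, a gene model is the union of its transcripts' exons
("splice variants merged"); a unique read is assigned to a gene when its
aligned blocks overlap the union, dropped when it overlaps two genes'
unions. rpkM uses the union length in kb and the number of uniquely mapped
reads as the per-million denominator (mapped-only is a documented choice;
the alternative — all input reads — only rescales every gene equally).
A gene with ≥ 10 assigned reads is "quantified"; summary statistics
(mean/median rpkM), the GC-vs-expression table (5% GC bins over the exon
union, genes with rpkM > 1) and the 3′-coverage profile (read starts
projected to relative position on the gene's longest transcript, 100 bins,
profiles normalised to mean 1, genes stratified by mRNA length) are
reporting utilities over the quantified set.

## Synthetic data

The simulator emulates the regime the mapper targets, not any particular
dataset: a random genome with `n_genes` multi-exon genes (defaults: 3–6
exons of 100–300 nt, introns 60–2000 nt — inside the mapper's `[N, X]` —
random strand, GT-AG intron ends on the transcribed strand with
configurable GC-AG/AT-AC/non-canonical fractions); log-normal per-gene
expression; sense-strand fragments with log-normal lengths (mean 87 nt,
sigma 0.25, clipped to 30–250 nt); substitution errors at 1% and
insertion/deletion errors at 0.75% each by default, i.e. indel-heavy, with
indel positions drawn proportionally to homopolymer run length and
insertions duplicating the local base, as on semiconductor sequencers.
A 5% fraction of reads receives a few Phred-8 bases within the first 42 nt
to exercise the filter. Every read carries a truth record (transcript,
genomic blocks, spanned junctions with flank lengths, error counts), and
the whole generator is deterministic under a fixed seed.

What the simulator does not model: amplification and coverage bias along
transcripts, quality-score correlation with true error positions,
flow-space signal artefacts, overlapping genes and antisense
transcription, and alternative isoforms (one transcript per gene by
default). Passing tests therefore demonstrate algorithmic correctness and
parameter recovery under controlled noise, not performance on any real
library.

## Scoring definitions used in tests

Junction recall/precision are evaluated on junctions with ≥ 5 supporting
reads, where a truth junction's support counts filtered-in reads spanning
it with both flanks ≥ `min_anchor` (14 nt): a junction read with a
shorter flank carries no seed on that side and is unrecoverable by a
seed-anchored method, so it is not evidence the mapper could have used.
The spliced-resolution oracle (exhaustive breakpoint/slack enumeration
with independent edit-distance calls) is compared on error count for every
read and on the exact site whenever the optimum is unique; under exact
cost-and-motif ties any optimum is an acceptable answer and only the
deterministic tie-break distinguishes them. Test problem sizes (20 kb
oracle genome, 100-gene/12 000-read recovery surface, 500-read oracle
samples) keep the full suite in the minutes range while leaving every
statistic estimated from hundreds of events.

## Numerical and degenerate-input choices

* Uniqueness margin: a second locus within `score_margin` (default 0)
  errors of the best voids uniqueness; ties at one locus collapse first.
* All coordinates are 0-based half-open internally; GTF and SAM conversion
  happens only in the I/O layer. Junction coordinates denote the intron
  (first and one-past-last intronic base).
* Reads shorter than `S` cannot be seeded and are unmappable; all-N reads
  produce no hotspots; empty inputs yield empty outputs and zeroed
  reports.
* Output order is deterministic everywhere (input read order in SAM,
  coordinate order in the junction table, gene id in the quant table), so
  identical inputs reproduce byte-identical outputs.

## Known limitations

Single-intron reads only; no inter-contig (fusion) junctions; no
mapping-quality calibration beyond unique/non-unique (MAPQ 60/0); the
transcriptome pass trusts the annotation's exon structure; rpkM inherits
the usual length biases of per-kilobase measures on short genes.
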