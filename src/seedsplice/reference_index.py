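"""Exact-match seed index and transcriptome construction / projection.

The index maps every k-mer of the forward reference strand to its
occurrence list; reverse-strand hits are found by querying the
reverse-complemented read, so the reference is indexed once.  k-mers
containing N are skipped (exact matching is undefined for them).

The transcriptome holds each transcript's spliced (mature mRNA, 5'->3')
sequence together with an exon block table, so that an alignment interval
on a transcript can be projected to genomic blocks and the annotated
introns it crosses.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field

from seedsplice._dna import revcomp
from seedsplice.formats_io import Genome, Transcript


@dataclass
class SeedIndex:
    """k-mer -> list of (sequence name, 0-based offset) on the forward strand."""

    k: int
    table: dict[str, list[tuple[str, int]]]

    def lookup(self, kmer: str) -> list[tuple[str, int]]:
        if "N" in kmer:
            return []
        return self.table.get(kmer, [])

    def occurrence_count(self, kmer: str) -> int:
        return len(self.table.get(kmer, ()))


def build_seed_index(sequences: dict[str, str], k: int) -> SeedIndex:
    """Index every k-mer of every sequence; k must be >= 8.

    Raises if no sequence is at least k long (nothing could ever match).
    """
    if k < 8:
        raise ValueError("seed length must be >= 8")
    if all(len(s) < k for s in sequences.values()):
        raise ValueError(f"no reference sequence is >= {k} nt; cannot build index")
    table: dict[str, list[tuple[str, int]]] = {}
    for name, seq in sequences.items():
        seq = seq.upper()
        for pos in range(len(seq) - k + 1):
            kmer = seq[pos : pos + k]
            if "N" in kmer:
                continue
            table.setdefault(kmer, []).append((name, pos))
    return SeedIndex(k=k, table=table)


@dataclass
class TranscriptomeRef:
    """Spliced transcript sequences plus the transcript<->genome projector."""

    sequences: dict[str, str]
    transcripts: dict[str, Transcript]
    junction_set: set[tuple[str, int, int]]
    junction_strand: dict[tuple[str, int, int], str] = field(default_factory=dict)

    def gene_of(self, transcript_id: str) -> str:
        return self.transcripts[transcript_id].gene_id

    # -- projection ---------------------------------------------------------

    def project_to_genome(
        self, transcript_id: str, t_start: int, t_end: int
    ) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
        """Map a transcript interval to (genomic blocks, crossed introns).

        Coordinates are 0-based half-open on both sides.  Blocks are maximal
        and ascending; each adjacent block pair brackets the annotated
        intron listed between them.  For minus-strand transcripts the mRNA
        interval is flipped onto the plus-strand exon concatenation first.
        """
        tx = self.transcripts[transcript_id]
        total = tx.spliced_length
        if not (0 <= t_start < t_end <= total):
            raise ValueError(
                f"interval ({t_start},{t_end}) outside transcript "
                f"{transcript_id} of spliced length {total}"
            )
        if tx.strand == "-":
            t_start, t_end = total - t_end, total - t_start
        blocks: list[tuple[int, int]] = []
        offset = 0  # transcript offset (plus-strand concatenation) of exon start
        for start, end in tx.exons:
            exon_len = end - start
            lo = max(t_start, offset)
            hi = min(t_end, offset + exon_len)
            if lo < hi:
                blocks.append((start + lo - offset, start + hi - offset))
            offset += exon_len
        introns = [(a_end, b_start) for (_, a_end), (b_start, _) in zip(blocks, blocks[1:])]
        return blocks, introns

    def project_to_transcript(
        self, transcript_id: str, blocks: list[tuple[int, int]]
    ) -> tuple[int, int]:
        """Inverse of :meth:`project_to_genome` for blocks lying on exons."""
        tx = self.transcripts[transcript_id]
        starts = [s for s, _ in tx.exons]
        offsets = []
        offset = 0
        for s, e in tx.exons:
            offsets.append(offset)
            offset += e - s
        total = offset

        def to_concat(g: int, right_edge: bool) -> int:
            i = bisect.bisect_right(starts, g) - 1
            if right_edge and i >= 0 and tx.exons[i][0] == g and i > 0:
                # a block end equal to an exon start belongs to the previous exon
                i -= 1
            s, e = tx.exons[i]
            if not (s <= g <= e):
                raise ValueError(f"coordinate {g} not on exons of {transcript_id}")
            return offsets[i] + g - s

        c_start = to_concat(blocks[0][0], right_edge=False)
        c_end = to_concat(blocks[-1][1], right_edge=True)
        if tx.strand == "-":
            c_start, c_end = total - c_end, total - c_start
        return c_start, c_end


def build_transcriptome(genome: Genome, transcripts: list[Transcript]) -> TranscriptomeRef:
    """Assemble spliced sequences and the annotated intron set.

    Minus-strand sequences are reverse-complemented so every stored
    sequence reads 5'->3' along the mature mRNA.
    """
    sequences: dict[str, str] = {}
    tx_map: dict[str, Transcript] = {}
    junction_set: set[tuple[str, int, int]] = set()
    junction_strand: dict[tuple[str, int, int], str] = {}
    for tx in transcripts:
        if tx.contig not in genome:
            raise ValueError(f"{tx.transcript_id}: unknown contig {tx.contig!r}")
        contig_seq = genome[tx.contig]
        for start, end in tx.exons:
            if not (0 <= start < end <= len(contig_seq)):
                raise ValueError(
                    f"{tx.transcript_id}: exon ({start},{end}) outside contig "
                    f"{tx.contig} of length {len(contig_seq)}"
                )
        concat = "".join(contig_seq[s:e] for s, e in tx.exons)
        sequences[tx.transcript_id] = revcomp(concat) if tx.strand == "-" else concat
        tx_map[tx.transcript_id] = tx
        for intron in tx.introns:
            key = (tx.contig, intron[0], intron[1])
            junction_set.add(key)
            junction_strand[key] = tx.strand
    return TranscriptomeRef(sequences, tx_map, junction_set, junction_strand)
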