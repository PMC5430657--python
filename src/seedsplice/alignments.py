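"""Alignment records shared by the unspliced and spliced mapping stages.

CIGAR strings use M/I/D/N ops over the forward reference strand; for
reverse-strand alignments the query implied by the CIGAR is the
reverse-complemented read, per SAM convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from seedsplice.formats_io import Read

#: motif class rank used when breaking ties between equal-error breakpoints
MOTIF_RANK = {"GT-AG": 0, "GC-AG": 1, "AT-AC": 2, "noncanonical": 3}

#: (donor dinucleotide, acceptor dinucleotide) on the forward genome ->
#: (motif class, transcribed strand).  A GT-AG intron transcribed from the
#: minus strand shows CT..AC on the forward reference.
_MOTIF_TABLE = {
    ("GT", "AG"): ("GT-AG", "+"),
    ("GC", "AG"): ("GC-AG", "+"),
    ("AT", "AC"): ("AT-AC", "+"),
    ("CT", "AC"): ("GT-AG", "-"),
    ("CT", "GC"): ("GC-AG", "-"),
    ("GT", "AT"): ("AT-AC", "-"),
}


def classify_intron_motif(contig_seq: str, start: int, end: int) -> tuple[str, str | None]:
    """Motif class and transcribed strand of the intron [start, end).

    Returns ``("noncanonical", None)`` when neither strand shows a known
    splice signal.
    """
    donor = contig_seq[start : start + 2]
    acceptor = contig_seq[end - 2 : end]
    return _MOTIF_TABLE.get((donor, acceptor), ("noncanonical", None))


@dataclass
class UnsplicedAlignment:
    """A contiguous (single-block) alignment of a full read."""

    read: Read
    contig: str
    strand: str
    ref_start: int
    cigar: str
    n_errors: int
    unique: bool = True
    source: str = "genome"  # "transcriptome" when found via an annotated mRNA

    @property
    def read_id(self) -> str:
        return self.read.read_id

    @property
    def blocks(self) -> tuple[tuple[int, int], ...]:
        from seedsplice.formats_io import cigar_ref_span

        return ((self.ref_start, self.ref_start + cigar_ref_span(self.cigar)),)

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        return ()


@dataclass
class SplicedAlignment:
    """An alignment whose CIGAR contains one or more intron (N) gaps.

    ``strand`` is the mapping orientation and drives the SAM FLAG;
    ``junction_strand`` is the transcribed strand the introns are reported
    on (from the splice motif for de novo junctions, from the annotation
    for transcriptome-projected ones).
    """

    read: Read
    contig: str
    strand: str
    blocks: tuple[tuple[int, int], ...]
    cigar: str
    n_errors: int
    motif_class: str = "noncanonical"
    junction_strand: str = "+"
    unique: bool = True
    source: str = "spliced"  # "transcriptome" for projected known junctions

    @property
    def read_id(self) -> str:
        return self.read.read_id

    @property
    def ref_start(self) -> int:
        return self.blocks[0][0]

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        return tuple(
            (a_end, b_start)
            for (_, a_end), (b_start, _) in zip(self.blocks, self.blocks[1:])
        )

    @property
    def intron(self) -> tuple[int, int]:
        return self.introns[0]
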