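"""Standard-format I/O: FASTA, FASTQ (Phred+33), GTF exons, SAM, junction TSV.

All internal coordinates are 0-based half-open.  Conversion to the 1-based
conventions of GTF and SAM happens here and only here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import pysam
from Bio import SeqIO
from gffutils.feature import feature_from_line

from seedsplice._dna import revcomp


@dataclass
class Read:
    """A single-end sequencing read with optional per-base Phred qualities."""

    read_id: str
    sequence: str
    qualities: list[int] | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"read {self.read_id!r}: empty sequence")
        self.sequence = self.sequence.upper()
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise ValueError(
                f"read {self.read_id!r}: {len(self.qualities)} quality values "
                f"for {len(self.sequence)} bases"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class Genome:
    """Reference sequences; an ordered map of contig name -> uppercase DNA."""

    contigs: dict[str, str]

    def __post_init__(self) -> None:
        self.contigs = {name: seq.upper() for name, seq in self.contigs.items()}

    def __getitem__(self, name: str) -> str:
        return self.contigs[name]

    def __contains__(self, name: str) -> bool:
        return name in self.contigs

    def __iter__(self) -> Iterator[str]:
        return iter(self.contigs)


@dataclass
class Transcript:
    """One transcript: exons in genomic 0-based half-open coordinates.

    Exons are stored sorted ascending by genomic start regardless of strand;
    the mRNA orientation is recovered from ``strand`` when the spliced
    sequence is built.
    """

    gene_id: str
    transcript_id: str
    contig: str
    strand: str
    exons: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.transcript_id}: strand must be + or -")
        self.exons = sorted(tuple(e) for e in self.exons)
        for start, end in self.exons:
            if end <= start:
                raise ValueError(f"{self.transcript_id}: empty exon ({start},{end})")
        for (_, e0), (s1, _) in zip(self.exons, self.exons[1:]):
            if s1 < e0:
                raise ValueError(f"{self.transcript_id}: overlapping exons")

    @property
    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [(e0, s1) for (_, e0), (s1, _) in zip(self.exons, self.exons[1:])]


# ---------------------------------------------------------------------------
# readers


def read_fasta(path) -> Genome:
    """Load a FASTA file into a :class:`Genome`; sequences are uppercased."""
    contigs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in contigs:
            raise ValueError(f"duplicate contig name {rec.id!r} in {path}")
        contigs[rec.id] = str(rec.seq).upper()
    if not contigs:
        raise ValueError(f"no FASTA records in {path}")
    return Genome(contigs)


def read_fastq(path) -> Iterator[Read]:
    """Stream Phred+33 FASTQ records as :class:`Read` objects."""
    for rec in SeqIO.parse(str(path), "fastq"):
        quals = rec.letter_annotations["phred_quality"]
        yield Read(rec.id, str(rec.seq), list(quals))


def read_fasta_reads(path) -> Iterator[Read]:
    """Read FASTA as reads; qualities absent (treated as perfect downstream)."""
    for rec in SeqIO.parse(str(path), "fasta"):
        yield Read(rec.id, str(rec.seq), None)


def read_gtf(path) -> list[Transcript]:
    """Parse exon features of a GTF file into :class:`Transcript` objects.

    GTF coordinates (1-based inclusive) are converted to 0-based half-open.
    Only ``exon`` features are consumed; each must carry ``gene_id`` and
    ``transcript_id`` attributes.
    """
    by_tx: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            feat = feature_from_line(line, dialect=None)
            if feat.featuretype != "exon":
                continue
            try:
                tx_id = feat.attributes["transcript_id"][0]
            except KeyError:
                raise ValueError(f"{path}:{lineno}: exon without transcript_id")
            try:
                gene_id = feat.attributes["gene_id"][0]
            except KeyError:
                raise ValueError(f"{path}:{lineno}: exon without gene_id")
            entry = by_tx.setdefault(
                tx_id,
                {"gene_id": gene_id, "contig": feat.seqid, "strand": feat.strand, "exons": []},
            )
            entry["exons"].append((feat.start - 1, feat.end))
            if tx_id not in order:
                order.append(tx_id)
    transcripts = []
    for tx_id in order:
        e = by_tx[tx_id]
        transcripts.append(
            Transcript(e["gene_id"], tx_id, e["contig"], e["strand"], e["exons"])
        )
    return transcripts


# ---------------------------------------------------------------------------
# writers


def write_fastq(reads: Iterable[Read], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            quals = r.qualities if r.qualities is not None else [40] * len(r)
            qline = "".join(chr(q + 33) for q in quals)
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{qline}\n")


def write_gtf(transcripts: Sequence[Transcript], path, source: str = "seedsplice") -> None:
    """Write exon features back out as GTF (1-based inclusive)."""
    with open(path, "w") as fh:
        for tx in transcripts:
            for start, end in tx.exons:
                attrs = f'gene_id "{tx.gene_id}"; transcript_id "{tx.transcript_id}";'
                fh.write(
                    f"{tx.contig}\t{source}\texon\t{start + 1}\t{end}\t.\t"
                    f"{tx.strand}\t.\t{attrs}\n"
                )


def cigar_read_length(cigar: str) -> int:
    """Read bases consumed by a CIGAR (sum of M/I/S/=/X lengths)."""
    return sum(n for n, op in _iter_cigar(cigar) if op in "MIS=X")


def cigar_ref_span(cigar: str) -> int:
    """Reference bases consumed by a CIGAR (sum of M/D/N/=/X lengths)."""
    return sum(n for n, op in _iter_cigar(cigar) if op in "MDN=X")


def _iter_cigar(cigar: str):
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            yield int(num), ch
            num = ""


def write_sam(alignments: Iterable, genome: Genome, path) -> None:
    """Write alignments as SAM 1.x with M/I/D/N CIGAR ops.

    Each alignment must expose ``read`` (a :class:`Read`), ``contig``,
    ``strand``, ``ref_start`` (0-based), ``cigar``, ``n_errors`` and
    ``unique``.  Reverse-strand alignments are written with FLAG 16 and the
    reverse-complemented sequence, per SAM convention.
    """
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": name, "LN": len(seq)} for name, seq in genome.contigs.items()],
    }
    names = list(genome.contigs)
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for aln in alignments:
            if aln.contig not in genome:
                raise ValueError(f"alignment references unknown contig {aln.contig!r}")
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = aln.read.read_id
            seg.reference_id = names.index(aln.contig)
            seg.reference_start = aln.ref_start
            seg.cigarstring = aln.cigar
            seg.mapping_quality = 60 if aln.unique else 0
            if aln.strand == "-":
                seg.flag = 16
                seg.query_sequence = revcomp(aln.read.sequence)
                quals = aln.read.qualities
                seg.query_qualities = quals[::-1] if quals is not None else None
            else:
                seg.flag = 0
                seg.query_sequence = aln.read.sequence
                seg.query_qualities = aln.read.qualities
            seg.set_tag("NM", int(aln.n_errors))
            out.write(seg)


JUNCTION_COLUMNS = [
    "contig",
    "intron_start",
    "intron_end",
    "strand",
    "motif_class",
    "support_count",
    "annotation_class",
]


def write_junction_table(junctions: Iterable, path) -> None:
    """Write junction calls as a TSV (intron coordinates, 0-based half-open)."""
    with open(path, "w") as fh:
        fh.write("\t".join(JUNCTION_COLUMNS) + "\n")
        for j in junctions:
            fh.write(
                f"{j.contig}\t{j.intron[0]}\t{j.intron[1]}\t{j.strand}\t"
                f"{j.motif_class}\t{j.support}\t{j.annotation_class}\n"
            )
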