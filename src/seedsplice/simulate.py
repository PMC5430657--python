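"""Truth-tracked synthetic data: genome, annotation and error-prone reads.

The generator emulates the input regime the mapper is designed for: a
small multi-gene genome with multi-exon transcripts, and single-end reads
of variable length (log-normal, mean ~87 nt) carrying both substitution
and indel errors, with indels preferentially placed in homopolymer runs
as on semiconductor sequencers.  Every read comes with a truth record
(origin, spanned junctions with flank lengths, injected errors) so
mapping and junction calls can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from seedsplice._dna import revcomp
from seedsplice.formats_io import Genome, Read, Transcript
from seedsplice.reference_index import build_transcriptome

_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Study conditions for the synthetic genome and read set.

    Error-rate defaults are indel-heavy (insertions + deletions above the
    substitution rate), matching the error profile of semiconductor
    single-end sequencing; all rates are per base.
    """

    seed: int = 0
    # genome / annotation
    n_genes: int = 20
    exons_per_gene: tuple[int, int] = (3, 6)
    exon_length: tuple[int, int] = (100, 300)
    intron_length: tuple[int, int] = (60, 2000)
    intergenic_length: tuple[int, int] = (200, 800)
    gc_ag_fraction: float = 0.0
    at_ac_fraction: float = 0.0
    noncanonical_fraction: float = 0.0
    contig_name: str = "chr1"
    # reads
    n_reads: int = 2000
    read_length_mean: float = 87.0
    read_length_sigma: float = 0.25
    read_length_min: int = 30
    read_length_max: int = 250
    substitution_rate: float = 0.01
    insertion_rate: float = 0.0075
    deletion_rate: float = 0.0075
    homopolymer_bias: bool = True
    expression_sigma: float = 1.0
    base_quality: int = 30
    low_quality_read_fraction: float = 0.05
    low_quality_value: int = 8

    def __post_init__(self) -> None:
        for rate in (self.substitution_rate, self.insertion_rate, self.deletion_rate):
            if not 0 <= rate < 1:
                raise ValueError("error rates must be in [0, 1)")
        if self.exon_length[0] > self.exon_length[1] or self.exon_length[0] < 1:
            raise ValueError("infeasible exon length range")
        if self.intron_length[0] > self.intron_length[1] or self.intron_length[0] < 1:
            raise ValueError("infeasible intron length range")


@dataclass
class TruthRecord:
    """Exact provenance of one simulated read."""

    read_id: str
    gene_id: str
    transcript_id: str
    contig: str
    strand: str
    blocks: tuple[tuple[int, int], ...]  # genomic blocks of the error-free fragment
    junctions: tuple[tuple[int, int, int, int], ...]  # (start, end, flank5, flank3)
    n_sub: int
    n_ins: int
    n_del: int


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, n)])


def simulate_genome(config: SimConfig, rng: np.random.Generator | None = None):
    """Random genome with embedded multi-exon genes; returns (Genome, transcripts).

    Annotated introns carry GT..AG ends on the transcribed strand by
    default; configured fractions replace the signal with GC-AG, AT-AC or
    a non-canonical dinucleotide pair, in that order of assignment.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    chunks: list[str] = []
    pos = 0
    transcripts: list[Transcript] = []
    for g in range(config.n_genes):
        gap = int(rng.integers(*config.intergenic_length))
        chunks.append(_random_seq(rng, gap))
        pos += gap
        n_exons = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        exons: list[tuple[int, int]] = []
        for e in range(n_exons):
            if e > 0:
                ilen = int(rng.integers(config.intron_length[0], config.intron_length[1] + 1))
                intron_seq = list(_random_seq(rng, ilen))
                u = rng.random()
                if u < config.noncanonical_fraction:
                    d5, d3 = "CC", "GG"
                elif u < config.noncanonical_fraction + config.at_ac_fraction:
                    d5, d3 = "AT", "AC"
                elif (
                    u
                    < config.noncanonical_fraction
                    + config.at_ac_fraction
                    + config.gc_ag_fraction
                ):
                    d5, d3 = "GC", "AG"
                else:
                    d5, d3 = "GT", "AG"
                if strand == "-":
                    # transcribed right-to-left: 5' signal at the right end
                    d5, d3 = revcomp(d5), revcomp(d3)
                    d5, d3 = d3, d5
                intron_seq[0:2] = list(d5)
                intron_seq[-2:] = list(d3)
                chunks.append("".join(intron_seq))
                pos += ilen
            elen = int(rng.integers(config.exon_length[0], config.exon_length[1] + 1))
            chunks.append(_random_seq(rng, elen))
            exons.append((pos, pos + elen))
            pos += elen
        gene_id = f"gene{g + 1:04d}"
        transcripts.append(
            Transcript(gene_id, f"{gene_id}.t1", config.contig_name, strand, exons)
        )
    tail = int(rng.integers(*config.intergenic_length))
    chunks.append(_random_seq(rng, tail))
    genome = Genome({config.contig_name: "".join(chunks)})
    return genome, transcripts


def _weighted_positions(
    rng: np.random.Generator, seq: str, n: int, homopolymer_bias: bool
) -> np.ndarray:
    """Draw n distinct positions; with bias, weight by homopolymer run length."""
    L = len(seq)
    if n == 0 or L == 0:
        return np.empty(0, dtype=int)
    n = min(n, L)
    if not homopolymer_bias:
        return rng.choice(L, size=n, replace=False)
    runs = np.empty(L, dtype=float)
    i = 0
    while i < L:
        j = i
        while j < L and seq[j] == seq[i]:
            j += 1
        runs[i:j] = j - i
        i = j
    w = runs / runs.sum()
    return rng.choice(L, size=n, replace=False, p=w)


def _inject_errors(
    rng: np.random.Generator, fragment: str, config: SimConfig
) -> tuple[str, int, int, int]:
    """Apply substitutions, then deletions, then insertions; returns counts."""
    seq = list(fragment)
    n_sub = int(rng.binomial(len(seq), config.substitution_rate))
    for p in rng.choice(len(seq), size=min(n_sub, len(seq)), replace=False):
        alternatives = [b for b in "ACGT" if b != seq[p]]
        seq[p] = alternatives[int(rng.integers(0, 3))]
    s = "".join(seq)

    n_del = int(rng.binomial(len(s), config.deletion_rate))
    del_pos = _weighted_positions(rng, s, n_del, config.homopolymer_bias)
    for p in sorted(del_pos, reverse=True):
        s = s[:p] + s[p + 1 :]
    n_del_applied = len(del_pos)

    n_ins = int(rng.binomial(len(s), config.insertion_rate)) if s else 0
    for p in sorted(
        _weighted_positions(rng, s, n_ins, config.homopolymer_bias), reverse=True
    ):
        # homopolymer-style: duplicate the base at the chosen position
        s = s[: p + 1] + s[p] + s[p + 1 :]
    return s, n_sub, n_ins, n_del_applied


def simulate_reads(
    genome: Genome,
    transcripts: list[Transcript],
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[Read], list[TruthRecord]]:
    """Sample error-prone single-end reads from spliced transcripts.

    Fragments are drawn from mRNA sequences with per-gene log-normal
    expression weights and log-normal lengths; errors are injected at the
    configured rates.  A small fraction of reads receives low-quality 5'
    bases to exercise the quality filter.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    ref = build_transcriptome(genome, transcripts)
    by_gene: dict[str, list[Transcript]] = {}
    for tx in transcripts:
        by_gene.setdefault(tx.gene_id, []).append(tx)
    genes = sorted(by_gene)
    weights = rng.lognormal(0.0, config.expression_sigma, len(genes))
    weights /= weights.sum()

    reads: list[Read] = []
    truths: list[TruthRecord] = []
    for i in range(config.n_reads):
        gene = genes[int(rng.choice(len(genes), p=weights))]
        tx = by_gene[gene][int(rng.integers(0, len(by_gene[gene])))]
        mrna = ref.sequences[tx.transcript_id]
        total = len(mrna)
        mu = np.log(config.read_length_mean) - config.read_length_sigma**2 / 2
        length = int(round(rng.lognormal(mu, config.read_length_sigma)))
        length = max(config.read_length_min, min(length, config.read_length_max, total))
        start = int(rng.integers(0, total - length + 1))
        fragment = mrna[start : start + length]

        blocks, introns = ref.project_to_genome(tx.transcript_id, start, start + length)
        junctions = []
        for intron in introns:
            # flank lengths in mRNA orientation
            left_gb = sum(e - s for s, e in blocks if e <= intron[0])
            flank_a, flank_b = left_gb, length - left_gb
            if tx.strand == "-":
                flank_a, flank_b = flank_b, flank_a
            junctions.append((intron[0], intron[1], flank_a, flank_b))

        seq, n_sub, n_ins, n_del = _inject_errors(rng, fragment, config)
        quals = [config.base_quality] * len(seq)
        if rng.random() < config.low_quality_read_fraction and len(seq) > 4:
            k = int(rng.integers(1, 4))
            for p in rng.choice(min(42, len(seq)), size=k, replace=False):
                quals[p] = config.low_quality_value
        read_id = f"r{i:06d}"
        reads.append(Read(read_id, seq, quals))
        truths.append(
            TruthRecord(
                read_id=read_id,
                gene_id=gene,
                transcript_id=tx.transcript_id,
                contig=tx.contig,
                strand=tx.strand,
                blocks=tuple(blocks),
                junctions=tuple(junctions),
                n_sub=n_sub,
                n_ins=n_ins,
                n_del=n_del,
            )
        )
    return reads, truths


def write_truth_table(truths: list[TruthRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "read_id\tgene_id\ttranscript_id\tcontig\tstrand\tblocks\t"
            "junctions\tn_sub\tn_ins\tn_del\n"
        )
        for t in truths:
            blocks = ",".join(f"{s}-{e}" for s, e in t.blocks)
            juncs = ",".join(f"{s}-{e}:{f5}/{f3}" for s, e, f5, f3 in t.junctions)
            fh.write(
                f"{t.read_id}\t{t.gene_id}\t{t.transcript_id}\t{t.contig}\t"
                f"{t.strand}\t{blocks}\t{juncs}\t{t.n_sub}\t{t.n_ins}\t{t.n_del}\n"
            )
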