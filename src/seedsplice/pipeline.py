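"""End-to-end orchestration: filter -> map (transcriptome, genome, spliced)
-> junction calling -> quantification.

With an annotation, reads are mapped to the transcriptome first (known
junctions fall out of the exon projection), remaining reads to the genome
contiguously, and the rest through the de novo spliced stage.  Without an
annotation the transcriptome stage is skipped and every junction is
classified novel_II.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field

from seedsplice.alignments import SplicedAlignment, classify_intron_motif
from seedsplice.config import MapperConfig
from seedsplice.formats_io import (
    Genome,
    Read,
    Transcript,
    write_junction_table,
    write_sam,
)
from seedsplice.junction_caller import Junction, call_junctions, support_histogram
from seedsplice.quantifier import GeneQuant, quantify_genes
from seedsplice.read_filter import FilterReport, filter_reads
from seedsplice.reference_index import build_seed_index, build_transcriptome
from seedsplice.spliced_mapper import map_spliced
from seedsplice.unspliced_mapper import map_unspliced, map_via_transcriptome


@dataclass
class RunReport:
    """Per-stage tallies of one pipeline run."""

    filter: FilterReport
    mapped_transcriptome: int = 0
    mapped_genome_unspliced: int = 0
    mapped_spliced: int = 0
    non_unique: int = 0
    unmapped: int = 0
    junction_classes: dict = field(default_factory=dict)
    junction_support: dict = field(default_factory=dict)
    quantified_genes: int = 0

    @property
    def total_unique(self) -> int:
        return self.mapped_transcriptome + self.mapped_genome_unspliced + self.mapped_spliced

    def check(self) -> None:
        total = self.total_unique + self.non_unique + self.unmapped
        assert total == self.filter.kept, "mapping categories do not add up"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["total_unique"] = self.total_unique
        return d


def run_pipeline(
    genome: Genome,
    transcripts: list[Transcript] | None,
    reads: list[Read],
    config: MapperConfig | None = None,
    outdir: str | None = None,
    min_phred: int = 10,
    min_len: int | None = None,
    qual_window: int | None = None,
):
    """Run the full mapping pipeline.

    Returns ``(report, alignments, junctions, quants)``; when ``outdir``
    is given also writes ``out.sam``, ``junctions.tsv``, ``quant.tsv`` and
    ``report.json`` there.  Output order is deterministic (input read
    order for SAM, coordinate order for junctions, gene id for quants).
    """
    config = config or MapperConfig()
    if min_len is None:
        min_len = config.min_read_length

    kept, filter_report = filter_reads(
        reads, min_len=min_len, min_phred=min_phred, window=qual_window
    )
    report = RunReport(filter=filter_report)

    unique_alignments = []
    remaining = kept

    if transcripts:
        transcriptome = build_transcriptome(genome, transcripts)
        tx_index = build_seed_index(transcriptome.sequences, config.seed_length)
        nxt = []
        for read in remaining:
            aln = map_via_transcriptome(read, transcriptome, config, index=tx_index)
            if aln is None:
                nxt.append(read)
            elif aln.unique:
                unique_alignments.append(aln)
                report.mapped_transcriptome += 1
            else:
                report.non_unique += 1
        remaining = nxt

    genome_index = build_seed_index(genome.contigs, config.seed_length)
    nxt = []
    for read in remaining:
        aln = map_unspliced(read, genome_index, genome, config)
        if aln is None:
            nxt.append(read)
        elif aln.unique:
            unique_alignments.append(aln)
            report.mapped_genome_unspliced += 1
        else:
            report.non_unique += 1
    remaining = nxt

    for read in remaining:
        aln = map_spliced(read, genome_index, genome, config)
        if aln is None:
            report.unmapped += 1
        elif aln.unique:
            unique_alignments.append(aln)
            report.mapped_spliced += 1
        else:
            report.non_unique += 1
    report.check()

    # annotate motif classes on projected alignments from the reference
    for aln in unique_alignments:
        if isinstance(aln, SplicedAlignment) and aln.source == "transcriptome":
            aln.motif_class = classify_intron_motif(
                genome[aln.contig], aln.intron[0], aln.intron[1]
            )[0]

    de_novo = [
        a for a in unique_alignments if isinstance(a, SplicedAlignment) and a.source == "spliced"
    ]
    projected = [
        a
        for a in unique_alignments
        if isinstance(a, SplicedAlignment) and a.source == "transcriptome"
    ]
    junctions = call_junctions(de_novo, projected, transcripts, genome=genome)
    report.junction_classes = {
        cls: sum(1 for j in junctions if j.annotation_class == cls)
        for cls in ("known", "novel_I", "novel_II")
    }
    report.junction_support = support_histogram(junctions)

    quants: list[GeneQuant] = []
    if transcripts and unique_alignments:
        quants = quantify_genes(unique_alignments, transcripts, len(unique_alignments))
        report.quantified_genes = sum(1 for q in quants if q.quantified)

    if outdir is not None:
        os.makedirs(outdir, exist_ok=True)
        write_sam(unique_alignments, genome, os.path.join(outdir, "out.sam"))
        write_junction_table(junctions, os.path.join(outdir, "junctions.tsv"))
        with open(os.path.join(outdir, "quant.tsv"), "w") as fh:
            fh.write("gene_id\tread_count\tgene_length\trpkM\tquantified\n")
            for q in quants:
                fh.write(
                    f"{q.gene_id}\t{q.read_count}\t{q.gene_length}\t"
                    f"{q.rpkm:.6f}\t{int(q.quantified)}\n"
                )
        with open(os.path.join(outdir, "report.json"), "w") as fh:
            json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    return report, unique_alignments, junctions, quants
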