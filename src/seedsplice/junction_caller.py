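"""Aggregate per-read junction evidence into classified junction calls.

Junctions are keyed by (contig, strand, intron interval); support is the
number of distinct uniquely-mapped reads whose alignment spans the intron,
pooling transcriptome-projected (annotated) and de novo spliced
alignments.  Classification follows the annotation:

* ``known``    — the intron is in the annotated junction set;
* ``novel_I``  — unannotated, but inside an annotated gene's genomic span;
* ``novel_II`` — outside any annotated gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from intervaltree import IntervalTree

from seedsplice.alignments import classify_intron_motif
from seedsplice.formats_io import Genome, Transcript

ANNOTATION_CLASSES = ("known", "novel_I", "novel_II")


@dataclass
class Junction:
    contig: str
    strand: str
    intron: tuple[int, int]
    motif_class: str
    support: int
    annotation_class: str
    matches_known_elsewhere: bool = False


def _gene_span_trees(transcripts: Sequence[Transcript]) -> dict[str, IntervalTree]:
    """Per-contig interval tree of gene spans (union of transcript spans,
    introns included, strand ignored)."""
    spans: dict[tuple[str, str], list[int]] = {}
    for tx in transcripts:
        key = (tx.contig, tx.gene_id)
        lo, hi = tx.span
        if key in spans:
            spans[key][0] = min(spans[key][0], lo)
            spans[key][1] = max(spans[key][1], hi)
        else:
            spans[key] = [lo, hi]
    trees: dict[str, IntervalTree] = {}
    for (contig, gene_id), (lo, hi) in spans.items():
        trees.setdefault(contig, IntervalTree()).addi(lo, hi, gene_id)
    return trees


def annotated_junction_set(transcripts: Sequence[Transcript]) -> set[tuple[str, int, int]]:
    out: set[tuple[str, int, int]] = set()
    for tx in transcripts:
        for intron in tx.introns:
            out.add((tx.contig, intron[0], intron[1]))
    return out


def call_junctions(
    spliced_alignments: Iterable,
    known_alignments: Iterable,
    annotation: Sequence[Transcript] | None,
    genome: Genome | None = None,
) -> list[Junction]:
    """Pool unique spanning reads into classified junction calls.

    ``spliced_alignments`` are de novo calls, ``known_alignments`` come
    from transcriptome projection; both must already be unique mappings
    (non-unique ones are ignored defensively).  When a genome is supplied
    the motif class of every junction is (re)derived from the reference;
    otherwise the class recorded on the supporting alignments is used.
    Junctions are returned sorted by coordinate.
    """
    annotation = annotation or []
    known_set = annotated_junction_set(annotation)
    gene_trees = _gene_span_trees(annotation)

    support: dict[tuple[str, str, tuple[int, int]], set[str]] = {}
    motif_of: dict[tuple[str, str, tuple[int, int]], str] = {}
    for aln in list(spliced_alignments) + list(known_alignments):
        if not aln.unique:
            continue
        strand = getattr(aln, "junction_strand", aln.strand)
        for intron in aln.introns:
            key = (aln.contig, strand, intron)
            support.setdefault(key, set()).add(aln.read_id)
            if key not in motif_of and aln.motif_class in (
                "GT-AG",
                "GC-AG",
                "AT-AC",
                "noncanonical",
            ):
                motif_of[key] = aln.motif_class

    junctions: list[Junction] = []
    for (contig, strand, intron), readers in sorted(support.items()):
        if genome is not None:
            motif = classify_intron_motif(genome[contig], intron[0], intron[1])[0]
        else:
            motif = motif_of.get((contig, strand, intron), "noncanonical")
        if (contig, intron[0], intron[1]) in known_set:
            ann_class = "known"
        elif contig in gene_trees and gene_trees[contig].overlap(intron[0], intron[1]):
            ann_class = "novel_I"
        else:
            ann_class = "novel_II"
        junctions.append(
            Junction(
                contig=contig,
                strand=strand,
                intron=intron,
                motif_class=motif,
                support=len(readers),
                annotation_class=ann_class,
            )
        )
    return junctions


def support_histogram(junctions: Iterable[Junction]) -> dict[str, int]:
    """Junction counts stratified by supporting reads: 1, 2, 3, 4, >=5."""
    bins = {"1": 0, "2": 0, "3": 0, "4": 0, ">=5": 0}
    for j in junctions:
        if j.support >= 5:
            bins[">=5"] += 1
        else:
            bins[str(j.support)] += 1
    return bins


def flag_known_equivalents(
    junctions: Sequence[Junction],
    annotation: Sequence[Transcript],
    tolerance: int = 0,
) -> list[Junction]:
    """Mark novel-labelled junctions whose intron matches an annotated one.

    With ``tolerance`` 0 the match is exact coordinate identity; a positive
    tolerance allows each intron end to differ by up to that many nt.
    Returns the same junction objects with the flag set.
    """
    known = annotated_junction_set(annotation)
    by_contig: dict[str, list[tuple[int, int]]] = {}
    for contig, s, e in known:
        by_contig.setdefault(contig, []).append((s, e))
    for j in junctions:
        if j.annotation_class == "known":
            continue
        for s, e in by_contig.get(j.contig, ()):
            if abs(j.intron[0] - s) <= tolerance and abs(j.intron[1] - e) <= tolerance:
                j.matches_known_elsewhere = True
                break
    return list(junctions)
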