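"""Gene-level quantification (merged splice variants, rpkM) and bias metrics.

Splice variants of a gene are merged into the union of their exons; a read
is assigned to a gene when its aligned blocks overlap that union, and
dropped as ambiguous when it overlaps more than one gene.  Expression is
reported as rpkM = reads per kilobase of merged exon model per million
uniquely mapped reads, and a gene with at least 10 assigned reads counts
as quantified.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree

from seedsplice._dna import gc_fraction
from seedsplice.formats_io import Genome, Transcript

QUANTIFIED_MIN_READS = 10


@dataclass
class GeneQuant:
    gene_id: str
    read_count: int
    gene_length: int
    rpkm: float
    quantified: bool


def merged_exon_union(transcripts: Sequence[Transcript]) -> dict[str, list[tuple[str, int, int]]]:
    """Per-gene merged exon intervals: gene_id -> [(contig, start, end), ...]."""
    raw: dict[str, list[tuple[str, int, int]]] = {}
    for tx in transcripts:
        raw.setdefault(tx.gene_id, []).extend((tx.contig, s, e) for s, e in tx.exons)
    merged: dict[str, list[tuple[str, int, int]]] = {}
    for gene_id, ivs in raw.items():
        out: list[tuple[str, int, int]] = []
        for contig in sorted({c for c, _, _ in ivs}):
            spans = sorted((s, e) for c, s, e in ivs if c == contig)
            cur_s, cur_e = spans[0]
            for s, e in spans[1:]:
                if s <= cur_e:
                    cur_e = max(cur_e, e)
                else:
                    out.append((contig, cur_s, cur_e))
                    cur_s, cur_e = s, e
            out.append((contig, cur_s, cur_e))
        merged[gene_id] = out
    return merged


def quantify_genes(
    alignments: Iterable,
    annotation: Sequence[Transcript],
    total_mapped: int,
) -> list[GeneQuant]:
    """Count unique reads per gene and compute rpkM.

    ``total_mapped`` is the rpkM denominator: the number of uniquely
    mapped reads in the run.  Reads whose blocks overlap the merged exons
    of more than one gene are ambiguous and counted for none.
    """
    if total_mapped <= 0:
        raise ValueError("total_mapped must be positive")
    union = merged_exon_union(annotation)
    trees: dict[str, IntervalTree] = {}
    lengths: dict[str, int] = {}
    for gene_id, ivs in union.items():
        lengths[gene_id] = sum(e - s for _, s, e in ivs)
        for contig, s, e in ivs:
            trees.setdefault(contig, IntervalTree()).addi(s, e, gene_id)

    counts: dict[str, int] = {g: 0 for g in union}
    for aln in alignments:
        if not aln.unique:
            continue
        genes: set[str] = set()
        tree = trees.get(aln.contig)
        if tree is None:
            continue
        for s, e in aln.blocks:
            genes.update(iv.data for iv in tree.overlap(s, e))
        if len(genes) == 1:
            counts[genes.pop()] += 1

    quants = []
    for gene_id in sorted(union):
        n = counts[gene_id]
        length = lengths[gene_id]
        rpkm = n / (length / 1000) / (total_mapped / 1_000_000)
        quants.append(
            GeneQuant(gene_id, n, length, rpkm, quantified=n >= QUANTIFIED_MIN_READS)
        )
    return quants


def expression_summary(quants: Sequence[GeneQuant]) -> tuple[float, float]:
    """Mean and median rpkM over quantified genes only."""
    vals = [q.rpkm for q in quants if q.quantified]
    if not vals:
        raise ValueError("no quantified genes")
    return float(np.mean(vals)), float(np.median(vals))


def gc_expression_profile(
    quants: Sequence[GeneQuant],
    annotation: Sequence[Transcript],
    genome: Genome,
    min_rpkm: float = 1.0,
) -> list[dict]:
    """Mean rpkM per 5% GC bin over genes with rpkM above ``min_rpkm``.

    GC content is computed over the merged exon union of each gene.
    Returns one row per non-empty bin:
    ``{"gc_bin": "40-45%", "mean_rpkm": ..., "n_genes": ...}``.
    """
    union = merged_exon_union(annotation)
    rows: dict[int, list[float]] = {}
    for q in quants:
        if q.rpkm <= min_rpkm:
            continue
        seq = "".join(genome[c][s:e] for c, s, e in union[q.gene_id])
        gc = gc_fraction(seq)
        b = min(int(gc * 100 // 5), 19)
        rows.setdefault(b, []).append(q.rpkm)
    return [
        {
            "gc_bin": f"{5 * b}-{5 * b + 5}%",
            "mean_rpkm": float(np.mean(vals)),
            "n_genes": len(vals),
        }
        for b, vals in sorted(rows.items())
    ]


def three_prime_coverage(
    alignments: Iterable,
    annotation: Sequence[Transcript],
    length_classes: Mapping[str, tuple[int, float]] | None = None,
    n_bins: int = 100,
) -> dict[str, np.ndarray]:
    """Normalised read-start coverage along relative mRNA position.

    Each gene uses its longest annotated transcript as the coordinate
    frame; read starts (5' end of the mRNA-strand alignment) are projected
    to relative position in [0, 1), histogrammed into ``n_bins`` bins per
    gene, and gene profiles are averaged per length class and scaled to
    mean 1.  Reads whose start does not fall on the frame transcript's
    exons are skipped.
    """
    if length_classes is None:
        length_classes = {"<4kb": (0, 4000), ">=4kb": (4000, float("inf"))}

    frame: dict[str, Transcript] = {}
    for tx in annotation:
        cur = frame.get(tx.gene_id)
        if cur is None or tx.spliced_length > cur.spliced_length:
            frame[tx.gene_id] = tx

    trees: dict[str, IntervalTree] = {}
    for gene_id, tx in frame.items():
        for s, e in tx.exons:
            trees.setdefault(tx.contig, IntervalTree()).addi(s, e, gene_id)

    per_gene: dict[str, np.ndarray] = {}
    for aln in alignments:
        if not aln.unique:
            continue
        tree = trees.get(aln.contig)
        if tree is None:
            continue
        genes = {iv.data for s, e in aln.blocks for iv in tree.overlap(s, e)}
        if len(genes) != 1:
            continue
        gene_id = genes.pop()
        tx = frame[gene_id]
        # 5' end of the alignment in mRNA orientation
        g5 = aln.blocks[0][0] if tx.strand == "+" else aln.blocks[-1][1] - 1
        offset = 0
        t_pos = None
        for s, e in tx.exons:
            if s <= g5 < e:
                t_pos = offset + g5 - s
                break
            offset += e - s
        if t_pos is None:
            continue
        if tx.strand == "-":
            t_pos = tx.spliced_length - 1 - t_pos
        rel_bin = min(int(t_pos / tx.spliced_length * n_bins), n_bins - 1)
        per_gene.setdefault(gene_id, np.zeros(n_bins))[rel_bin] += 1

    profiles: dict[str, np.ndarray] = {}
    for cls, (lo, hi) in length_classes.items():
        mats = []
        for gene_id, counts in per_gene.items():
            length = frame[gene_id].spliced_length
            if lo <= length < hi and counts.sum() > 0:
                mats.append(counts / counts.mean())
        if mats:
            prof = np.mean(mats, axis=0)
            profiles[cls] = prof / prof.mean()
        else:
            profiles[cls] = np.zeros(n_bins)
    return profiles
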