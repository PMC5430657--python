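"""Error-tolerant unspliced (contiguous) read mapping.

Reads are split into exact-match seeds, seed hits vote for candidate
diagonals, and each candidate locus is verified by banded edit-distance
alignment of the whole read (edlib).  The same machinery maps reads to the
transcriptome first: a transcript alignment is projected through the exon
table to genomic blocks, turning annotated introns it crosses into N gaps.
"""

from __future__ import annotations

import re

import edlib

from seedsplice._dna import revcomp
from seedsplice.alignments import SplicedAlignment, UnsplicedAlignment
from seedsplice.config import MapperConfig
from seedsplice.formats_io import Genome, Read, cigar_ref_span
from seedsplice.reference_index import SeedIndex, TranscriptomeRef

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


def split_into_seeds(sequence: str, seed_length: int) -> list[tuple[int, str]]:
    """Split a read into consecutive non-overlapping seeds of ``seed_length``.

    When the read length is not a multiple of the seed length, one extra
    seed covering the final ``seed_length`` bases is appended (it overlaps
    the previous seed), so the union of seeds covers the whole read.
    """
    n = len(sequence)
    if n < seed_length:
        raise ValueError(f"read of {n} nt shorter than seed length {seed_length}")
    offsets = list(range(0, n - seed_length + 1, seed_length))
    if n % seed_length != 0:
        offsets.append(n - seed_length)
    return [(off, sequence[off : off + seed_length]) for off in offsets]


def _edlib_to_midn(ext_cigar: str) -> str:
    """Collapse edlib's =/X ops to M and merge adjacent equal ops."""
    out: list[tuple[int, str]] = []
    for m in _CIGAR_RE.finditer(ext_cigar):
        n, op = int(m.group(1)), m.group(2)
        if op in "=X":
            op = "M"
        if out and out[-1][1] == op:
            out[-1] = (out[-1][0] + n, op)
        else:
            out.append((n, op))
    return "".join(f"{n}{op}" for n, op in out)


def align_candidate(
    query: str, ref: str, ref_start_guess: int, max_errors: int
) -> tuple[int, str, int] | None:
    """Verify one candidate locus by banded full-read alignment.

    Aligns the whole query inside a reference window of
    ``[guess - E, guess + len(query) + E)`` and returns
    ``(ref_start, cigar, n_errors)`` for the minimal-edit placement, or
    None when no placement within ``max_errors`` exists there.
    """
    lo = max(0, ref_start_guess - max_errors)
    hi = min(len(ref), ref_start_guess + len(query) + max_errors)
    window = ref[lo:hi]
    if len(window) < 1:
        return None
    res = edlib.align(query, window, mode="HW", task="path", k=max_errors)
    if res["editDistance"] < 0:
        return None
    start = lo + res["locations"][0][0]
    return start, _edlib_to_midn(res["cigar"]), res["editDistance"]


def _candidate_diagonals(
    query: str, index: SeedIndex, config: MapperConfig
) -> set[tuple[str, int]]:
    diags: set[tuple[str, int]] = set()
    if len(query) < index.k:
        return diags
    for offset, seed in split_into_seeds(query, index.k):
        if "N" in seed:
            continue
        occ = index.lookup(seed)
        if len(occ) > config.occurrence_cap:
            continue
        for name, pos in occ:
            diags.add((name, pos - offset))
    return diags


def _collapse_loci(hits: list[tuple], max_errors: int) -> list[tuple]:
    """Merge verified placements closer than E on one sequence/strand,
    keeping the lowest-error representative."""
    hits.sort(key=lambda h: (h[0], h[1], h[2]))  # (name, strand, ref_start, ...)
    merged: list[tuple] = []
    for h in hits:
        if (
            merged
            and merged[-1][0] == h[0]
            and merged[-1][1] == h[1]
            and abs(h[2] - merged[-1][2]) <= max_errors
        ):
            if h[4] < merged[-1][4]:
                merged[-1] = h
        else:
            merged.append(h)
    return merged


def _search_unspliced(
    read_seq: str, index: SeedIndex, sequences: dict[str, str], config: MapperConfig
) -> list[tuple[str, str, int, str, int]]:
    """All verified placements of the read (both orientations), locus-collapsed.

    Returns tuples ``(name, strand, ref_start, cigar, n_errors)``.
    """
    hits: list[tuple[str, str, int, str, int]] = []
    for strand in "+-":
        q = read_seq if strand == "+" else revcomp(read_seq)
        for name, diag in _candidate_diagonals(q, index, config):
            res = align_candidate(q, sequences[name], diag, config.max_errors)
            if res is not None:
                hits.append((name, strand, res[0], res[1], res[2]))
    return _collapse_loci(hits, config.max_errors)


def map_unspliced(
    read: Read, index: SeedIndex, ref: Genome | dict[str, str], config: MapperConfig
) -> UnsplicedAlignment | None:
    """Best contiguous alignment of the read over both strands, or None.

    ``unique`` is False when a second locus aligns within
    ``config.score_margin`` errors of the best.
    """
    sequences = ref.contigs if isinstance(ref, Genome) else ref
    hits = _search_unspliced(read.sequence, index, sequences, config)
    if not hits:
        return None
    hits.sort(key=lambda h: (h[4], h[0], h[1], h[2]))
    best = hits[0]
    n_close = sum(1 for h in hits if h[4] <= best[4] + config.score_margin)
    return UnsplicedAlignment(
        read=read,
        contig=best[0],
        strand=best[1],
        ref_start=best[2],
        cigar=best[3],
        n_errors=best[4],
        unique=(n_close == 1),
    )


# ---------------------------------------------------------------------------
# transcriptome mapping with projection to the genome


def _project_cigar(
    tx, c_start: int, ops: list[tuple[int, str]]
) -> tuple[tuple[tuple[int, int], ...], str]:
    """Project a concatenation-coordinate alignment through the exon table.

    ``c_start`` and ``ops`` are on the plus-strand exon concatenation, left
    to right; M/D segments crossing an exon boundary are split and the
    annotated intron inserted as an N op.  Returns (genomic blocks, cigar).
    """
    # exon table in concatenation coordinates
    bounds = []
    off = 0
    for s, e in tx.exons:
        bounds.append((off, off + (e - s), s))
        off += e - s

    def to_genomic(c: int) -> int:
        for lo, hi, gstart in bounds:
            if lo <= c < hi:
                return gstart + (c - lo)
        raise ValueError("concatenation coordinate out of range")

    out: list[tuple[int, str]] = []
    blocks: list[list[int]] = []
    c = c_start

    def emit(n: int, op: str) -> None:
        if out and out[-1][1] == op:
            out[-1] = (out[-1][0] + n, op)
        else:
            out.append((n, op))

    g_prev_end: int | None = None

    def advance_ref(n: int, op: str) -> None:
        nonlocal c, g_prev_end
        remaining = n
        while remaining > 0:
            g = to_genomic(c)
            # room left in the current exon
            for lo, hi, gstart in bounds:
                if lo <= c < hi:
                    room = hi - c
                    break
            step = min(remaining, room)
            if g_prev_end is not None and g > g_prev_end:
                emit(g - g_prev_end, "N")
            if op == "M":
                if blocks and g_prev_end == g:
                    blocks[-1][1] = g + step
                else:
                    blocks.append([g, g + step])
            else:  # D consumes reference inside the current block
                if blocks and g_prev_end == g:
                    blocks[-1][1] = g + step
                else:
                    blocks.append([g, g + step])
            emit(step, op)
            g_prev_end = g + step
            c += step
            remaining -= step

    for n, op in ops:
        if op in "M":
            advance_ref(n, "M")
        elif op == "D":
            advance_ref(n, "D")
        elif op == "I":
            emit(n, "I")
        else:
            raise ValueError(f"unexpected op {op!r} in transcript alignment")
    cigar = "".join(f"{n}{op}" for n, op in out)
    return tuple((b[0], b[1]) for b in blocks), cigar


def _parse_midn(cigar: str) -> list[tuple[int, str]]:
    return [(int(n), op) for n, op in re.findall(r"(\d+)([MIDN])", cigar)]


def map_via_transcriptome(
    read: Read,
    transcriptome: TranscriptomeRef,
    config: MapperConfig,
    index: SeedIndex | None = None,
) -> UnsplicedAlignment | SplicedAlignment | None:
    """Map a read to annotated mRNAs and project the hit onto the genome.

    Crossed annotated introns become N gaps; placements projecting to
    identical genomic blocks (e.g. via two isoforms sharing the exon)
    count as one location for uniqueness.  Returns None when no transcript
    aligns within the error budget.
    """
    if index is None:
        from seedsplice.reference_index import build_seed_index

        index = build_seed_index(transcriptome.sequences, config.seed_length)
    hits = _search_unspliced(read.sequence, index, transcriptome.sequences, config)
    if not hits:
        return None

    placements: dict[tuple, dict] = {}
    for tx_id, orientation, t_start, cigar_t, n_err in hits:
        tx = transcriptome.transcripts[tx_id]
        total = tx.spliced_length
        ops = _parse_midn(cigar_t)
        t_end = t_start + sum(n for n, op in ops if op in "MD")
        if tx.strand == "-":
            c_start = total - t_end
            ops = ops[::-1]
        else:
            c_start = t_start
        blocks, g_cigar = _project_cigar(tx, c_start, ops)
        g_strand = "+" if orientation == tx.strand else "-"
        key = (tx.contig, g_strand, blocks)
        prev = placements.get(key)
        if prev is None or n_err < prev["n_errors"]:
            placements[key] = {
                "contig": tx.contig,
                "strand": g_strand,
                "blocks": blocks,
                "cigar": g_cigar,
                "n_errors": n_err,
                "tx_strand": tx.strand,
            }

    ranked = sorted(
        placements.values(),
        key=lambda p: (p["n_errors"], p["contig"], p["strand"], p["blocks"]),
    )
    best = ranked[0]
    n_close = sum(
        1 for p in ranked if p["n_errors"] <= best["n_errors"] + config.score_margin
    )
    unique = n_close == 1
    if len(best["blocks"]) == 1:
        return UnsplicedAlignment(
            read=read,
            contig=best["contig"],
            strand=best["strand"],
            ref_start=best["blocks"][0][0],
            cigar=best["cigar"],
            n_errors=best["n_errors"],
            unique=unique,
            source="transcriptome",
        )
    return SplicedAlignment(
        read=read,
        contig=best["contig"],
        strand=best["strand"],
        blocks=best["blocks"],
        cigar=best["cigar"],
        n_errors=best["n_errors"],
        motif_class="annotated",
        junction_strand=best["tx_strand"],
        unique=unique,
        source="transcriptome",
    )
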