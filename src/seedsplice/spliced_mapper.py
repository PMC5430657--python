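"""De novo spliced mapping: hotspots, hotspot pairs, splice-site resolution.

A read that failed contiguous mapping is split into exact seeds; seed hits
sharing a (contig, strand, diagonal) are merged into *hotspots*; hotspot
pairs in read order whose genomic gap lies within the intron bounds
[N, X] are scored by their total seed support and examined in descending
score order.  For each pair the unanchored interval between the two
anchored spans is aligned carefully from both directions: prefix edit
distances extend the left hotspot's diagonal, suffix edit distances the
right's, and every breakpoint (with up to E nt of slack on each induced
intron end) is scored.  The minimal-error breakpoint wins; among
equal-error placements those whose intron bears a canonical splice signal
are preferred, in the order GT-AG > GC-AG > AT-AC > noncanonical.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib
import numpy as np

from seedsplice._dna import revcomp
from seedsplice.alignments import (
    MOTIF_RANK,
    SplicedAlignment,
    classify_intron_motif,
)
from seedsplice.config import MapperConfig
from seedsplice.formats_io import Genome, Read
from seedsplice.reference_index import SeedIndex
from seedsplice.unspliced_mapper import _edlib_to_midn, split_into_seeds

_BIG = np.int64(10**6)

_BASE_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i


def _dinuc_codes(contig_seq: str, lo: int, hi: int) -> np.ndarray:
    """Code (0..24) of the dinucleotide starting at each position in [lo, hi)."""
    lo_c = max(0, lo)
    window = contig_seq[lo_c : hi + 1]
    enc = _BASE_CODE[np.frombuffer(window.encode(), dtype=np.uint8)].astype(np.intp)
    # pad so out-of-range positions decode as N-containing (rank: noncanonical)
    pad_left = lo_c - lo
    enc = np.concatenate([np.full(pad_left, 4, dtype=np.intp), enc, [4, 4]])
    return enc[:-1][: hi - lo] * 5 + enc[1:][: hi - lo]


def _build_rank_table() -> np.ndarray:
    from seedsplice.alignments import _MOTIF_TABLE

    bases = "ACGTN"
    table = np.full((25, 25), MOTIF_RANK["noncanonical"], dtype=np.int8)
    for (donor, acceptor), (motif, _) in _MOTIF_TABLE.items():
        di = bases.index(donor[0]) * 5 + bases.index(donor[1])
        ai = bases.index(acceptor[0]) * 5 + bases.index(acceptor[1])
        table[di, ai] = MOTIF_RANK[motif]
    return table


_RANK_TABLE = _build_rank_table()


@dataclass(frozen=True)
class SeedMatch:
    """One exact seed hit; diagonal = ref_pos - seed_offset."""

    seed_offset: int
    contig: str
    strand: str
    ref_pos: int

    @property
    def diagonal(self) -> int:
        return self.ref_pos - self.seed_offset


@dataclass
class Hotspot:
    """A diagonal cluster of exact seed matches (one candidate exon anchor)."""

    contig: str
    strand: str
    diagonal: int
    read_span: tuple[int, int]  # first offset, last offset + S
    n_seeds: int


@dataclass
class HotspotPair:
    """Two read-ordered hotspots bracketing a candidate intron."""

    left: Hotspot
    right: Hotspot

    @property
    def score(self) -> int:
        return self.left.n_seeds + self.right.n_seeds

    @property
    def gap(self) -> int:
        return self.right.diagonal - self.left.diagonal

    @property
    def contig(self) -> str:
        return self.left.contig

    @property
    def strand(self) -> str:
        return self.left.strand


def generate_hotspots(read: Read, index: SeedIndex, config: MapperConfig) -> list[Hotspot]:
    """Exact seed matches of both read orientations, merged along diagonals.

    Matches on one diagonal whose read offsets are within
    ``config.adjacency_slack`` of each other join one hotspot, so a single
    error-destroyed seed does not split an anchor.  Seeds whose k-mer
    exceeds the occurrence cap are ignored.
    """
    hotspots: list[Hotspot] = []
    S = index.k
    if len(read) < S:
        return hotspots
    for strand in "+-":
        q = read.sequence if strand == "+" else revcomp(read.sequence)
        by_diag: dict[tuple[str, int], list[int]] = {}
        for offset, seed in split_into_seeds(q, S):
            if "N" in seed:
                continue
            occ = index.lookup(seed)
            if len(occ) > config.occurrence_cap:
                continue
            for name, pos in occ:
                by_diag.setdefault((name, pos - offset), []).append(offset)
        for (name, diag), offsets in by_diag.items():
            offsets = sorted(set(offsets))
            run = [offsets[0]]
            for off in offsets[1:]:
                if off - run[-1] <= config.adjacency_slack:
                    run.append(off)
                else:
                    hotspots.append(
                        Hotspot(name, strand, diag, (run[0], run[-1] + S), len(run))
                    )
                    run = [off]
            hotspots.append(Hotspot(name, strand, diag, (run[0], run[-1] + S), len(run)))
    return hotspots


def enumerate_pairs(hotspots: list[Hotspot], config: MapperConfig) -> list[HotspotPair]:
    """All read-ordered same-strand hotspot pairs with gap in [N, X].

    Sorted by descending score; ties examine the shorter genomic gap first,
    then the smaller genomic coordinate, so the order is deterministic.
    """
    pairs: list[HotspotPair] = []
    for left in hotspots:
        for right in hotspots:
            if left is right:
                continue
            if (left.contig, left.strand) != (right.contig, right.strand):
                continue
            if not (
                left.read_span[0] < right.read_span[0]
                and left.read_span[1] <= right.read_span[1]
            ):
                continue
            gap = right.diagonal - left.diagonal
            if config.min_intron <= gap <= config.max_intron:
                pairs.append(HotspotPair(left, right))
    pairs.sort(key=lambda p: (-p.score, p.gap, p.contig, p.left.diagonal))
    return pairs


# ---------------------------------------------------------------------------
# bidirectional splice-site resolution


def _prefix_edit_matrix(query: str, ref: str) -> np.ndarray:
    """D[i, j] = edit distance between query[:i] and ref[:j].

    Row update uses the prefix-minimum identity
    ``D[i, j] = min(V[j], min_{k<=j}(V[k] + j - k))`` with
    ``V[j] = min(D[i-1, j] + 1, D[i-1, j-1] + subst_cost)``, which makes
    each row a vectorised scan instead of a sequential loop.
    """
    n, m = len(query), len(ref)
    q = np.frombuffer(query.encode(), dtype=np.uint8)
    r = np.frombuffer(ref.encode(), dtype=np.uint8)
    D = np.empty((n + 1, m + 1), dtype=np.int32)
    D[0] = np.arange(m + 1, dtype=np.int32)
    j_idx = np.arange(m + 1, dtype=np.int32)
    for i in range(1, n + 1):
        prev = D[i - 1]
        V = np.empty(m + 1, dtype=np.int32)
        V[0] = i
        sub = prev[:-1] + (q[i - 1] != r).astype(np.int32)
        np.minimum(prev[1:] + 1, sub, out=V[1:])
        D[i] = np.minimum.accumulate(V - j_idx) + j_idx
    return D


def _block_cigar(query: str, ref: str) -> str:
    if not query and not ref:
        return ""
    res = edlib.align(query, ref, mode="NW", task="path")
    return _edlib_to_midn(res["cigar"])


def resolve_splice_site(
    read: Read, pair: HotspotPair, genome: Genome, config: MapperConfig
) -> SplicedAlignment | None:
    """Place the splice junction inside the interval between two hotspots.

    The left exonic block starts on the left hotspot's diagonal at the
    read's first base; the right block ends on the right hotspot's diagonal
    at the read's last base.  Every breakpoint b (read coordinate) and up
    to E nt of diagonal slack on each intron end are scored by the sum of
    prefix and suffix edit distances; the minimum wins, canonical splice
    signals breaking ties (GT-AG > GC-AG > AT-AC > noncanonical) when
    ``config.motif_guidance`` is on.  Returns None when the best placement
    needs more than E errors, violates the intron bounds, leaves an exonic
    block shorter than ``min_anchor``, or (with ``canonical_only``) is
    non-canonical.
    """
    contig_seq = genome[pair.contig]
    E = config.max_errors
    q = read.sequence if pair.strand == "+" else revcomp(read.sequence)
    L = len(q)
    dL = pair.left.diagonal
    dR = pair.right.diagonal
    if dL < 0 or dR + L > len(contig_seq):
        return None
    if L < 2 * config.min_anchor:
        return None

    left_ref = contig_seq[dL : dL + L + E]
    right_lo = max(0, dR - E)
    right_ref = contig_seq[right_lo : dR + L]
    off_r = dR - right_lo  # index in right_ref of genomic position dR

    D = _prefix_edit_matrix(q, left_ref)
    Dr = _prefix_edit_matrix(q[::-1], right_ref[::-1])
    # R[i, j] = edit distance of q[i:] vs right_ref[j:]
    R = Dr[::-1, ::-1]

    b_vals = np.arange(config.min_anchor, L - config.min_anchor + 1)
    if b_vals.size == 0:
        return None
    W = 2 * E + 1
    t = np.arange(W) - E

    # banded prefix/suffix costs: jl = b + t, jr = b + off_r + t
    jl = b_vals[:, None] + t[None, :]
    jr = b_vals[:, None] + off_r + t[None, :]
    jl_ok = (jl >= 1) & (jl <= len(left_ref))
    jr_ok = (jr >= 0) & (jr <= len(right_ref) - 1)
    Dband = np.where(jl_ok, D[b_vals[:, None], np.clip(jl, 0, len(left_ref))], _BIG)
    Rband = np.where(jr_ok, R[b_vals[:, None], np.clip(jr, 0, len(right_ref))], _BIG)

    cost = Dband[:, :, None] + Rband[:, None, :]  # (B, W, W)

    # intron length depends only on the two slacks: gap - t1 + t2
    intron_len = pair.gap - t[:, None] + t[None, :]  # (W, W)
    len_ok = (intron_len >= config.min_intron) & (intron_len <= config.max_intron)

    # motif rank of every (donor, acceptor) combination via dinucleotide codes
    donor_pos = dL + jl  # (B, W) genomic start of the intron
    accept_pos = right_lo + jr  # (B, W) genomic end (one past last intronic base)
    d_lo = int(donor_pos.min())
    d_hi = int(donor_pos.max())
    a_lo = int(accept_pos.min())
    a_hi = int(accept_pos.max())
    donor_codes = _dinuc_codes(contig_seq, d_lo, d_hi + 2)
    accept_codes = _dinuc_codes(contig_seq, a_lo - 2, a_hi)
    dc = donor_codes[donor_pos - d_lo]  # (B, W)
    ac = accept_codes[accept_pos - a_lo]  # (B, W)
    rank = _RANK_TABLE[dc[:, :, None], ac[:, None, :]].astype(np.int64)

    valid = len_ok[None, :, :] & jl_ok[:, :, None] & jr_ok[:, None, :]
    rank_term = rank if config.motif_guidance else np.zeros_like(rank)

    # lexicographic key: errors, motif rank, donor offset, slacks
    b_off = (b_vals - b_vals[0])[:, None, None] + np.arange(W)[None, :, None]
    key = (
        ((cost * 4 + rank_term) * (len(b_vals) + W) + b_off) * W
        + np.arange(W)[None, None, :]
    )
    key = np.where(valid & (cost <= E), key, np.int64(2**62))
    flat = int(np.argmin(key))
    if key.flat[flat] == 2**62:
        return None
    bi, t1, t2 = np.unravel_index(flat, key.shape)
    b = int(b_vals[bi])
    donor = int(donor_pos[bi, t1])
    acceptor = int(accept_pos[bi, t2])
    n_err = int(cost[bi, t1, t2])
    motif, motif_strand = classify_intron_motif(contig_seq, donor, acceptor)
    if config.canonical_only and motif == "noncanonical":
        return None

    left_cig = _block_cigar(q[:b], contig_seq[dL:donor])
    right_cig = _block_cigar(q[b:], contig_seq[acceptor : dR + L])
    cigar = f"{left_cig}{acceptor - donor}N{right_cig}"
    return SplicedAlignment(
        read=read,
        contig=pair.contig,
        strand=pair.strand,
        blocks=((dL, donor), (acceptor, dR + L)),
        cigar=cigar,
        n_errors=n_err,
        motif_class=motif,
        junction_strand=motif_strand if motif_strand is not None else pair.strand,
        unique=True,
        source="spliced",
    )


def map_spliced(
    read: Read, index: SeedIndex, genome: Genome, config: MapperConfig
) -> SplicedAlignment | None:
    """Resolve the best-scoring hotspot pair into a spliced alignment.

    Pairs are examined in descending score order; all resolvable pairs are
    checked so that a second distinct placement with an equally good error
    count marks the read non-unique (such reads contribute no junctions).
    """
    hotspots = generate_hotspots(read, index, config)
    pairs = enumerate_pairs(hotspots, config)[: config.max_pairs]
    resolved: list[SplicedAlignment] = []
    for pair in pairs:
        aln = resolve_splice_site(read, pair, genome, config)
        if aln is not None:
            resolved.append(aln)
    if not resolved:
        return None
    best = min(range(len(resolved)), key=lambda i: (resolved[i].n_errors, i))
    best_aln = resolved[best]
    placements = {
        (a.contig, a.blocks)
        for a in resolved
        if a.n_errors <= best_aln.n_errors + config.score_margin
    }
    best_aln.unique = len(placements) == 1
    return best_aln
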