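"""Independent reference implementations used as test oracles.

These deliberately use different code paths from the package:

* ``edit_distance`` / ``infix_distance`` are hand-written Wagner-Fischer
  dynamic programming, checking the edlib-backed unspliced verifier;
* ``exhaustive_splice_scan`` scores every breakpoint/slack combination
  with edlib NW calls, checking the package's own bidirectional DP;
* ``naive_kmer_scan`` is a direct string scan, checking the seed index.
"""

from __future__ import annotations

import numpy as np

_ORACLE_MOTIFS = {
    ("GT", "AG"): 0,
    ("GC", "AG"): 1,
    ("AT", "AC"): 2,
    ("CT", "AC"): 0,
    ("CT", "GC"): 1,
    ("GT", "AT"): 2,
}


def edit_distance(a: str, b: str) -> int:
    """Plain O(nm) global edit distance, no banding, no tricks."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def infix_distance(query: str, text: str) -> int:
    """Minimal edit distance of the whole query against any substring of text.

    Row-wise DP with free start/end in the text; vectorised per row so a
    20 kb text stays fast, but structurally independent of the mapper.
    """
    q = np.frombuffer(query.encode(), dtype=np.uint8)
    t = np.frombuffer(text.encode(), dtype=np.uint8)
    m = len(t)
    j_idx = np.arange(m + 1, dtype=np.int32)
    row = np.zeros(m + 1, dtype=np.int32)  # free start in text
    for i in range(1, len(q) + 1):
        V = np.empty(m + 1, dtype=np.int32)
        V[0] = i
        np.minimum(row[1:] + 1, row[:-1] + (q[i - 1] != t).astype(np.int32), out=V[1:])
        row = np.minimum.accumulate(V - j_idx) + j_idx
    return int(row.min())


def naive_kmer_scan(sequences: dict[str, str], kmer: str) -> list[tuple[str, int]]:
    hits = []
    for name, seq in sequences.items():
        start = 0
        while True:
            p = seq.find(kmer, start)
            if p < 0:
                break
            hits.append((name, p))
            start = p + 1
    return hits


def exhaustive_splice_scan(
    q: str,
    contig_seq: str,
    d_left: int,
    d_right: int,
    *,
    max_errors: int,
    min_intron: int,
    max_intron: int,
    min_anchor: int,
    motif_guidance: bool = True,
):
    """Try every breakpoint and every intron-end slack; return the best.

    The left exon block starts at ``d_left`` (the left hotspot diagonal),
    the right block ends at ``d_right + len(q)``.  Returns
    ``(cost, donor, acceptor, rank)`` of the optimum under the ordering
    (cost, motif rank, donor, acceptor) or None if nothing fits within
    ``max_errors``.  Uses edlib for the per-side distances.
    """
    import edlib

    L = len(q)
    E = max_errors
    best = None
    for b in range(min_anchor, L - min_anchor + 1):
        for s1 in range(-E, E + 1):
            donor = d_left + b + s1
            if donor <= d_left or donor + 2 > len(contig_seq):
                continue
            left = edlib.align(q[:b], contig_seq[d_left:donor], mode="NW", task="distance")
            lc = left["editDistance"]
            if lc < 0 or lc > E:
                continue
            for s2 in range(-E, E + 1):
                acceptor = d_right + b + s2
                if acceptor - 2 < 0 or acceptor >= d_right + L:
                    continue
                ilen = acceptor - donor
                if not (min_intron <= ilen <= max_intron):
                    continue
                right = edlib.align(
                    q[b:], contig_seq[acceptor : d_right + L], mode="NW", task="distance"
                )
                rc = right["editDistance"]
                if rc < 0:
                    continue
                cost = lc + rc
                if cost > E:
                    continue
                dinuc = (contig_seq[donor : donor + 2], contig_seq[acceptor - 2 : acceptor])
                rank = _ORACLE_MOTIFS.get(dinuc, 3)
                key = (cost, rank if motif_guidance else 0, donor, acceptor)
                if best is None or key < best[0]:
                    best = (key, cost, donor, acceptor, rank)
    if best is None:
        return None
    return best[1], best[2], best[3], best[4]
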