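"""Mapper parameters shared across the unspliced and spliced stages."""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class MapperConfig:
    """Parameters of the seed-and-extend mapper.

    Attributes
    ----------
    max_errors : int
        ``E`` — maximum edit operations (mismatches + inserted + deleted
        bases) tolerated in one alignment.  Default 5, suited to
        indel-prone single-end platforms.
    seed_length : int
        ``S`` — length in nt of the exact-match seeds a read is split
        into.  Default 14.
    min_intron : int
        ``N`` — shortest intron the spliced stage may call.  Default 50.
    max_intron : int
        ``X`` — longest intron the spliced stage may call.  Default 500000.
    occurrence_cap : int
        k-mers occurring more often than this in the reference are kept in
        the index but ignored when generating hotspots (repeat guard).
    score_margin : int
        A second-best alignment within this many errors of the best makes
        the read non-unique.  0 means only exact ties void uniqueness.
    min_anchor : int
        Shortest exonic block (in read bases) allowed on either side of a
        called splice junction.  Defaults to the seed length.
    adjacency_slack : int
        Maximum read-offset gap (nt) between seed matches on one diagonal
        that are still merged into a single hotspot.  ``2*S`` tolerates one
        error-destroyed seed between two surviving ones.
    motif_guidance : bool
        When True, breakpoints whose induced intron bears a canonical
        signal (GT-AG > GC-AG > AT-AC) are preferred among equal-error
        placements.
    canonical_only : bool
        When True, spliced alignments whose intron is non-canonical are
        rejected outright.
    max_pairs : int
        Hotspot pairs examined per read, in descending score order.
    """

    max_errors: int = 5
    seed_length: int = 14
    min_intron: int = 50
    max_intron: int = 500_000
    occurrence_cap: int = 1000
    score_margin: int = 0
    min_anchor: int | None = None
    adjacency_slack: int | None = None
    motif_guidance: bool = True
    canonical_only: bool = False
    max_pairs: int = 50

    def __post_init__(self) -> None:
        if self.max_errors < 0:
            raise ValueError("max_errors must be >= 0")
        if self.seed_length < 8:
            raise ValueError("seed_length must be >= 8")
        if not (0 < self.min_intron < self.max_intron):
            raise ValueError("need 0 < min_intron < max_intron")
        if self.min_anchor is None:
            self.min_anchor = self.seed_length
        if self.adjacency_slack is None:
            self.adjacency_slack = 2 * self.seed_length

    @property
    def min_read_length(self) -> int:
        """Default retention threshold: three seed lengths (42 nt at S=14)."""
        return 3 * self.seed_length
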