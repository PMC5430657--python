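"""Read retention by length and 5' base quality.

A read is kept iff it is strictly longer than ``min_len`` nt and every base
within the first ``window`` bases has Phred quality strictly above
``min_phred``.  The default ``min_len`` is three seed lengths (42 nt at
S=14), and the default window equals ``min_len``: a noisy single-end
platform tends to concentrate low-quality calls at the 5' end, and a read
whose first three seeds are unreliable cannot anchor the seed mapper.
Reads without qualities (FASTA input) pass the quality test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from seedsplice.formats_io import Read


@dataclass
class FilterReport:
    total_in: int = 0
    kept: int = 0
    dropped_short: int = 0
    dropped_quality: int = 0

    def __post_init__(self) -> None:
        self._check()

    def _check(self) -> None:
        assert self.total_in == self.kept + self.dropped_short + self.dropped_quality


def filter_reads(
    reads: Iterable[Read],
    min_len: int = 42,
    min_phred: int = 10,
    window: int | None = None,
) -> tuple[list[Read], FilterReport]:
    """Apply the retention rule; returns kept reads and a tally.

    Length is tested first: a short read counts as ``dropped_short`` even if
    it would also fail on quality.
    """
    if window is None:
        window = min_len
    kept: list[Read] = []
    report = FilterReport()
    for read in reads:
        report.total_in += 1
        if len(read) <= min_len:
            report.dropped_short += 1
            continue
        if read.qualities is not None and any(
            q <= min_phred for q in read.qualities[:window]
        ):
            report.dropped_quality += 1
            continue
        report.kept += 1
        kept.append(read)
    report._check()
    return kept, report
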