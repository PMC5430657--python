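"""Small DNA helpers used throughout the package."""

from __future__ import annotations

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def gc_fraction(seq: str) -> float:
    """Fraction of G/C over A/C/G/T bases (N ignored); 0.0 for empty input."""
    acgt = sum(seq.count(b) for b in "ACGT")
    if acgt == 0:
        return 0.0
    return (seq.count("G") + seq.count("C")) / acgt
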