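"""Sequence records and nucleotide helpers shared by all stages.

T and U are treated as the same base throughout: small-RNA libraries are
RNA sequenced as cDNA, so inputs may use either alphabet. Sequences are
normalised to upper case at parse time; U is preserved as written but all
comparisons go through :func:`dna`.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

_COMPLEMENT = str.maketrans("ACGTUN", "TGCAAN")


@dataclass
class SequenceRecord:
    """One named nucleotide sequence, optionally with per-base qualities."""

    id: str
    seq: str
    qual: Optional[str] = None

    def __post_init__(self) -> None:
        if len(self.seq) < 1:
            raise ValueError(f"record {self.id!r}: empty sequence")
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise ValueError(
                f"record {self.id!r}: quality length {len(self.qual)} != "
                f"sequence length {len(self.seq)}"
            )


def dna(seq: str) -> str:
    """Normalise to the DNA alphabet (U -> T), upper case."""
    return seq.upper().replace("U", "T")


def revcomp(seq: str) -> str:
    """Reverse complement (DNA output regardless of input alphabet)."""
    return dna(seq).translate(_COMPLEMENT)[::-1]
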