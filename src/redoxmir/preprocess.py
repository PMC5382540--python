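"""Read preprocessing and exact genome placement.

Adapter trimming, size/contaminant filtering, collapsing to unique reads
with per-library counts, and exact full-length placement of unique reads
on the genome. Exact (0-mismatch) matching is deliberate: on same-genome
data it is lossless, dependency-free and checkable against a naive scan;
pre-computed SAM alignments are the entry point for real cross-species
data.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Tuple

from .sequences import SequenceRecord, dna, revcomp

logger = logging.getLogger(__name__)


@dataclass
class UniqueRead:
    """A distinct trimmed read sequence with one count per library."""

    seq: str
    counts: List[int]

    @property
    def total(self) -> int:
        return sum(self.counts)


@dataclass
class AlignmentRecord:
    """A unique read placed on the genome (0-based half-open interval)."""

    read: UniqueRead
    chrom: str
    start: int
    end: int
    strand: str  # "+" or "-"
    n_placements: int = 1

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.read.seq):
            raise ValueError("alignment interval length != read length")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")


def trim_adapter(seq: str, adapter: str, min_overlap: int = 8) -> Tuple[str, bool]:
    """Remove the 3' adapter from a read.

    The leftmost position where either the full adapter occurs, or a
    suffix of the read of length >= ``min_overlap`` equals a prefix of
    the adapter, marks the insert end; everything from there on is cut.
    Reads without such a match are returned unchanged and flagged
    untrimmed.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    s = dna(seq)
    a = dna(adapter)
    n, la = len(s), len(a)
    for i in range(n):
        tail = s[i:]
        if len(tail) >= la:
            if tail.startswith(a):
                return seq[:i], True
        elif len(tail) >= min_overlap and a.startswith(tail):
            return seq[:i], True
    return seq, False


def drop_n_reads(records: Sequence[SequenceRecord]) -> Tuple[List[SequenceRecord], int]:
    """Drop reads containing N (they break complementarity scoring)."""
    kept = [r for r in records if "N" not in r.seq.upper()]
    n_dropped = len(records) - len(kept)
    if n_dropped:
        logger.info("dropped %d reads containing N", n_dropped)
    return kept, n_dropped


def filter_reads(
    reads: Sequence[str],
    len_min: int,
    len_max: int,
    contaminants: Sequence[SequenceRecord] = (),
) -> Tuple[List[str], Dict[str, int]]:
    """Length filter then exact-substring contaminant filter.

    A read is a contaminant hit when it occurs verbatim (either strand)
    inside any contaminant sequence. Tallies are reported in application
    order so that input = kept + sum(drops).
    """
    tallies = {"length": 0, "contaminant": 0}
    cont_fwd = [dna(c.seq) for c in contaminants]
    kept: List[str] = []
    for seq in reads:
        s = dna(seq)
        if not (len_min <= len(s) <= len_max):
            tallies["length"] += 1
            continue
        rc = revcomp(s)
        if any(s in c or rc in c for c in cont_fwd):
            tallies["contaminant"] += 1
            continue
        kept.append(seq)
    return kept, tallies


def collapse_unique(
    tagged_reads: Iterable[Tuple[str, int]], n_libraries: int
) -> List[UniqueRead]:
    """Collapse (sequence, library index) occurrences into unique reads.

    Output is sorted by total count descending, ties broken by sequence
    lexicographically, which fixes the downstream clustering order.
    """
    counts: Dict[str, List[int]] = {}
    for seq, lib in tagged_reads:
        if not (0 <= lib < n_libraries):
            raise ValueError(f"library index {lib} out of range")
        s = dna(seq)
        if s not in counts:
            counts[s] = [0] * n_libraries
        counts[s][lib] += 1
    uniq = [UniqueRead(seq=s, counts=c) for s, c in counts.items()]
    uniq.sort(key=lambda u: (-u.total, u.seq))
    return uniq


def map_exact(
    unique_reads: Sequence[UniqueRead],
    genome: Sequence[SequenceRecord],
    k: int = 18,
) -> Tuple[List[AlignmentRecord], int]:
    """Every exact, ungapped, full-length placement on both strands.

    A k-mer table over the genome (k = minimum read length) seeds the
    search; each seed hit is verified over the full read. Minus-strand
    placements store the genome-forward interval with strand "-".
    Returns (alignments, number of unplaced reads).
    """
    index: Dict[str, List[Tuple[str, int]]] = {}
    seqs = {g.id: dna(g.seq) for g in genome}
    for chrom, s in seqs.items():
        for i in range(len(s) - k + 1):
            index.setdefault(s[i : i + k], []).append((chrom, i))

    alignments: List[AlignmentRecord] = []
    n_unplaced = 0
    for ur in unique_reads:
        s = dna(ur.seq)
        if len(s) < k:
            n_unplaced += 1
            continue
        placements: List[Tuple[str, int, str]] = []
        for chrom, i in index.get(s[:k], ()):  # forward strand
            if seqs[chrom][i : i + len(s)] == s:
                placements.append((chrom, i, "+"))
        rc = revcomp(s)
        for chrom, i in index.get(rc[:k], ()):  # minus strand
            if seqs[chrom][i : i + len(rc)] == rc:
                placements.append((chrom, i, "-"))
        if not placements:
            n_unplaced += 1
            continue
        for chrom, i, strand in placements:
            alignments.append(
                AlignmentRecord(
                    read=ur,
                    chrom=chrom,
                    start=i,
                    end=i + len(s),
                    strand=strand,
                    n_placements=len(placements),
                )
            )
    if n_unplaced:
        logger.info("%d unique reads had no exact genome placement", n_unplaced)
    return alignments, n_unplaced
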