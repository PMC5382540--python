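"""Greedy positional read clustering and hairpin-candidate pairing.

The clustering is a single greedy pass over alignments sorted by read
abundance: the most frequent read founds the first cluster, whose
coordinates stay those of that founding read; every later read joins the
first existing same-strand cluster whose isomiR window (3 nt upstream /
5 nt downstream of the founder, in strand orientation) fully contains
it, else it founds a new cluster. Bona fide miRNA precursors then show
up as two same-strand clusters — the mature and star arms — separated
by less than 150 nt, which is the pairing rule.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .preprocess import AlignmentRecord

logger = logging.getLogger(__name__)


@dataclass
class ReadCluster:
    """A positional cluster of aligned reads.

    ``start``/``end`` are the founder's coordinates (the cluster keeps
    the coordinates of its most frequent read); the window extends them
    by the isomiR flanks in strand orientation.
    """

    chrom: str
    start: int
    end: int
    strand: str
    window_start: int
    window_end: int
    founder: AlignmentRecord
    members: List[AlignmentRecord] = field(default_factory=list)

    @property
    def total_count(self) -> int:
        return sum(m.read.total for m in self.members)

    def counts_per_library(self, n_libraries: int) -> List[int]:
        out = [0] * n_libraries
        for m in self.members:
            for i, c in enumerate(m.read.counts):
                out[i] += c
        return out


@dataclass
class HairpinCandidate:
    """Two same-strand read clusters < max_pair_gap apart: a putative
    pre-miRNA with the higher-count arm as the mature miRNA."""

    id: str
    arm_a: ReadCluster  # genomically left
    arm_b: ReadCluster  # genomically right
    gap: int
    mature: str
    star: str
    strand: str
    multi_mapped: bool = False

    @property
    def chrom(self) -> str:
        return self.arm_a.chrom

    @property
    def mature_cluster(self) -> ReadCluster:
        return self.arm_a if self.arm_a.total_count >= self.arm_b.total_count else self.arm_b

    @property
    def star_cluster(self) -> ReadCluster:
        return self.arm_b if self.arm_a.total_count >= self.arm_b.total_count else self.arm_a

    @property
    def precursor_start(self) -> int:
        return min(self.arm_a.window_start, self.arm_a.start)

    @property
    def precursor_end(self) -> int:
        return max(self.arm_b.window_end, self.arm_b.end)


def _window(start: int, end: int, strand: str, up: int, down: int) -> Tuple[int, int]:
    """IsomiR window around an interval, flanks applied 5'->3'."""
    if strand == "+":
        return start - up, end + down
    return start - down, end + up


def cluster_reads(
    alignments: Sequence[AlignmentRecord],
    up_flank: int = 3,
    down_flank: int = 5,
) -> List[ReadCluster]:
    """The greedy clustering pass.

    Sort order is total read count descending with a full deterministic
    tie-break (chrom, start, strand, sequence), so equal-count reads
    cluster identically regardless of input order. Each alignment joins
    the first cluster, in creation order, that is on its chromosome and
    strand and whose window fully contains its interval.
    """
    if up_flank < 0 or down_flank < 0:
        raise ValueError("flanks must be >= 0")
    order = sorted(
        alignments,
        key=lambda a: (-a.read.total, a.chrom, a.start, a.strand, a.read.seq),
    )
    clusters: List[ReadCluster] = []
    by_key: Dict[Tuple[str, str], List[ReadCluster]] = {}
    for a in order:
        placed = False
        for cl in by_key.get((a.chrom, a.strand), ()):  # creation order
            if cl.window_start <= a.start and a.end <= cl.window_end:
                cl.members.append(a)
                placed = True
                break
        if not placed:
            ws, we = _window(a.start, a.end, a.strand, up_flank, down_flank)
            cl = ReadCluster(
                chrom=a.chrom, start=a.start, end=a.end, strand=a.strand,
                window_start=ws, window_end=we, founder=a, members=[a],
            )
            clusters.append(cl)
            by_key.setdefault((a.chrom, a.strand), []).append(cl)
    return clusters


def pair_clusters(
    clusters: Sequence[ReadCluster],
    max_pair_gap: int = 150,
) -> List[HairpinCandidate]:
    """Pair same-strand clusters whose gap is in [0, max_pair_gap).

    The gap is edge-to-edge between founder coordinates
    (downstream.start - upstream.end). Each cluster joins at most one
    candidate: eligible pairs are taken greedily by smallest gap, ties
    resolved toward the genomically left pair. Overlapping clusters
    (gap < 0) are never paired.
    """
    pairs: List[Tuple[int, int, int, int, int]] = []  # (gap, a.start, b.start, ia, ib)
    n_overlap = 0
    for ia in range(len(clusters)):
        for ib in range(len(clusters)):
            if ia == ib:
                continue
            a, b = clusters[ia], clusters[ib]
            if a.chrom != b.chrom or a.strand != b.strand or a.start > b.start:
                continue
            if a.start == b.start and ia > ib:
                continue
            gap = b.start - a.end
            if gap < 0:
                n_overlap += 1
                continue
            if gap < max_pair_gap:
                pairs.append((gap, a.start, b.start, ia, ib))
    if n_overlap:
        logger.info("%d overlapping cluster pairs not paired", n_overlap)

    pairs.sort()
    used: set = set()
    candidates: List[HairpinCandidate] = []
    for gap, _, _, ia, ib in pairs:
        if ia in used or ib in used:
            continue
        used.update((ia, ib))
        a, b = clusters[ia], clusters[ib]
        if a.total_count >= b.total_count:
            mature_cl, star_cl = a, b
        else:
            mature_cl, star_cl = b, a
        candidates.append(
            HairpinCandidate(
                id="", arm_a=a, arm_b=b, gap=gap,
                mature=mature_cl.founder.read.seq,
                star=star_cl.founder.read.seq,
                strand=a.strand,
                multi_mapped=any(
                    m.n_placements > 1 for m in a.members + b.members
                ),
            )
        )
    candidates.sort(key=lambda c: (c.chrom, c.arm_a.start, c.strand))
    for i, c in enumerate(candidates, start=1):
        c.id = f"cand_{i:04d}"
    return candidates


def filter_candidate_length(
    candidates: Sequence[HairpinCandidate],
    len_min: int = 20,
    len_max: int = 24,
) -> Tuple[List[HairpinCandidate], int]:
    """Keep candidates whose mature length is within [len_min, len_max]."""
    kept = [c for c in candidates if len_min <= len(c.mature) <= len_max]
    return kept, len(candidates) - len(kept)


def quantify(candidate: HairpinCandidate, n_libraries: int) -> List[int]:
    """Per-library mature-arm counts: the sum over the mature cluster's
    member reads of their library-wise counts."""
    return candidate.mature_cluster.counts_per_library(n_libraries)
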