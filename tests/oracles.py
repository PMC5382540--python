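"""Independent oracles used by the test suite.

Each oracle is a deliberately naive reimplementation — a literal
transcription, a brute-force enumeration, or an exact combinatorial
formula — kept free of any code path it is used to check.
"""
from __future__ import annotations

from fractions import Fraction
from math import comb, exp, lgamma
from typing import Dict, List, Sequence, Tuple

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def revcomp_naive(s: str) -> str:
    return "".join(_COMP[b] for b in reversed(s.upper().replace("U", "T")))


# ------------------------------------------------ greedy clustering (i)-(v)

def cluster_literal(alignments, up: int = 3, down: int = 5):
    """Literal transcription of the greedy clustering recipe:
    (i) sort reads by count; (ii) most frequent founds cluster 1 with
    its own coordinates; (iii) later reads are tested against the
    window ClusterStart-3 / ClusterEnd+5 on the same strand;
    (iv) joining adds the read to the cluster; (v) else a new cluster
    opens. Returns a list of (founder, [members])."""
    order = sorted(
        alignments,
        key=lambda a: (-a.read.total, a.chrom, a.start, a.strand, a.read.seq),
    )
    clusters: List[Tuple[object, List[object]]] = []
    for a in order:
        joined = False
        for founder, members in clusters:
            if founder.chrom != a.chrom or founder.strand != a.strand:
                continue
            if founder.strand == "+":
                ws, we = founder.start - up, founder.end + down
            else:
                ws, we = founder.start - down, founder.end + up
            if ws <= a.start and a.end <= we:
                members.append(a)
                joined = True
                break
        if not joined:
            clusters.append((a, [a]))
    return clusters


# ------------------------------------------- exhaustive nested structures

_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}


def max_pairs_enum(seq: str, min_loop: int = 3) -> int:
    """Maximum pair count over every nested structure, by interval
    recursion on which partner (if any) the left endpoint takes."""
    s = seq.upper().replace("U", "T")
    cache: Dict[Tuple[int, int], int] = {}

    def go(i: int, j: int) -> int:
        if j - i <= min_loop:
            return 0
        if (i, j) in cache:
            return cache[(i, j)]
        best = go(i + 1, j)  # i unpaired
        for k in range(i + min_loop + 1, j + 1):
            if (s[i], s[k]) in _PAIRS:
                best = max(best, 1 + go(i + 1, k - 1) + go(k + 1, j))
        cache[(i, j)] = best
        return best

    return go(0, len(s) - 1)


# -------------------------------------------------- exact Fisher p-values

def fisher_two_sided_exact(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p for [[a, b], [c, d]] by full hypergeometric
    tail summation: exact rational arithmetic for small tables,
    log-gamma probabilities (with the customary 1+1e-7 inclusion gate)
    for large ones."""
    n = a + b + c + d
    r1, c1 = a + b, a + c
    if n <= 5000:
        denom = comb(n, c1)

        def pmf(x: int) -> Fraction:
            if x < 0 or x > r1 or c1 - x > n - r1:
                return Fraction(0)
            return Fraction(comb(r1, x) * comb(n - r1, c1 - x), denom)

        p_obs = pmf(a)
        total = Fraction(0)
        for x in range(0, min(r1, c1) + 1):
            px = pmf(x)
            if px <= p_obs:
                total += px
        return float(min(total, Fraction(1)))

    def log_pmf(x: int) -> float:
        return (
            lgamma(r1 + 1) - lgamma(x + 1) - lgamma(r1 - x + 1)
            + lgamma(n - r1 + 1) - lgamma(c1 - x + 1) - lgamma(n - r1 - c1 + x + 1)
            - (lgamma(n + 1) - lgamma(c1 + 1) - lgamma(n - c1 + 1))
        )

    lo = max(0, c1 - (n - r1))
    hi = min(r1, c1)
    lp_obs = log_pmf(a)
    total = 0.0
    for x in range(lo, hi + 1):
        lp = log_pmf(x)
        if lp <= lp_obs + 1e-7:
            total += exp(lp)
    return min(total, 1.0)


def fisher_greater_exact(a: int, b: int, c: int, d: int) -> float:
    """One-sided (enrichment) Fisher p by upper tail summation."""
    n = a + b + c + d
    r1, c1 = a + b, a + c
    denom = comb(n, c1)
    total = Fraction(0)
    for x in range(a, min(r1, c1) + 1):
        if c1 - x <= n - r1:
            total += Fraction(comb(r1, x) * comb(n - r1, c1 - x), denom)
    return float(min(total, Fraction(1)))


# ---------------------------------------------------- naive exact mapping

def map_naive(read: str, genome: Dict[str, str]) -> List[Tuple[str, int, int, str]]:
    """All exact placements of a read by scanning every offset."""
    out = []
    r = read.upper().replace("U", "T")
    rc = revcomp_naive(r)
    for chrom, s in genome.items():
        s = s.upper()
        for i in range(len(s) - len(r) + 1):
            if s[i : i + len(r)] == r:
                out.append((chrom, i, i + len(r), "+"))
            if s[i : i + len(rc)] == rc:
                out.append((chrom, i, i + len(rc), "-"))
    return out


# ------------------------------------------- exhaustive duplex alignment

def min_expectation_enum(mirna: str, window: str, hspsize: int = 20) -> float:
    """Minimum expectation over all antiparallel alignments with at
    most one gap, by direct enumeration of the gap position."""
    m = mirna.upper().replace("U", "T")
    r = revcomp_naive(window)

    def pen(state: str, pos: int) -> float:
        if pos > hspsize:
            return 0.0
        base = {"match": 0.0, "wobble": 0.5, "mismatch": 1.0, "gap": 2.0}[state]
        return base * 2 if 2 <= pos <= 13 else base

    def pair_state(mb: str, rb: str) -> str:
        if mb == rb:
            return "match"
        if (mb == "G" and rb == "A") or (mb == "T" and rb == "C"):
            return "wobble"
        return "mismatch"

    scores = []
    L, lr = len(m), len(r)
    if L == lr:  # no gap
        scores.append(sum(pen(pair_state(m[i], r[i]), i + 1) for i in range(L)))
    if lr == L - 1:  # one miRNA base bulged at position g
        for g in range(L):
            sc = pen("gap", g + 1)
            for i in range(L):
                if i == g:
                    continue
                j = i if i < g else i - 1
                sc += pen(pair_state(m[i], r[j]), i + 1)
            scores.append(sc)
    if lr == L + 1:  # one target base bulged after miRNA position g
        for g in range(lr):
            sc = pen("gap", max(g, 1))
            for j in range(lr):
                if j == g:
                    continue
                i = j if j < g else j - 1
                sc += pen(pair_state(m[i], r[j]), i + 1)
            scores.append(sc)
    return round(min(scores), 1) if scores else float("inf")
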