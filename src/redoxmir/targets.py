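"""Plant miRNA target-site scanning with an expectation score.

A target site is scored by aligning the miRNA (5'->3') against the
reverse-complement orientation of a transcript window and summing
per-position penalties: match 0, G:U wobble 0.5, mismatch 1.0, gap 2.0,
all doubled inside the seed-proximal region (miRNA positions 2-13).
Only the first ``hspsize`` (20) miRNA positions are scored. 0 means
perfect complementarity; sites above the expectation cutoff (2.0) are
rejected. A mismatch or gap at miRNA positions 9-11 marks the site as
translational inhibition rather than cleavage.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .sequences import dna, revcomp

MATCH, WOBBLE, MISMATCH, GAP_M, GAP_T = "match", "wobble", "mismatch", "gap_m", "gap_t"
_BASE_PENALTY = {MATCH: 0.0, WOBBLE: 0.5, MISMATCH: 1.0, GAP_M: 2.0, GAP_T: 2.0}
SEED_RANGE = (2, 13)  # penalty-doubled miRNA positions, inclusive


def _pair_state(m: str, r: str) -> str:
    """State of miRNA base ``m`` against ``r`` = complement of the
    target base it faces (so WC pairing reads as equality)."""
    if m == r:
        return MATCH
    if (m == "G" and r == "A") or (m == "T" and r == "C"):
        return WOBBLE  # G:U wobble in complement space
    return MISMATCH


def position_penalty(state: str, pos: int, hspsize: int = 20) -> float:
    if pos > hspsize:
        return 0.0
    p = _BASE_PENALTY[state]
    if SEED_RANGE[0] <= pos <= SEED_RANGE[1]:
        p *= 2.0
    return p


@dataclass
class DuplexAlignment:
    """miRNA:target duplex; states indexed by miRNA position (1-based
    from the miRNA 5' end; target-bulge gaps carry the position of the
    preceding miRNA base, floored at 1)."""

    mirna_seq: str
    site_seq: str  # target site, transcript orientation 5'->3'
    states: List[Tuple[int, str]]


@dataclass
class TargetSite:
    mirna_id: str
    transcript_id: str
    site_start: int  # 0-based half-open on the transcript
    site_end: int
    expectation: float
    mode: str  # cleavage | translational
    flank_up_seq: str = ""
    flank_down_seq: str = ""
    duplex: Optional[DuplexAlignment] = None


def expectation_score(duplex: DuplexAlignment, hspsize: int = 20) -> float:
    """Penalty sum of the duplex, reported to 1 decimal."""
    return round(
        sum(position_penalty(s, pos, hspsize) for pos, s in duplex.states), 1
    )


def classify_inhibition(
    duplex: DuplexAlignment, central_range: Tuple[int, int] = (9, 11)
) -> str:
    lo, hi = central_range
    for pos, s in duplex.states:
        if s in (MISMATCH, GAP_M, GAP_T) and lo <= pos <= hi:
            return "translational"
    return "cleavage"


def align_duplex(
    mirna: str,
    window: str,
    hspsize: int = 20,
    band: int = 2,
    max_gaps: int = 1,
) -> DuplexAlignment:
    """Minimum-expectation banded alignment of miRNA vs one window.

    The window is the candidate site in transcript orientation; it is
    reverse-complemented so Watson-Crick pairing reads as equality.
    Both sequences are consumed entirely; at most ``max_gaps`` gaps
    (one more if the length difference demands it), band +-``band``.
    Traceback is deterministic with preference match > wobble >
    mismatch > gap.
    """
    m = dna(mirna)
    r = revcomp(window)  # r[0] faces miRNA position 1
    L, lr = len(m), len(r)
    if not (L - band <= lr <= L + band):
        raise ValueError(f"window length {lr} outside band of miRNA length {L}")
    max_gaps = max(max_gaps, abs(lr - L))

    INF = float("inf")
    # dp[g][i][j]: min score, i miRNA bases and j window bases consumed, g gaps
    dp = np.full((max_gaps + 1, L + 1, lr + 1), INF)
    dp[0][0][0] = 0.0
    for i in range(L + 1):
        for j in range(max(0, i - band), min(lr, i + band) + 1):
            for g in range(max_gaps + 1):
                cur = dp[g][i][j]
                if cur == INF:
                    continue
                if i < L and j < lr:
                    st = _pair_state(m[i], r[j])
                    pen = position_penalty(st, i + 1, hspsize)
                    if cur + pen < dp[g][i + 1][j + 1]:
                        dp[g][i + 1][j + 1] = cur + pen
                if g < max_gaps:
                    if i < L:  # miRNA base bulged (gap in target)
                        pen = position_penalty(GAP_T, i + 1, hspsize)
                        if cur + pen < dp[g + 1][i + 1][j]:
                            dp[g + 1][i + 1][j] = cur + pen
                    if j < lr:  # target base bulged (gap in miRNA)
                        pen = position_penalty(GAP_M, max(i, 1), hspsize)
                        if cur + pen < dp[g + 1][i][j + 1]:
                            dp[g + 1][i][j + 1] = cur + pen

    best_g = int(np.argmin(dp[:, L, lr]))
    # deterministic traceback from (best_g, L, lr)
    states: List[Tuple[int, str]] = []
    i, j, g = L, lr, best_g
    while i > 0 or j > 0:
        cur = dp[g][i][j]
        moved = False
        # preference: match/wobble/mismatch (diagonal) before gaps
        if i > 0 and j > 0:
            st = _pair_state(m[i - 1], r[j - 1])
            pen = position_penalty(st, i, hspsize)
            if dp[g][i - 1][j - 1] + pen == cur:
                states.append((i, st))
                i, j = i - 1, j - 1
                moved = True
        if not moved and g > 0 and i > 0:
            pen = position_penalty(GAP_T, i, hspsize)
            if dp[g - 1][i - 1][j] + pen == cur:
                states.append((i, GAP_T))
                i, g = i - 1, g - 1
                moved = True
        if not moved and g > 0 and j > 0:
            pen = position_penalty(GAP_M, max(i, 1), hspsize)
            if dp[g - 1][i][j - 1] + pen == cur:
                states.append((max(i, 1), GAP_M))
                j, g = j - 1, g - 1
                moved = True
        if not moved:  # numerically unreachable; guards infinite loops
            raise RuntimeError("duplex traceback failed")
    states.reverse()
    return DuplexAlignment(mirna_seq=mirna, site_seq=window, states=states)


def _gapless_match_counts(m_arr: np.ndarray, r_arr: np.ndarray) -> np.ndarray:
    """Matches of the scored miRNA prefix against every offset of the
    reverse-complemented transcript (vectorised prefilter)."""
    ls, n = len(m_arr), len(r_arr)
    if n < ls:
        return np.zeros(0, dtype=int)
    windows = np.lib.stride_tricks.sliding_window_view(r_arr, ls)
    return (windows == m_arr).sum(axis=1)


def scan_transcript(
    mirna: str,
    transcript_id: str,
    transcript: str,
    max_expectation: float = 2.0,
    hspsize: int = 20,
    flank_up: int = 17,
    flank_down: int = 13,
    central_range: Tuple[int, int] = (9, 11),
    mirna_id: str = "",
) -> List[TargetSite]:
    """All target sites on one transcript with expectation <= cutoff.

    A vectorised complementarity prefilter nominates positions (single
    offsets with few gapless defects, or adjacent-offset pairs whose
    joint matches indicate a one-base bulge); each nominee is aligned
    at window lengths L-1, L, L+1 and the best-scoring placement per
    locus kept. Overlapping sites are merged keeping the lower
    expectation; output sorted by (expectation, position).
    """
    t = dna(transcript)
    m = dna(mirna)
    L = len(m)
    if len(t) < L:
        return []
    ls = min(L, hspsize)
    R = revcomp(t)
    n = len(t)
    m_arr = np.frombuffer(m[:ls].encode(), dtype=np.uint8)
    r_arr = np.frombuffer(R.encode(), dtype=np.uint8)
    D = _gapless_match_counts(m_arr, r_arr)
    if len(D) == 0:
        return []
    cand = set(np.nonzero(D >= ls - 6)[0].tolist())
    joint = D[:-1] + D[1:]
    for p in np.nonzero(joint >= ls - 3)[0].tolist():
        cand.update((p, p + 1))

    raw_sites: List[TargetSite] = []
    for p in sorted(cand):
        # R-offset p means the site ends at transcript position n - p
        site_end = n - p
        best: Optional[TargetSite] = None
        for wl in (L, L - 1, L + 1):  # gapless full-length window first; ties keep it
            s0 = site_end - wl
            if s0 < 0 or site_end > n or wl < 1:
                continue
            window = t[s0:site_end]
            dup = align_duplex(m, window, hspsize=hspsize)
            exp = expectation_score(dup, hspsize=hspsize)
            if exp > max_expectation:
                continue
            if best is None or exp < best.expectation:
                best = TargetSite(
                    mirna_id=mirna_id, transcript_id=transcript_id,
                    site_start=s0, site_end=site_end, expectation=exp,
                    mode=classify_inhibition(dup, central_range),
                    flank_up_seq=t[max(0, s0 - flank_up) : s0],
                    flank_down_seq=t[site_end : site_end + flank_down],
                    duplex=dup,
                )
        if best is not None:
            raw_sites.append(best)

    # merge overlapping sites, keeping the lower expectation
    raw_sites.sort(key=lambda s: (s.expectation, s.site_start))
    kept: List[TargetSite] = []
    for s in raw_sites:
        if any(
            s.site_start < k.site_end and k.site_start < s.site_end for k in kept
        ):
            continue
        kept.append(s)
    kept.sort(key=lambda s: (s.expectation, s.site_start))
    return kept


def scan_transcriptome(
    mirna_id: str,
    mirna: str,
    transcripts: Dict[str, str],
    max_expectation: float = 2.0,
    max_sites: int = 200,
    **kwargs,
) -> List[TargetSite]:
    """Scan every transcript; keep at most ``max_sites`` best sites."""
    sites: List[TargetSite] = []
    for tid in sorted(transcripts):
        sites.extend(
            scan_transcript(
                mirna, tid, transcripts[tid],
                max_expectation=max_expectation, mirna_id=mirna_id, **kwargs,
            )
        )
    sites.sort(key=lambda s: (s.expectation, s.transcript_id, s.site_start))
    return sites[:max_sites]
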