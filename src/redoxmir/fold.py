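"""Secondary-structure screen for candidate precursors.

A Nussinov base-pair-maximization fold (Watson-Crick + G:U, hairpin
loop >= 3) stands in for a thermodynamic fold: the pipeline uses
structure only as a pass/fail plausibility screen, for which maximal
pairing discriminates planted/real hairpins from background sequence.
Externally computed dot-bracket strings can be supplied instead via
:func:`pairs_from_dotbracket`.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

from .sequences import dna

_CAN_PAIR = {
    ("A", "T"), ("T", "A"),
    ("G", "C"), ("C", "G"),
    ("G", "T"), ("T", "G"),  # G:U wobble, standard in miRNA stems
}


def can_pair(x: str, y: str) -> bool:
    return (x, y) in _CAN_PAIR


@dataclass
class FoldResult:
    seq: str
    structure: str
    pairs: List[Tuple[int, int]]
    n_pairs: int


def fold_maxpair(seq: str, min_loop: int = 3) -> FoldResult:
    """Maximize the number of nested base pairs with loop >= min_loop.

    Dynamic program over intervals; traceback is deterministic, pairing
    position i with the largest admissible partner j whenever pairing
    attains the optimum.
    """
    s = dna(seq)
    n = len(s)
    if not (1 <= n <= 500):
        raise ValueError("sequence length must be in [1, 500]")

    # N[i][j] = max pairs in s[i..j]; partners[i][j] = admissible ks for j
    N = [[0] * n for _ in range(n)]
    pairable = [[can_pair(s[i], s[j]) for j in range(n)] for i in range(n)]

    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            best = N[i][j - 1]  # j unpaired
            row = N[i]
            for k in range(i, j - min_loop):
                if pairable[k][j]:
                    inner = N[k + 1][j - 1] if k + 1 <= j - 1 else 0
                    left = row[k - 1] if k > i else 0
                    v = left + inner + 1
                    if v > best:
                        best = v
            N[i][j] = best

    pairs: List[Tuple[int, int]] = []

    def trace(i: int, j: int) -> None:
        while i < j:
            target = N[i][j]
            # pairing preferred over leaving j unpaired; among partners
            # the widest-span admissible one wins, which favours the
            # arm-to-arm stem over narrow loop-proximal alternatives
            found = False
            for k in range(i, j - min_loop):
                if pairable[k][j]:
                    inner = N[k + 1][j - 1] if k + 1 <= j - 1 else 0
                    left = N[i][k - 1] if k > i else 0
                    if left + inner + 1 == target:
                        pairs.append((k, j))
                        if k + 1 <= j - 1:
                            trace(k + 1, j - 1)
                        j = k - 1
                        found = True
                        break
            if not found:
                j -= 1

    if n > min_loop + 1:
        trace(0, n - 1)
    pairs.sort()
    struct = ["."] * n
    for i, j in pairs:
        struct[i], struct[j] = "(", ")"
    return FoldResult(seq=seq, structure="".join(struct), pairs=pairs, n_pairs=len(pairs))


def pairs_from_dotbracket(seq: str, structure: str) -> FoldResult:
    """Adopt an externally computed structure (e.g. a thermodynamic fold)."""
    if len(seq) != len(structure):
        raise ValueError("structure length != sequence length")
    stack: List[int] = []
    pairs: List[Tuple[int, int]] = []
    for i, ch in enumerate(structure):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise ValueError(f"unbalanced ')' at position {i}")
            pairs.append((stack.pop(), i))
        elif ch != ".":
            raise ValueError(f"bad dot-bracket character {ch!r}")
    if stack:
        raise ValueError("unbalanced '(' in structure")
    pairs.sort()
    return FoldResult(seq=seq, structure=structure, pairs=pairs, n_pairs=len(pairs))


def count_terminal_loops(fold: FoldResult, min_stack: int = 3) -> int:
    """Number of hairpin loops closed by a real helix.

    Only pairs belonging to a stack of at least ``min_stack``
    consecutive pairs count: a base-pair-maximising fold decorates any
    sequence with isolated opportunistic pairs, and a single such pair
    in a flank must not read as a second stem.
    """
    pairset = set(fold.pairs)
    stacked = []
    for (i, j) in fold.pairs:
        run = 1
        a, b = i + 1, j - 1
        while (a, b) in pairset:
            run += 1
            a, b = a + 1, b - 1
        a, b = i - 1, j + 1
        while (a, b) in pairset:
            run += 1
            a, b = a - 1, b + 1
        if run >= min_stack:
            stacked.append((i, j))
    n_loops = 0
    for (i, j) in stacked:
        if not any(i < k and l < j for (k, l) in stacked if (k, l) != (i, j)):
            n_loops += 1
    return n_loops


def hairpin_check(
    mature_rel: Tuple[int, int],
    star_rel: Tuple[int, int],
    fold: FoldResult,
    min_mature_paired_frac: float = 0.8,
) -> Tuple[bool, Dict[str, float]]:
    """Pass/fail structural screen for one candidate precursor.

    ``mature_rel``/``star_rel`` are the mature and star arm intervals
    relative to the folded precursor sequence. Pass requires (a) at
    least ``min_mature_paired_frac`` of mature positions pairing into
    the star-arm half of the precursor (the side of the midline the
    star arm sits on — a real stem sends the mature arm across the
    loop, while opportunistic single pairs into the loop or flanks do
    not count), and (b) exactly one terminal loop, i.e. no second stem.
    """
    m0, m1 = mature_rel
    s0, s1 = star_rel
    partner: Dict[int, int] = {}
    for i, j in fold.pairs:
        partner[i] = j
        partner[j] = i
    mature_pos = range(max(0, m0), min(len(fold.seq), m1))
    n_mature = max(1, len(mature_pos))
    paired = [p for p in mature_pos if p in partner]
    mid = len(fold.seq) / 2
    star_is_left = (s0 + s1) < (m0 + m1)
    if star_is_left:
        into_star = [p for p in paired if partner[p] < mid]
    else:
        into_star = [p for p in paired if partner[p] >= mid]
    frac_paired = len(paired) / n_mature
    frac_star = len(into_star) / n_mature
    n_loops = count_terminal_loops(fold)
    ok = frac_star >= min_mature_paired_frac and n_loops == 1
    metrics = {
        "mature_paired_frac": frac_paired,
        "mature_into_star_frac": frac_star,
        "n_terminal_loops": float(n_loops),
    }
    return ok, metrics
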