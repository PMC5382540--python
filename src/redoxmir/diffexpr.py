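"""Count normalisation and differential-expression calling.

Counts are normalised to CPM; each treatment-vs-control contrast gets a
log2 fold change on mean CPM (pseudocount 0.5) and a two-sided Fisher
exact test on the pooled 2x2 table (candidate counts vs the remainder of
each group's libraries), with Benjamini-Hochberg FDR across candidates.
A candidate is called up/down when |log2FC| >= 1 (i.e. at least a
2-fold change) with raw p < 0.05; the FDR is reported alongside. Fisher
on pooled counts is anti-conservative under biological overdispersion —
the simulator's dispersion knob exists to quantify exactly that.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Dict, FrozenSet, List, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

TREATMENTS = ("control", "NaCl", "NaCl+TU", "TU")


@dataclass
class CountMatrix:
    """Candidate x library counts with a (treatment, replicate) map."""

    counts: pd.DataFrame  # rows: candidate ids, columns: library labels
    library_treatments: Dict[str, str]  # library label -> treatment

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("negative counts")
        sizes = self.counts.sum(axis=0)
        if (sizes == 0).any():
            bad = list(sizes.index[sizes == 0])
            raise ValueError(f"all-zero libraries: {bad}")
        missing = set(self.counts.columns) - set(self.library_treatments)
        if missing:
            raise ValueError(f"libraries without treatment label: {sorted(missing)}")

    def libraries_of(self, treatment: str) -> List[str]:
        return [c for c in self.counts.columns if self.library_treatments[c] == treatment]


@dataclass
class DEResult:
    id: str
    comparison: Tuple[str, str]  # (treatment, reference)
    log2fc: float
    p: float
    fdr: float
    call: str = "ns"  # up | down | ns


def normalize_cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts per million per library; no pseudocount (that is added
    only before logs)."""
    sizes = counts.sum(axis=0)
    if (sizes == 0).any():
        raise ValueError("zero library size")
    return counts / sizes * 1e6


def de_test(cm: CountMatrix, treat: str, ref: str) -> List[DEResult]:
    """Fisher-exact DE for one contrast, BH-corrected across rows."""
    t_libs, r_libs = cm.libraries_of(treat), cm.libraries_of(ref)
    if not t_libs or not r_libs:
        raise ValueError(f"no libraries for contrast {treat} vs {ref}")
    cpm = normalize_cpm(cm.counts)
    mean_t = cpm[t_libs].mean(axis=1)
    mean_r = cpm[r_libs].mean(axis=1)
    log2fc = np.log2(mean_t + 0.5) - np.log2(mean_r + 0.5)

    tot_t = int(cm.counts[t_libs].values.sum())
    tot_r = int(cm.counts[r_libs].values.sum())
    ps = []
    for rid in cm.counts.index:
        a = int(cm.counts.loc[rid, t_libs].sum())
        b = int(cm.counts.loc[rid, r_libs].sum())
        table = [[a, b], [tot_t - a, tot_r - b]]
        ps.append(stats.fisher_exact(table, alternative="two-sided")[1])
    ps_arr = np.minimum(np.asarray(ps), 1.0)
    fdr = stats.false_discovery_control(ps_arr, method="bh")
    return [
        DEResult(
            id=str(rid), comparison=(treat, ref),
            log2fc=float(log2fc.loc[rid]), p=float(p), fdr=float(q),
        )
        for rid, p, q in zip(cm.counts.index, ps_arr, fdr)
    ]


def call_de(
    results: Sequence[DEResult],
    min_abs_log2fc: float = 1.0,
    alpha: float = 0.05,
) -> List[DEResult]:
    """up iff log2FC >= +cutoff and p < alpha; down symmetric; else ns.

    The fold-change threshold is inclusive, the p threshold strict.
    """
    for r in results:
        if r.p < alpha and r.log2fc >= min_abs_log2fc:
            r.call = "up"
        elif r.p < alpha and r.log2fc <= -min_abs_log2fc:
            r.call = "down"
        else:
            r.call = "ns"
    return list(results)


def treatment_specific_sets(
    calls: Dict[str, Sequence[DEResult]],
) -> Dict[FrozenSet[str], Set[str]]:
    """Partition DE ids into the 7 Venn regions of the three contrasts.

    ``calls`` maps treatment label -> called DEResults of that
    treatment vs control; an id is 'in' a treatment when its call is
    not ns.
    """
    treatments = list(calls)
    membership: Dict[str, Set[str]] = {
        t: {r.id for r in rs if r.call != "ns"} for t, rs in calls.items()
    }
    regions: Dict[FrozenSet[str], Set[str]] = {}
    for k in range(1, len(treatments) + 1):
        for combo in combinations(treatments, k):
            inside = set.intersection(*(membership[t] for t in combo))
            outside = set.union(
                set(), *(membership[t] for t in treatments if t not in combo)
            )
            regions[frozenset(combo)] = inside - outside
    return regions


def de_results_frame(results: Sequence[DEResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": [r.id for r in results],
            "treatment": [r.comparison[0] for r in results],
            "reference": [r.comparison[1] for r in results],
            "log2fc": [r.log2fc for r in results],
            "p": [r.p for r in results],
            "fdr": [r.fdr for r in results],
            "call": [r.call for r in results],
        }
    )
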