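"""miRNA:target coupling, key-gene ranking, and term enrichment.

Per-organ expression profiles over the four treatments (control, NaCl,
NaCl+TU, TU) are correlated between each miRNA and its target (Pearson
r over the 4 treatment means): strongly negative r is the canonical
inverse regulation, strongly positive r marks targets decoupled from
miRNA-mediated repression. Targets are then ranked by the expression
difference between NaCl+TU and TU; top-ranked targets also showing at
least a 2-fold difference between NaCl+TU and NaCl are nominated "key
genes" of the redox-mediated salt-tolerance response.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
from scipy import stats

from .diffexpr import TREATMENTS

logger = logging.getLogger(__name__)


@dataclass
class ExpressionProfile:
    """Relative expression (fold over control) across the 4 treatments."""

    entity_id: str
    organ: str  # root | shoot
    values: Tuple[float, float, float, float]  # (control, NaCl, NaCl+TU, TU)

    def __post_init__(self) -> None:
        if len(self.values) != len(TREATMENTS):
            raise ValueError("expected one value per treatment")

    def value(self, treatment: str) -> float:
        return self.values[TREATMENTS.index(treatment)]


@dataclass
class CouplingRecord:
    mirna_id: str
    target_id: str
    r: Optional[float]  # None when a profile has zero variance
    klass: str  # inverse | decoupled | indeterminate


@dataclass
class KeyGeneReport:
    target_id: str
    delta_tu: float  # expression(NaCl+TU) - expression(TU)
    fold_nacl_vs_nacltu: float  # larger/smaller ratio of the two
    rank: int
    key_gene: bool


def pearson_r(x: Sequence[float], y: Sequence[float]) -> Optional[float]:
    """Product-moment correlation; None for degenerate (zero-variance)
    input rather than a number."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return None
    return float(stats.pearsonr(x, y)[0])


def classify_coupling(
    r: Optional[float],
    inverse_max: float = -0.25,
    decoupled_min: float = 0.25,
) -> str:
    if r is None:
        return "indeterminate"
    if r <= inverse_max:
        return "inverse"
    if r >= decoupled_min:
        return "decoupled"
    return "indeterminate"


def couple(
    mirna_profiles: Dict[str, ExpressionProfile],
    target_profiles: Dict[str, ExpressionProfile],
    target_map: Dict[str, str],
    inverse_max: float = -0.25,
    decoupled_min: float = 0.25,
) -> List[CouplingRecord]:
    """Pearson-couple each miRNA with its mapped target."""
    records: List[CouplingRecord] = []
    for mid in sorted(target_map):
        tid = target_map[mid]
        if mid not in mirna_profiles or tid not in target_profiles:
            logger.info("coupling skipped for %s:%s (missing profile)", mid, tid)
            continue
        r = pearson_r(mirna_profiles[mid].values, target_profiles[tid].values)
        records.append(
            CouplingRecord(
                mirna_id=mid, target_id=tid, r=r,
                klass=classify_coupling(r, inverse_max, decoupled_min),
            )
        )
    return records


def rank_targets(
    profiles: Sequence[ExpressionProfile],
    fold_cutoff: float = 2.0,
) -> List[KeyGeneReport]:
    """Rank targets by NaCl+TU minus TU expression, then flag key genes.

    Ranking is on delta_tu descending (ties by id). The key-gene flag
    additionally requires the NaCl+TU vs NaCl expression ratio
    (larger over smaller) to reach ``fold_cutoff`` and delta_tu > 0;
    both quantities are reported so either stage can be audited.
    """
    rows: List[KeyGeneReport] = []
    for p in profiles:
        nacl = p.value("NaCl")
        nacl_tu = p.value("NaCl+TU")
        tu = p.value("TU")
        delta = nacl_tu - tu
        lo, hi = sorted((abs(nacl), abs(nacl_tu)))
        fold = math.inf if lo == 0 and hi > 0 else (hi / lo if lo > 0 else 1.0)
        rows.append(
            KeyGeneReport(
                target_id=p.entity_id, delta_tu=delta,
                fold_nacl_vs_nacltu=fold, rank=0,
                key_gene=bool(fold >= fold_cutoff and delta > 0),
            )
        )
    rows.sort(key=lambda r: (-r.delta_tu, r.target_id))
    for i, r in enumerate(rows, start=1):
        r.rank = i
    return rows


def enrich_terms(
    selected: Set[str],
    universe: Set[str],
    term_map: Dict[str, Set[str]],
    alpha: float = 0.05,
) -> List[Tuple[str, float, float]]:
    """One-sided Fisher enrichment with Bonferroni correction.

    Returns (term, raw p, corrected p) for terms with corrected
    p < alpha, sorted by corrected p then term.
    """
    if not universe:
        raise ValueError("empty universe")
    if not selected <= universe:
        raise ValueError("selected ids must be a subset of the universe")
    terms = sorted({t for i in universe for t in term_map.get(i, ())})
    n_tests = len(terms)
    out: List[Tuple[str, float, float]] = []
    for term in terms:
        with_term = {i for i in universe if term in term_map.get(i, ())}
        a = len(selected & with_term)
        b = len(selected - with_term)
        c = len(with_term - selected)
        d = len(universe - selected - with_term)
        p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")[1]
        p_corr = min(1.0, p * n_tests)
        if p_corr < alpha:
            out.append((term, float(p), float(p_corr)))
    out.sort(key=lambda t: (t[2], t[0]))
    return out


def end_to_end_keygenes(
    de_mirnas: Set[str],
    target_sites: Dict[str, str],
    mirna_profiles: Dict[str, ExpressionProfile],
    target_profiles: Dict[str, ExpressionProfile],
    fold_cutoff: float = 2.0,
    inverse_max: float = -0.25,
    decoupled_min: float = 0.25,
) -> Dict[str, object]:
    """Join DE miRNAs -> targets -> coupling -> ranking for one organ.

    ``target_sites`` maps each DE miRNA id to its best-scoring target
    transcript id. Targets without an expression profile are excluded
    with a log entry. Returns couplings, the full ranking, and the
    key-gene set.
    """
    usable_map = {}
    for mid in sorted(de_mirnas):
        tid = target_sites.get(mid)
        if tid is None:
            continue
        if tid not in target_profiles or mid not in mirna_profiles:
            logger.info("target %s of %s has no expression profile; excluded", tid, mid)
            continue
        usable_map[mid] = tid
    couplings = couple(
        mirna_profiles, target_profiles, usable_map,
        inverse_max=inverse_max, decoupled_min=decoupled_min,
    )
    ranked = rank_targets(
        [target_profiles[t] for t in sorted(set(usable_map.values()))],
        fold_cutoff=fold_cutoff,
    )
    key_genes = {r.target_id for r in ranked if r.key_gene}
    return {"couplings": couplings, "ranking": ranked, "key_genes": key_genes}
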