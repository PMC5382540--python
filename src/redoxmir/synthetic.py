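"""Ground-truth simulator: genomes with planted pre-miRNA hairpins,
treatment-structured small-RNA libraries, and coupled target mRNAs.

The generator emulates the experimental design it is meant to test:
four treatments (control, NaCl, NaCl+TU, TU) with replicated size-
selected small-RNA libraries whose reads come from the two arms of
planted hairpins — the mature arm dominant, the star arm at a fixed
fraction — plus adapter read-through, isomiR end jitter within the
-3/+5 nt clustering window, ncRNA contaminants and random degradation
fragments. Mature lengths are drawn 20-24 nt with mode 23 (then 21,
then 22), matching the size profile of plant small-RNA libraries.
Target transcripts carry a complementary site for each mature miRNA and
an expression profile that is an affine decreasing map of the miRNA's
(inverse coupling, r = -1 noiselessly) or an increasing one
(deliberately decoupled, r = +1).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from .diffexpr import TREATMENTS
from .keygene import ExpressionProfile
from .sequences import SequenceRecord, dna, revcomp

BASES = np.array(list("ACGT"))

# mature-length weights: mode 23, then 21, then 22
_LEN_CHOICES = (20, 21, 22, 23, 24)
_LEN_WEIGHTS = (0.05, 0.25, 0.15, 0.45, 0.10)

# relative miRNA expression patterns (control, NaCl, NaCl+TU, TU);
# the key pattern is down in NaCl+TU and up in TU, so its inversely
# coupled target peaks in NaCl+TU — the key-gene signature
MIRNA_PATTERNS = {
    "key": (1.0, 2.0, 0.2, 2.4),
    "up_nacl": (1.0, 4.0, 2.5, 1.0),
    "down_nacl": (1.0, 0.25, 1.3, 1.0),
    "up_nacl_tu": (1.0, 1.2, 3.0, 1.0),
    "flat": (1.0, 1.0, 1.0, 1.0),
}


@dataclass
class HairpinSpec:
    """One planted pre-miRNA hairpin and where it sits on the genome."""

    id: str
    mature_seq: str
    star_seq: str
    loop_seq: str
    chrom: str
    start: int  # hairpin genome interval start (0-based)
    strand: str
    arm: str  # "5p" | "3p": which arm the mature miRNA comes from

    def __post_init__(self) -> None:
        if not (20 <= len(self.mature_seq) <= 24):
            raise ValueError("mature length must be 20-24 nt")
        if len(self.loop_seq) < 3:
            raise ValueError("loop must be >= 3 nt")

    @property
    def hairpin_seq(self) -> str:
        """5'->3' on the hairpin's own strand."""
        if self.arm == "5p":
            return self.mature_seq + self.loop_seq + self.star_seq
        return self.star_seq + self.loop_seq + self.mature_seq

    @property
    def end(self) -> int:
        return self.start + len(self.hairpin_seq)

    def _arm_interval(self, offset: int, length: int) -> Tuple[int, int]:
        if self.strand == "+":
            return self.start + offset, self.start + offset + length
        n = len(self.hairpin_seq)
        return self.start + n - offset - length, self.start + n - offset

    @property
    def mature_interval(self) -> Tuple[int, int]:
        off = 0 if self.arm == "5p" else len(self.star_seq) + len(self.loop_seq)
        return self._arm_interval(off, len(self.mature_seq))

    @property
    def star_interval(self) -> Tuple[int, int]:
        off = 0 if self.arm == "3p" else len(self.mature_seq) + len(self.loop_seq)
        return self._arm_interval(off, len(self.star_seq))


@dataclass
class TargetPlan:
    transcript_id: str
    site_start: int
    coupling: str  # inverse | decoupled | key
    mode: str  # cleavage | translational


@dataclass
class PlantedTruth:
    hairpins: List[HairpinSpec] = field(default_factory=list)
    target_map: Dict[str, TargetPlan] = field(default_factory=dict)
    key_gene_ids: Set[str] = field(default_factory=set)


@dataclass
class TreatmentProfile:
    """Per-hairpin mean relative expression per treatment, plus the
    negative-binomial dispersion of library counts."""

    replicates: int = 2
    means: Dict[str, Tuple[float, float, float, float]] = field(default_factory=dict)
    dispersion: float = 10.0
    treatments: Tuple[str, ...] = TREATMENTS

    def __post_init__(self) -> None:
        if self.replicates < 2:
            raise ValueError("need >= 2 replicates")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        for hid, m in self.means.items():
            if any(v <= 0 for v in m):
                raise ValueError(f"non-positive mean expression for {hid}")

    @property
    def library_labels(self) -> List[str]:
        return [f"{t}_rep{r + 1}" for t in self.treatments for r in range(self.replicates)]

    def library_treatments(self) -> Dict[str, str]:
        return {f"{t}_rep{r + 1}": t for t in self.treatments for r in range(self.replicates)}


def _random_seq(rng: np.random.Generator, n: int, alphabet: str = "ACGT") -> str:
    return "".join(rng.choice(list(alphabet), size=n))


def _folds_cleanly(hp: "HairpinSpec", chrom_seq: List[str]) -> bool:
    """Certify a hairpin draw in its genomic context: the precursor
    (isomiR windows included) must fold as one stem with >= 90% of
    mature positions pairing into the star half."""
    from .fold import fold_maxpair, hairpin_check

    planted = hp.hairpin_seq if hp.strand == "+" else revcomp(hp.hairpin_seq)
    n = len(planted)
    region = (
        "".join(chrom_seq[max(0, hp.start - 8) : hp.start])
        + planted
        + "".join(chrom_seq[hp.start + n : hp.start + n + 8])
    )
    off = hp.start - min(8, hp.start)  # region start in genome coords
    (a0, a1), (b0, b1) = sorted([hp.mature_interval, hp.star_interval])
    p0, p1 = (a0 - 3, b1 + 5) if hp.strand == "+" else (a0 - 5, b1 + 3)
    seq = region[p0 - off : p1 - off]
    if hp.strand == "-":
        seq = revcomp(seq)

    def rel(s: int, e: int) -> Tuple[int, int]:
        return (s - p0, e - p0) if hp.strand == "+" else (p1 - e, p1 - s)

    fr = fold_maxpair(seq)
    ok, _ = hairpin_check(
        rel(*hp.mature_interval), rel(*hp.star_interval), fr,
        min_mature_paired_frac=0.9,
    )
    return ok


def make_genome(
    n_chrom: int,
    chrom_len: int,
    n_hairpins: int,
    seed: int,
    min_spacing: int = 300,
    n_gu: int = 1,
) -> Tuple[List[SequenceRecord], PlantedTruth]:
    """Uniform-random genome with hairpins planted >= min_spacing apart.

    Each hairpin is mature + loop + star (or the 3p mirror), the star
    being the reverse complement of the mature with up to ``n_gu`` G:U
    wobble substitutions; strand is +/- with probability 1/2. Loops are
    drawn over {A, C} so they cannot base-pair internally. Each planted
    hairpin is certified in its genomic context: candidate draws are
    rejected until the precursor (with its real flanking bases)
    max-pair-folds as a single-stem hairpin with >= 90% of mature
    positions pairing across the loop — mirroring the biological fact
    that real pre-miRNAs are selected for clean folding, and making
    the planted truth unambiguous.
    """
    rng = np.random.default_rng(seed)
    truth = PlantedTruth()
    per_chrom = [n_hairpins // n_chrom + (1 if i < n_hairpins % n_chrom else 0)
                 for i in range(n_chrom)]
    max_hp = 2 * 24 + 16  # two arms + longest loop
    for i, k in enumerate(per_chrom):
        if k and k * (max_hp + min_spacing) + min_spacing > chrom_len:
            raise ValueError(
                f"cannot place {k} hairpins {min_spacing} nt apart on a "
                f"{chrom_len} nt chromosome"
            )
    records: List[SequenceRecord] = []
    hp_idx = 0
    for ci in range(n_chrom):
        chrom = f"chr{ci + 1}"
        seq = list(_random_seq(rng, chrom_len))
        stride = (chrom_len - min_spacing) // max(1, per_chrom[ci])
        for slot in range(per_chrom[ci]):
            hp_idx += 1
            start = min_spacing // 2 + slot * stride + int(rng.integers(0, max(1, stride - max_hp - min_spacing)))
            hp = None
            for _attempt in range(100):
                lm = int(rng.choice(_LEN_CHOICES, p=_LEN_WEIGHTS))
                mature = _random_seq(rng, lm)
                star = list(revcomp(mature))
                # plant up to n_gu G:U wobbles in the star arm
                eligible = [p for p, b in enumerate(star) if b in "CA"]
                rng.shuffle(eligible)
                for p in eligible[: int(n_gu)]:
                    star[p] = "T" if star[p] == "C" else "G"  # C->U keeps G:U; A->G keeps U:G
                loop = _random_seq(rng, int(rng.integers(8, 17)), alphabet="AC")
                strand = "+" if rng.random() < 0.5 else "-"
                arm = "5p" if rng.random() < 0.5 else "3p"
                hp = HairpinSpec(
                    id=f"hp{hp_idx:03d}", mature_seq=mature, star_seq="".join(star),
                    loop_seq=loop, chrom=chrom, start=start, strand=strand, arm=arm,
                )
                if _folds_cleanly(hp, seq):
                    break
            planted = hp.hairpin_seq if hp.strand == "+" else revcomp(hp.hairpin_seq)
            seq[start : start + len(planted)] = list(planted)
            truth.hairpins.append(hp)
        records.append(SequenceRecord(id=chrom, seq="".join(seq)))
    return records, truth


def make_profile(
    truth: PlantedTruth,
    seed: int,
    replicates: int = 2,
    dispersion: float = 10.0,
    n_key: int = 2,
) -> TreatmentProfile:
    """Assign expression patterns: the first ``n_key`` hairpins get the
    key-gene signature, the rest cycle through the remaining patterns."""
    rng = np.random.default_rng(seed)
    means: Dict[str, Tuple[float, ...]] = {}
    cycle = ["up_nacl", "down_nacl", "up_nacl_tu", "flat"]
    for i, hp in enumerate(truth.hairpins):
        if i < n_key:
            pat = MIRNA_PATTERNS["key"]
        else:
            pat = MIRNA_PATTERNS[cycle[i % len(cycle)]]
        # small per-hairpin abundance scale, shared across treatments
        scale = float(rng.uniform(0.7, 1.4))
        means[hp.id] = tuple(v * scale for v in pat)
    return TreatmentProfile(replicates=replicates, means=means, dispersion=dispersion)


def make_contaminants(seed: int, n: int = 4, length: int = 90) -> List[SequenceRecord]:
    """Synthetic stand-ins for rRNA/tRNA/snoRNA contaminant sequences."""
    rng = np.random.default_rng(seed)
    return [
        SequenceRecord(id=f"ncrna{i + 1}", seq=_random_seq(rng, length))
        for i in range(n)
    ]


def _nb_draw(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    """Negative binomial with mean ``mean`` and size ``dispersion``."""
    if mean <= 0:
        return 0
    p = dispersion / (dispersion + mean)
    return int(rng.negative_binomial(dispersion, p))


def _strand_slice(genome: Dict[str, str], chrom: str, start: int, end: int, strand: str) -> str:
    s = genome[chrom][max(0, start) : end]
    return s if strand == "+" else revcomp(s)


def simulate_reads(
    genome: Sequence[SequenceRecord],
    truth: PlantedTruth,
    profile: TreatmentProfile,
    total_depth: int,
    adapter: str,
    noise: float,
    seed: int,
    read_length: int = 40,
    star_fraction: float = 0.1,
    contaminants: Sequence[SequenceRecord] = (),
) -> Dict[str, List[SequenceRecord]]:
    """Per-library raw reads (adapter read-through included).

    ``total_depth`` is the expected mature-arm read count per library
    at control expression levels, split over hairpins. ``noise``
    bundles the nuisance processes: a fraction 0.4*noise of arm reads
    are isomiRs with 5'/3' offsets in {-3..+5} (kept within 18-30 nt so
    they survive size selection and inside the founder's clustering
    window), 0.1*noise of total reads are contaminant fragments, and
    0.02*noise are random degradation fragments. noise=0 gives exactly
    one distinct read per arm.
    """
    if not 0 <= noise <= 1:
        raise ValueError("noise must be in [0, 1]")
    rng = np.random.default_rng(seed)
    gseq = {g.id: dna(g.seq) for g in genome}
    depth_per_arm = total_depth / max(1, len(truth.hairpins))
    isomir_frac = 0.4 * noise
    libs: Dict[str, List[SequenceRecord]] = {}
    lib_treatment = profile.library_treatments()

    def arm_read(hp: HairpinSpec, interval: Tuple[int, int]) -> str:
        a, b = interval
        if rng.random() >= isomir_frac:
            return _strand_slice(gseq, hp.chrom, a, b, hp.strand)
        for _ in range(50):  # rejection-sample a valid isomiR
            d5, d3 = int(rng.integers(-3, 6)), int(rng.integers(-3, 6))
            ln = (b - a) - d5 + d3
            if not (18 <= ln <= 30):
                continue
            if hp.strand == "+":
                na, nb = a + d5, b + d3
            else:
                na, nb = a - d3, b - d5
            if na < 0 or nb > len(gseq[hp.chrom]):
                continue
            return _strand_slice(gseq, hp.chrom, na, nb, hp.strand)
        return _strand_slice(gseq, hp.chrom, a, b, hp.strand)

    for label in profile.library_labels:
        treatment = lib_treatment[label]
        t_idx = TREATMENTS.index(treatment)
        reads: List[str] = []
        for hp in truth.hairpins:
            mean = profile.means[hp.id][t_idx] * depth_per_arm
            n_mature = _nb_draw(rng, mean, profile.dispersion)
            n_star = _nb_draw(rng, mean * star_fraction, profile.dispersion)
            for _ in range(n_mature):
                reads.append(arm_read(hp, hp.mature_interval))
            for _ in range(n_star):
                reads.append(arm_read(hp, hp.star_interval))
        n_arm = len(reads)
        n_cont = int(round(0.1 * noise * n_arm)) if contaminants else 0
        n_degr = int(round(0.02 * noise * n_arm))
        for _ in range(n_cont):
            c = contaminants[int(rng.integers(0, len(contaminants)))]
            ln = int(rng.integers(18, 31))
            s0 = int(rng.integers(0, max(1, len(c.seq) - ln)))
            reads.append(dna(c.seq)[s0 : s0 + ln])
        for _ in range(n_degr):
            chrom = list(gseq)[int(rng.integers(0, len(gseq)))]
            ln = int(rng.integers(18, 31))
            s0 = int(rng.integers(0, len(gseq[chrom]) - ln))
            strand = "+" if rng.random() < 0.5 else "-"
            reads.append(_strand_slice(gseq, chrom, s0, s0 + ln, strand))
        records = []
        for i, insert in enumerate(reads):
            raw = (insert + dna(adapter))[:read_length]
            records.append(
                SequenceRecord(id=f"{label}_{i:06d}", seq=raw, qual="I" * len(raw))
            )
        libs[label] = records
    return libs


def simulate_targets(
    truth: PlantedTruth,
    profile: TreatmentProfile,
    seed: int,
    noise: float = 0.0,
    transcript_len: int = 400,
    n_key: int = 2,
    decoupled_every: int = 5,
    central_mismatch_every: int = 4,
) -> Tuple[List[SequenceRecord], List[ExpressionProfile], List[ExpressionProfile]]:
    """Target transcripts plus miRNA/target expression profiles.

    Each hairpin's mature miRNA gets one transcript with a planted
    complementary site (perfect, or with a central mismatch at miRNA
    position 10 for every ``central_mismatch_every``-th hairpin, which
    scores 2.0 and classifies as translational inhibition). Target
    expression is a normalised affine map of the miRNA profile —
    decreasing for inverse/key pairs, increasing for decoupled ones —
    with multiplicative Gaussian noise of sd ``noise``. Fills in
    ``truth.target_map`` and ``truth.key_gene_ids``.
    """
    rng = np.random.default_rng(seed)
    transcripts: List[SequenceRecord] = []
    mirna_profiles: List[ExpressionProfile] = []
    target_profiles: List[ExpressionProfile] = []
    _WOBBLE_FREE = {"A": "C", "C": "A", "G": "C", "T": "A"}  # neither WC nor G:U
    for i, hp in enumerate(truth.hairpins):
        tid = f"tx_{hp.id}"
        if i < n_key:
            coupling = "key"
        elif decoupled_every and (i % decoupled_every == decoupled_every - 1):
            coupling = "decoupled"
        else:
            coupling = "inverse"
        site = list(revcomp(hp.mature_seq))
        mode = "cleavage"
        if central_mismatch_every and (i % central_mismatch_every == central_mismatch_every - 1):
            # mismatch facing miRNA position 10: site is antiparallel, so
            # position 10 from the miRNA 5' end is len-10 from site start
            p = len(site) - 10
            site[p] = _WOBBLE_FREE[site[p]]
            mode = "translational"
        site_seq = "".join(site)
        pad = 30  # room for the 17/13 nt accessibility flanks
        s0 = int(rng.integers(pad, transcript_len - len(site_seq) - pad))
        bg = _random_seq(rng, transcript_len)
        tseq = bg[:s0] + site_seq + bg[s0 + len(site_seq) :]
        transcripts.append(SequenceRecord(id=tid, seq=tseq))

        e = np.asarray(profile.means[hp.id], dtype=float)
        e_rel = e / e[0]
        if coupling == "decoupled":
            t = 0.8 + 0.2 * e_rel
        else:
            c = float(e_rel.max()) + 0.5
            t = c - e_rel
        t = t / t[0]
        if noise > 0:
            t = t * np.exp(rng.normal(0.0, noise, size=len(t)))
            t = t / t[0]
        mirna_profiles.append(
            ExpressionProfile(entity_id=hp.id, organ="root", values=tuple(e_rel))
        )
        target_profiles.append(
            ExpressionProfile(entity_id=tid, organ="root", values=tuple(t))
        )
        truth.target_map[hp.id] = TargetPlan(
            transcript_id=tid, site_start=s0, coupling=coupling, mode=mode
        )
        if coupling == "key":
            truth.key_gene_ids.add(tid)
    return transcripts, mirna_profiles, target_profiles
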