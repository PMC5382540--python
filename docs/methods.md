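# Methods

This note records the models, parameter choices and numerical
conventions behind each pipeline stage, what the synthetic-data
generator does and does not emulate, and the known limitations.

## Coordinates and alphabet

All intervals are 0-based half-open internally; SAM (1-based POS) and
GFF3 (1-based inclusive) conventions are applied only at the I/O
boundary, so the conversion happens exactly once in each direction. T
and U are one base everywhere: libraries are RNA sequenced as cDNA, so
input may use either alphabet; sequences are upper-cased at parse time
and compared in DNA space. Reads containing N are dropped at parse with
a logged count, because N breaks both exact placement and
complementarity scoring.

## Preprocessing and placement

Adapter trimming removes everything from the leftmost position where
either the full 3′ adapter occurs or a read suffix of ≥ 8 nt matches an
adapter prefix. Untrimmed reads are kept but flagged (configurable);
with the default simulated read length of 40 nt every insert that
survives the 18–30 nt size filter carries at least 10 adapter bases, so
flagged reads in synthetic data indicate adapter-through failures
rather than real inserts. Contaminant filtering is exact-substring
against the contaminant set, on both strands — conservative, fully
testable, and adequate for a screen whose reference sets are themselves
curated sequences.

Genome placement is exact, ungapped and full-length on both strands,
seeded by an 18-mer table and verified over the whole read. Multi-mapped
reads are kept at every placement with full counts, and candidates
containing any multi-placed member are flagged (`multi_mapped`), which
preserves auditability without guessing a fractional-assignment model.
For real cross-species data, where mismatch-tolerant alignment is
needed, per-library SAM files are the entry point and the internal
mapper is bypassed.

## Greedy read clustering and arm pairing

The clustering pass is deliberately literal: alignments sorted by total
read count (ties broken by chromosome, start, strand, sequence, making
the result independent of input order), the most frequent read founding
a cluster whose coordinates stay those of that founder, and each later
read joining the first existing cluster — in creation order — whose
window fully contains it. The window is the founder interval extended
3 nt upstream and 5 nt downstream in strand orientation; full
containment (not overlap) is required, since partial overlap would
merge tandem clusters and destroy arm pairing. The −3/+5 window is what
bounds isomiR 5′/3′ variation in the generator, so in noiseless data
each planted arm yields exactly one cluster.

Arm pairing takes same-chromosome, same-strand cluster pairs with
edge-to-edge founder gap in [0, 150) — the 150 nt bound is exclusive
and the distance is measured between founder edges (a midpoint reading
would shift the bound by arm length; edge-to-edge is configurable and
stated). Each cluster may enter one candidate only: eligible pairs are
consumed greedily by smallest gap, ties resolved toward the genomically
left pair, which is deterministic and keeps chains (A–B–C) from
producing overlapping candidates. Overlapping clusters (negative gap)
never pair. The pipeline additionally requires clusters to carry ≥ 5
reads before pairing (`min_cluster_total`): 1–2-read clusters are
degradation background, and because the pairing rule is
nearest-neighbour, even rare background clusters sitting inside a
precursor's 150 nt neighbourhood would otherwise capture a genuine arm.
The mature arm is the higher-count founder sequence and must be
20–24 nt.

## Structure screen

The fold is Nussinov base-pair maximisation (Watson–Crick plus G:U,
hairpin loop ≥ 3) with a deterministic traceback that prefers pairing a
position with its most distant admissible partner. The widest-pair
preference matters: tied maximal structures exist in which a mature arm
pairs into the loop instead of across it, and the outermost-partner rule
resolves those ties toward the biologically meaningful stem. An
externally computed dot-bracket structure (e.g. from a thermodynamic
folder) can be substituted via `pairs_from_dotbracket`.

A candidate passes when (a) at least 80 % of mature positions pair into
the star-arm half of the precursor and (b) the structure has exactly one
terminal loop, counting only helices of ≥ 3 stacked pairs. Both
criteria are stand-ins — maximal pairing decorates any sequence with
isolated opportunistic pairs, so single pairs must not count as stems,
and requiring literally every paired mature base to land inside the
star cluster would reject genuine hairpins whose edge bases pair one
position off. The 0.8 fraction was chosen from the measured
discrimination of the screen: planted hairpins are constructed to fold
with ≥ 0.9 of mature positions across the loop, while ~2 % of random
length-matched genomic intervals reach 0.8 (≈ 7 % would reach 0.7).
Free energies are not computed; the screen is a pass/fail plausibility
filter, not a stability estimate.

## Differential expression

CPM normalisation (no pseudocount; 0.5 is added only inside logarithms)
and a two-sided Fisher exact test on the pooled 2×2 table — candidate
counts vs the remainder of each group's libraries — with BH FDR across
candidates per contrast. Calls: up if log₂FC ≥ +1 and p < 0.05, down if
log₂FC ≤ −1 and p < 0.05 (fold threshold inclusive, p threshold
strict); raw p is used for the call with FDR reported alongside.

Two properties of this self-contained test are worth stating plainly.
First, pooling replicates makes Fisher anti-conservative under
biological overdispersion: on negative-binomial null data with
dispersion 10 (variance ≈ 6× mean at the simulated depths) the
empirical false-positive rate at p < 0.05 is roughly 0.4, while in the
near-Poisson regime it is calibrated (~0.05). The simulator's
dispersion knob exists precisely so this inflation can be quantified;
for well-calibrated inference on real replicated data a count model
with dispersion estimation should be used instead. Second, CPM is a
composition-sensitive normalisation: if a large fraction of counts
shifts in one direction, library totals absorb part of the fold change
(the DE power simulation therefore plants balanced up- and
down-regulated rows).

## Target scoring

The expectation score sums per-position penalties over the duplex —
match 0, G:U wobble 0.5, mismatch 1.0, gap 2.0 — doubled at miRNA
positions 2–13, scored over the first 20 miRNA positions (hspsize),
reported to one decimal. 0 means perfect complementarity; emitted sites
require expectation ≤ 2.0. The 2–13 doubling window is a convention
choice (2–12 is the plausible alternative) and is configurable. The
alignment is a banded (±2) dynamic program against the
reverse-complemented window, at most one gap, deterministic traceback
preferring match > wobble > mismatch > gap; site scanning uses a
vectorised complementarity prefilter (single offsets with ≤ 6 gapless
defects, or adjacent-offset pairs indicating a one-base bulge) before
running the DP, which is exact for every site within the 2.0 cutoff.
Overlapping sites are merged keeping the lower expectation; at most 200
sites are reported per miRNA. A mismatch or gap at miRNA positions 9–11
classifies the site as translational inhibition; wobbles do not.
Site flanks (17 nt up / 13 nt down, truncated at transcript ends) are
extracted for external accessibility tools; unpaired-energy
accessibility itself is out of scope.

## Coupling and key genes

Pearson r is computed over the four treatment-mean expressions
(fold-over-control), matching the granularity at which treatment
responses are summarised; with four points the r values are descriptive
statistics, not hypothesis tests. Classes: inverse if r ≤ −0.25,
decoupled if r ≥ +0.25, otherwise indeterminate (zero-variance profiles
are reported as indeterminate rather than given a number). The ±0.25
bounds are configurable conventions chosen so that weak but genuine
inverse coupling still classifies as inverse; raw r is always emitted.

The ranking stage computes Δ = expression(NaCl+TU) − expression(TU) per
target and sorts descending (ties by id). The key-gene flag additionally
requires the NaCl+TU vs NaCl ratio (larger over smaller) to reach 2.0
and Δ > 0. The two clauses are computed and reported separately so
either stage of the nomination can be audited. Enrichment is a
one-sided Fisher exact test per term with a Bonferroni multiplier equal
to the number of tested terms.

## The synthetic-data generator

The generator emulates the experimental design end to end: a uniform
random genome with planted hairpins ≥ 300 nt apart (so no spurious
cross-locus pairing), four treatments × ≥ 2 replicates, negative-
binomial counts (default dispersion 10) around per-hairpin treatment
means, star arms at 10 % of mature abundance, mature lengths 20–24 nt
with mode 23 then 21 then 22, 3′ adapter read-through at a 40 nt
instrument read length, and a single `noise` dial that sets the isomiR
fraction (0.4·noise, offsets in {−3..+5} kept inside the clustering
window and the 18–30 nt size range), contaminant reads (0.1·noise) and
random degradation fragments (0.02·noise).

Hairpins are mature + loop + star (or the 3p mirror), the star being
the reverse complement of the mature with one G:U wobble substitution —
which also prevents mature reads from mapping to the star locus on the
opposite strand — and loops drawn over {A, C} so they cannot pair
internally. Each draw is certified in its genomic context: candidates
are re-drawn until the precursor, including its real flanking bases,
max-pair-folds as a single stem with ≥ 90 % of mature positions pairing
across the loop. This mirrors the biological fact that real pre-miRNAs
are selected for clean folding and makes the planted truth unambiguous;
it also means the structure screen's pass rate on planted hairpins
measures pipeline correctness, not fold quality of random sequences.

Target transcripts carry one site per mature miRNA — perfect, or with a
central mismatch (position 10, expectation 2.0, translational) for
every fourth hairpin. Target expression is a normalised affine map of
the miRNA profile: decreasing for inverse pairs (r = −1 noiselessly),
increasing but flattened (0.8 + 0.2·e) for deliberately decoupled pairs
(r = +1), with multiplicative log-normal noise (sd 0.1 by default in
the standard fixture). The planted key-gene signature — miRNA up under
NaCl and TU but strongly suppressed under NaCl+TU, hence target peaking
under NaCl+TU — gives the key target Δ ≈ 1.2 against decoy Δ ≤ 0.4 and
a 3-fold NaCl+TU:NaCl ratio, so rank-1 recovery is robust at the
simulated noise level.

What the generator does **not** emulate: sequencing errors beyond what
the isomiR model induces, quality-score structure, GC or ligation bias,
genuine transcriptome complexity (one transcript per target),
multi-locus miRNA families, or organ differences (profiles carry an
organ label but the fixture simulates one organ). Passing tests
therefore demonstrate that the algorithms recover what they are
specified to recover under a faithful but idealised data model — not
that the Fisher DE test or the exact mapper are adequate for real
overdispersed, mismatch-laden libraries (see the DE caveats above and
the SAM entry point).

## Problem sizes and determinism

The standard fixture is 10 hairpins in 2 × 20 kb with ~13 k reads per
library at noise 0.2; recovery checks use 20 hairpins at 1 000
reads/arm, noiseless; oracle comparisons use 200 random clustering
instances, 500 sequences (≤ 12 nt) for the fold, and 2 000-row count
simulations for DE — sizes at which every stage, the full test suite
and the acceptance script run in well under a minute on one core while
keeping the statistical bounds (≥ 95 % recovery rates, FPR ≤ 0.07)
comfortably estimable. All randomness flows through seeded NumPy
generators; sorting is fully tie-broken, so two runs from the same seed
produce byte-identical outputs.

## Known limitations

- Fisher-on-pooled-counts DE is anti-conservative under overdispersion
  (quantified above) and CPM is composition-sensitive; both are
  documented trade-offs of keeping the stage self-contained.
- The structure screen is a base-pair-count heuristic; it accepts
  externally computed structures but never computes energies.
- Exact matching cannot place reads with sequencing errors or
  cross-species mismatches; use the SAM path for such data.
- Conserved-miRNA annotation, degradome validation, and accessibility
  energies are out of scope.
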