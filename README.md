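# redoxmir

Small-RNA sequencing analysis for experiments that probe **redox-mediated
salt tolerance** in plants: libraries from seedlings under four treatments —
control, NaCl, NaCl + thiourea (TU, a non-physiological thiol ROS
scavenger), and TU alone — are mined for miRNAs, their differential
expression, their mRNA targets, and finally the few "key genes" whose
treatment response best explains the priming phenotype. The package is
aimed at analysts who want every stage of that chain — read cleanup,
hairpin discovery, expression calls, target prediction, ranking — as
plain, testable, dependency-light Python, with a synthetic-data module
that plants known ground truth so the whole pipeline can be verified
without any sequencing data.

## The method

**Discovery by positional read clustering.** After 3′-adapter removal
(requiring ≥ 8 nt of adapter), ncRNA-contaminant filtering and 18–30 nt
size selection, reads are collapsed to unique sequences with per-library
counts and placed exactly on the genome. Clustering is a single greedy
pass: sort alignments by read count; the most frequent read founds the
first cluster and fixes its coordinates; every subsequent read joins the
first existing same-strand cluster whose isomiR window (3 nt upstream,
5 nt downstream of the founding read, in strand orientation) fully
contains it, otherwise it founds a new cluster. Because a pre-miRNA
hairpin is processed into a mature and a star arm, bona fide miRNA loci
appear as **two same-strand clusters separated by less than 150 nt**;
such pairs become hairpin candidates, the higher-count arm giving the
mature sequence (kept only if 20–24 nt). Each candidate precursor must
also fold as a hairpin: a Nussinov base-pair-maximisation fold
(Watson–Crick + G:U, loop ≥ 3) must send ≥ 80 % of mature positions into
the star-arm half of the precursor with a single terminal loop.

**Expression.** Counts are CPM-normalised; for each treatment *t* vs
control,

&nbsp;&nbsp;&nbsp;&nbsp;log₂FC = log₂(mean CPM_t + 0.5) − log₂(mean CPM_ctrl + 0.5),

with a two-sided Fisher exact test on pooled group counts and
Benjamini–Hochberg FDR across candidates. A candidate is called up/down
when |log₂FC| ≥ 1 and p < 0.05.

**Targets.** DE miRNAs are scanned against transcripts with a plant
target-site *expectation* score: per aligned position, match 0, G:U
wobble 0.5, mismatch 1.0, gap 2.0, doubled at miRNA positions 2–13,
scored over the first 20 positions (hspsize); sites with expectation
≤ 2.0 are kept (0 = perfect complementarity), and a mismatch or gap at
positions 9–11 classifies the site as translational inhibition rather
than cleavage. 17 nt upstream / 13 nt downstream flanks are attached
for downstream accessibility analysis.

**Key genes.** Each miRNA:target pair gets a Pearson r over the four
treatment expressions (r ≤ −0.25 inverse, r ≥ +0.25 decoupled from
miRNA-mediated repression). Targets are ranked by
Δ = expression(NaCl+TU) − expression(TU), and top-ranked targets whose
NaCl+TU vs NaCl expression differs by ≥ 2-fold are flagged as key genes
of the redox-mediated response. Term enrichment of target sets uses a
one-sided Fisher exact test with Bonferroni correction.

## Worked example

```bash
redoxmir simulate demo --seed 7 --n-hairpins 10 --depth 8000
redoxmir all demo demo_out
```

The simulated dataset plants 10 hairpins in a 2 × 20 kb genome and
writes eight FASTQ libraries (4 treatments × 2 replicates, ~13 k reads
each, 20 % nuisance noise), transcripts with complementary target
sites, and truth tables. The run prints

```
pipeline complete; key genes: {'couplings': 10, 'key_genes': ['tx_hp001', 'tx_hp002']}
```

and `demo_out/run_report.json` records the stage-by-stage counts:
107 827 raw reads, 2 105 dropped as ncRNA contaminants, 1 604 unique
sequences, 429 read clusters of which 11 candidate hairpins pair up
(10 planted + 1 strand-mirror artifact), all passing the structure
screen; 10 candidates are differentially expressed in at least one
treatment, every scanned miRNA finds its planted target site, and the
ranking recovers exactly the two planted key genes:

```
target_id  rank  delta_tu  fold_nacl_vs_nacltu  key_gene
tx_hp002   1     1.1802    3.306                True
tx_hp001   2     1.0141    3.6654               True
```

`delta_tu` is the NaCl+TU − TU expression difference the ranking sorts
on; the fold column is the NaCl+TU vs NaCl ratio the 2-fold key-gene
cutoff applies to. `demo_out/coupling.tsv` lists each miRNA:target
Pearson r with its class (the planted key pairs are inverse, r ≈ −0.9).

All outputs are plain TSV/GFF3/JSON; the same stages are available as
library functions (`redoxmir.cluster_reads`, `redoxmir.de_test`,
`redoxmir.scan_transcript`, `redoxmir.rank_targets`, ...).

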