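"""End-to-end driver: preprocess -> map -> cluster -> fold-screen ->
quantify -> differential expression -> target scan -> coupling/ranking.

Every stage writes its table under the output directory; a fixed
``rng_seed`` plus deterministic orderings make two runs byte-identical.
Entry points are per-library FASTQ plus a genome FASTA, or pre-computed
per-library SAM alignments (in which case trimming/filtering/mapping
are skipped and noted in the report).
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from . import cluster as clustermod
from . import diffexpr, io, keygene, preprocess, synthetic, targets
from .config import PipelineConfig
from .diffexpr import TREATMENTS, CountMatrix
from .fold import fold_maxpair, hairpin_check
from .keygene import ExpressionProfile
from .sequences import SequenceRecord, dna, revcomp

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """Raised with the failing stage's name."""


@dataclass
class PipelineInputs:
    library_treatments: Dict[str, str]  # library label -> treatment
    fastq_by_library: Optional[Dict[str, str]] = None
    sam_by_library: Optional[Dict[str, str]] = None
    genome_fasta: Optional[str] = None
    contaminants_fasta: Optional[str] = None
    transcripts_fasta: Optional[str] = None
    expression_tsv: Optional[str] = None  # target expression profiles

    def validate(self) -> "PipelineInputs":
        if self.fastq_by_library is None and self.sam_by_library is None:
            raise ValueError("need FASTQ or SAM input")
        if self.fastq_by_library is not None and self.genome_fasta is None:
            raise ValueError("FASTQ input requires a genome FASTA")
        labels = self.fastq_by_library or self.sam_by_library
        missing = set(labels) - set(self.library_treatments)
        if missing:
            raise ValueError(f"libraries without treatment: {sorted(missing)}")
        return self


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name}: {exc}") from exc
        return wrapped
    return deco


def read_expression_tsv(path) -> List[ExpressionProfile]:
    df = pd.read_csv(path, sep="\t")
    profiles = []
    for _, row in df.iterrows():
        profiles.append(
            ExpressionProfile(
                entity_id=str(row["entity"]), organ=str(row["organ"]),
                values=tuple(float(row[t]) for t in TREATMENTS),
            )
        )
    return profiles


def write_expression_tsv(profiles: Sequence[ExpressionProfile], path) -> None:
    rows = [
        {"entity": p.entity_id, "organ": p.organ,
         **{t: p.values[i] for i, t in enumerate(TREATMENTS)}}
        for p in profiles
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6g")


def run_pipeline(config: PipelineConfig, inputs: PipelineInputs, outdir) -> Dict:
    """Execute the full chain and write all intermediate tables.

    Returns a report dict with per-stage survivor counts, also written
    as ``run_report.json``.
    """
    config.validate()
    inputs.validate()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: Dict = {"stages": {}, "seed": config.rng_seed}
    labels = sorted(inputs.library_treatments)

    genome = io.read_fasta(inputs.genome_fasta) if inputs.genome_fasta else None

    # ---------------- preprocess + map (or SAM import) ----------------
    if inputs.fastq_by_library is not None:
        alignments, uniq, pre_counts = _preprocess_and_map(config, inputs, labels, genome)
        report["stages"]["preprocess"] = pre_counts
    else:
        alignments, uniq = _import_sam(inputs, labels)
        report["stages"]["preprocess"] = {"skipped": "SAM input; trimming/filtering/mapping not run"}
    report["stages"]["map"] = {"alignments": len(alignments), "unique_reads": len(uniq)}
    _write_unique_reads(uniq, labels, out / "collapsed_reads.tsv")
    _write_alignments(alignments, out / "alignments.tsv")

    # ------------------------------ cluster ---------------------------
    clusters, candidates, n_len_rejected = _cluster(config, alignments)
    report["stages"]["cluster"] = {
        "clusters": len(clusters),
        "candidates": len(candidates),
        "rejected_mature_length": n_len_rejected,
    }
    _write_clusters(clusters, labels, out / "clusters.tsv")

    # ----------------------------- fold screen ------------------------
    if genome is not None:
        candidates, fold_rows = _fold_screen(candidates, genome)
        report["stages"]["fold"] = {
            "passed": len(candidates),
            "failed": len(fold_rows) - len(candidates),
        }
        pd.DataFrame(fold_rows).to_csv(
            out / "fold_metrics.tsv", sep="\t", index=False, float_format="%.6g"
        )
    else:
        report["stages"]["fold"] = {"skipped": "no genome FASTA provided"}
    io.write_candidates_gff3(candidates, out / "candidates.gff3")
    _write_candidates(candidates, labels, out / "candidates.tsv")

    # ------------------------------ quantify + DE ---------------------
    cm = _quantify(candidates, labels, inputs.library_treatments)
    cm.counts.to_csv(out / "counts.tsv", sep="\t")
    calls = _de(config, cm)
    for treat, results in calls.items():
        diffexpr.de_results_frame(results).to_csv(
            out / f"de_{treat.replace('+', '_')}.tsv", sep="\t",
            index=False, float_format="%.6g",
        )
    venn = diffexpr.treatment_specific_sets(calls)
    _write_venn(venn, out / "venn.tsv")
    de_ids = sorted({r.id for rs in calls.values() for r in rs if r.call != "ns"})
    report["stages"]["de"] = {
        "contrasts": len(calls), "de_candidates": len(de_ids),
        "venn_regions": {"|".join(sorted(k)): len(v) for k, v in sorted(venn.items(), key=lambda kv: sorted(kv[0]))},
    }

    # ------------------------------ targets ---------------------------
    best_target: Dict[str, str] = {}
    if inputs.transcripts_fasta:
        site_rows, best_target = _scan_targets(config, candidates, de_ids, inputs.transcripts_fasta)
        pd.DataFrame(site_rows).to_csv(
            out / "target_sites.tsv", sep="\t", index=False, float_format="%.1f"
        )
        report["stages"]["targets"] = {
            "mirnas_scanned": len(de_ids), "sites": len(site_rows),
        }
    else:
        report["stages"]["targets"] = {"skipped": "no transcript FASTA provided"}

    # ------------------------- coupling / key genes -------------------
    if inputs.expression_tsv and best_target:
        kg = _keygenes(config, cm, best_target, inputs.expression_tsv, out)
        report["stages"]["keygene"] = kg
    else:
        report["stages"]["keygene"] = {"skipped": "needs target sites and expression TSV"}

    with open(out / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report


@_stage("preprocess")
def _preprocess_and_map(config, inputs, labels, genome):
    tagged: List[Tuple[str, int]] = []
    pre = {"input": 0, "n_dropped": 0, "untrimmed": 0, "length_dropped": 0,
           "contaminant_dropped": 0, "kept": 0}
    contaminants = (
        io.read_fasta(inputs.contaminants_fasta) if inputs.contaminants_fasta else []
    )
    for li, label in enumerate(labels):
        records = io.read_fastq(inputs.fastq_by_library[label])
        pre["input"] += len(records)
        records, n_dropped = preprocess.drop_n_reads(records)
        pre["n_dropped"] += n_dropped
        trimmed_seqs = []
        for r in records:
            t, was_trimmed = preprocess.trim_adapter(
                r.seq, config.adapter, config.min_adapter_overlap
            )
            if not was_trimmed:
                pre["untrimmed"] += 1  # kept, flagged
            if t:
                trimmed_seqs.append(t)
        kept, tallies = preprocess.filter_reads(
            trimmed_seqs, config.read_len_min, config.read_len_max, contaminants
        )
        pre["length_dropped"] += tallies["length"]
        pre["contaminant_dropped"] += tallies["contaminant"]
        pre["kept"] += len(kept)
        tagged.extend((s, li) for s in kept)
    uniq = preprocess.collapse_unique(tagged, n_libraries=len(labels))
    alignments, n_unplaced = preprocess.map_exact(
        uniq, genome, k=config.read_len_min
    )
    pre["unplaced_unique_reads"] = n_unplaced
    return alignments, uniq, pre


@_stage("sam_import")
def _import_sam(inputs, labels):
    paths = [inputs.sam_by_library[l] for l in labels]
    return io.merge_sam_libraries(paths)


@_stage("cluster")
def _cluster(config, alignments):
    clusters = clustermod.cluster_reads(
        alignments, config.cluster_upstream_flank, config.cluster_downstream_flank
    )
    pairable = [c for c in clusters if c.total_count >= config.min_cluster_total]
    candidates = clustermod.pair_clusters(pairable, config.max_pair_gap)
    candidates, n_rejected = clustermod.filter_candidate_length(
        candidates, config.mirna_len_min, config.mirna_len_max
    )
    return clusters, candidates, n_rejected


@_stage("fold")
def _fold_screen(candidates, genome):
    gseq = {g.id: dna(g.seq) for g in genome}
    passed = []
    rows = []
    for c in candidates:
        p0, p1 = c.precursor_start, c.precursor_end
        seq = gseq[c.chrom][max(0, p0) : p1]
        if c.strand == "-":
            seq = revcomp(seq)

        def rel(cl):
            if c.strand == "+":
                return (cl.start - p0, cl.end - p0)
            return (p1 - cl.end, p1 - cl.start)

        fr = fold_maxpair(seq)
        ok, metrics = hairpin_check(rel(c.mature_cluster), rel(c.star_cluster), fr)
        rows.append({"id": c.id, "pass": ok, "structure": fr.structure,
                     "n_pairs": fr.n_pairs, **metrics})
        if ok:
            passed.append(c)
    return passed, rows


@_stage("quantify")
def _quantify(candidates, labels, library_treatments) -> CountMatrix:
    data = {
        c.id: clustermod.quantify(c, n_libraries=len(labels)) for c in candidates
    }
    counts = pd.DataFrame.from_dict(data, orient="index", columns=labels)
    counts.index.name = "id"
    return CountMatrix(counts=counts, library_treatments=dict(library_treatments))


@_stage("de")
def _de(config, cm):
    calls = {}
    for treat in TREATMENTS[1:]:
        results = diffexpr.de_test(cm, treat, "control")
        calls[treat] = diffexpr.call_de(
            results, config.de_min_abs_log2fc, config.de_alpha
        )
    return calls


@_stage("targets")
def _scan_targets(config, candidates, de_ids, transcripts_fasta):
    transcripts = {r.id: r.seq for r in io.read_fasta(transcripts_fasta)}
    mature = {c.id: c.mature for c in candidates}
    rows = []
    best: Dict[str, str] = {}
    for mid in de_ids:
        sites = targets.scan_transcriptome(
            mid, mature[mid], transcripts,
            max_expectation=config.target_max_expectation,
            hspsize=config.hspsize,
            flank_up=config.flank_up, flank_down=config.flank_down,
            central_range=config.central_mismatch_range,
        )
        if sites:
            best[mid] = sites[0].transcript_id
        for s in sites:
            rows.append({
                "mirna_id": s.mirna_id, "transcript_id": s.transcript_id,
                "site_start": s.site_start, "site_end": s.site_end,
                "expectation": s.expectation, "mode": s.mode,
                "flank_up": s.flank_up_seq, "flank_down": s.flank_down_seq,
            })
    return rows, best


@_stage("keygene")
def _keygenes(config, cm, best_target, expression_tsv, out):
    target_profiles = {
        p.entity_id: p for p in read_expression_tsv(expression_tsv)
    }
    # miRNA expression from the pipeline's own counts: mean CPM per
    # treatment as fold over control
    cpm = diffexpr.normalize_cpm(cm.counts)
    mirna_profiles: Dict[str, ExpressionProfile] = {}
    organ = next(iter(target_profiles.values())).organ if target_profiles else "root"
    for rid in cm.counts.index:
        vals = []
        for t in TREATMENTS:
            libs = cm.libraries_of(t)
            vals.append(float(cpm.loc[rid, libs].mean()) if libs else 0.0)
        if vals[0] <= 0:
            logger.info("candidate %s unexpressed in control; excluded from coupling", rid)
            continue
        mirna_profiles[rid] = ExpressionProfile(
            entity_id=str(rid), organ=organ,
            values=tuple(v / vals[0] for v in vals),
        )
    result = keygene.end_to_end_keygenes(
        set(best_target), best_target, mirna_profiles, target_profiles,
        fold_cutoff=config.keygene_fold_cutoff,
    )
    pd.DataFrame(
        [{"mirna_id": c.mirna_id, "target_id": c.target_id,
          "r": "" if c.r is None else round(c.r, 4), "class": c.klass}
         for c in result["couplings"]]
    ).to_csv(out / "coupling.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"target_id": r.target_id, "rank": r.rank,
          "delta_tu": round(r.delta_tu, 4),
          "fold_nacl_vs_nacltu": round(r.fold_nacl_vs_nacltu, 4),
          "key_gene": r.key_gene}
         for r in result["ranking"]]
    ).to_csv(out / "keygenes.tsv", sep="\t", index=False)
    return {
        "couplings": len(result["couplings"]),
        "key_genes": sorted(result["key_genes"]),
    }


def _write_unique_reads(uniq, labels, path):
    pd.DataFrame(
        [{"seq": u.seq, **{l: c for l, c in zip(labels, u.counts)}} for u in uniq]
    ).to_csv(path, sep="\t", index=False)


def _write_alignments(alignments, path):
    rows = [
        {"chrom": a.chrom, "start": a.start, "end": a.end, "strand": a.strand,
         "seq": a.read.seq, "total_count": a.read.total,
         "n_placements": a.n_placements}
        for a in alignments
    ]
    rows.sort(key=lambda r: (r["chrom"], r["start"], r["strand"], r["seq"]))
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _write_clusters(clusters, labels, path):
    rows = [
        {"chrom": c.chrom, "start": c.start, "end": c.end, "strand": c.strand,
         "window_start": c.window_start, "window_end": c.window_end,
         "founder_seq": c.founder.read.seq, "n_members": len(c.members),
         "total_count": c.total_count}
        for c in clusters
    ]
    rows.sort(key=lambda r: (r["chrom"], r["start"], r["strand"]))
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _write_candidates(candidates, labels, path):
    rows = [
        {"id": c.id, "chrom": c.chrom, "strand": c.strand,
         "precursor_start": c.precursor_start, "precursor_end": c.precursor_end,
         "gap": c.gap, "mature": c.mature, "star": c.star,
         "mature_start": c.mature_cluster.start, "mature_end": c.mature_cluster.end,
         "star_start": c.star_cluster.start, "star_end": c.star_cluster.end,
         "multi_mapped": c.multi_mapped,
         **{l: n for l, n in zip(labels, clustermod.quantify(c, len(labels)))}}
        for c in candidates
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _write_venn(venn, path):
    rows = [
        {"region": "|".join(sorted(k)), "n": len(v), "ids": ",".join(sorted(v))}
        for k, v in venn.items()
    ]
    rows.sort(key=lambda r: r["region"])
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ------------------------------------------------------------ fixtures

def simulate_dataset(
    outdir,
    seed: int,
    n_chrom: int = 2,
    chrom_len: int = 20000,
    n_hairpins: int = 20,
    total_depth: int = 20000,
    noise: float = 0.2,
    replicates: int = 2,
    dispersion: float = 10.0,
    config: Optional[PipelineConfig] = None,
) -> Tuple[PipelineInputs, synthetic.PlantedTruth, PipelineConfig]:
    """Write a complete synthetic dataset plus truth tables to disk."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = config or PipelineConfig(rng_seed=seed)
    genome, truth = synthetic.make_genome(n_chrom, chrom_len, n_hairpins, seed=seed)
    profile = synthetic.make_profile(truth, seed=seed + 1, replicates=replicates,
                                     dispersion=dispersion)
    contaminants = synthetic.make_contaminants(seed=seed + 2)
    libs = synthetic.simulate_reads(
        genome, truth, profile, total_depth=total_depth, adapter=cfg.adapter,
        noise=noise, seed=seed + 3, contaminants=contaminants,
    )
    transcripts, mirna_prof, target_prof = synthetic.simulate_targets(
        truth, profile, seed=seed + 4, noise=min(0.1, noise)
    )
    io.write_fasta(genome, out / "genome.fa")
    io.write_fasta(contaminants, out / "contaminants.fa")
    io.write_fasta(transcripts, out / "transcripts.fa")
    fastqs = {}
    for label, records in libs.items():
        p = out / f"{label}.fastq"
        io.write_fastq(records, p)
        fastqs[label] = str(p)
    write_expression_tsv(target_prof, out / "target_expression.tsv")
    write_expression_tsv(mirna_prof, out / "mirna_expression.tsv")
    pd.DataFrame(
        [{"id": h.id, "chrom": h.chrom, "start": h.start, "end": h.end,
          "strand": h.strand, "arm": h.arm, "mature": h.mature_seq,
          "star": h.star_seq,
          "mature_start": h.mature_interval[0], "mature_end": h.mature_interval[1]}
         for h in truth.hairpins]
    ).to_csv(out / "truth_hairpins.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"mirna_id": mid, "transcript_id": tp.transcript_id,
          "site_start": tp.site_start, "coupling": tp.coupling, "mode": tp.mode,
          "key_gene": tp.transcript_id in truth.key_gene_ids}
         for mid, tp in sorted(truth.target_map.items())]
    ).to_csv(out / "truth_targets.tsv", sep="\t", index=False)
    cfg.to_yaml(out / "config.yaml")
    inputs = PipelineInputs(
        library_treatments=profile.library_treatments(),
        fastq_by_library=fastqs,
        genome_fasta=str(out / "genome.fa"),
        contaminants_fasta=str(out / "contaminants.fa"),
        transcripts_fasta=str(out / "transcripts.fa"),
        expression_tsv=str(out / "target_expression.tsv"),
    )
    return inputs, truth, cfg
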