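"""File-format boundaries: FASTA, FASTQ, SAM (via pysam), GFF3, TSV.

Internally every interval is 0-based half-open; the 1-based conventions
of SAM and GFF3 are applied exactly once, here. FASTA/FASTQ readers are
deliberately strict and report the offending line number, which is why
they are written out rather than delegated.
"""
from __future__ import annotations

import gzip
import logging
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pysam

from .preprocess import AlignmentRecord, UniqueRead
from .sequences import SequenceRecord

logger = logging.getLogger(__name__)


def _open_text(path, mode="rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


class ParseError(ValueError):
    """Malformed input file; message names the file and line."""


# ---------------------------------------------------------------- FASTA

def read_fasta(path) -> List[SequenceRecord]:
    """Read FASTA; sequences upper-cased, U preserved, file order kept.

    Duplicate ids are kept (a warning is logged); a header with no
    sequence, or sequence before any header, is a :class:`ParseError`
    naming the line.
    """
    records: List[SequenceRecord] = []
    seen: set = set()
    header: Optional[str] = None
    header_line = 0
    chunks: List[str] = []

    def flush():
        if header is None:
            return
        if not chunks:
            raise ParseError(f"{path}:{header_line}: header {header!r} has no sequence")
        rid = header.split()[0]
        if rid in seen:
            logger.warning("%s: duplicate FASTA id %r kept", path, rid)
        seen.add(rid)
        records.append(SequenceRecord(id=rid, seq="".join(chunks).upper()))

    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].strip()
                if not header:
                    raise ParseError(f"{path}:{lineno}: empty FASTA header")
                header_line = lineno
                chunks = []
            else:
                if header is None:
                    raise ParseError(f"{path}:{lineno}: sequence before first header")
                chunks.append(line)
        flush()
    return records


def write_fasta(records: Sequence[SequenceRecord], path, width: int = 70) -> None:
    with _open_text(path, "wt") as fh:
        for r in records:
            fh.write(f">{r.id}\n")
            for i in range(0, len(r.seq), width):
                fh.write(r.seq[i : i + width] + "\n")


# ---------------------------------------------------------------- FASTQ

def read_fastq(path) -> List[SequenceRecord]:
    """Read 4-line-record FASTQ (Sanger qualities, retained but unused)."""
    records: List[SequenceRecord] = []
    with _open_text(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    while lines and lines[-1] == "":
        lines.pop()
    if len(lines) % 4 != 0:
        raise ParseError(f"{path}: truncated FASTQ (line count {len(lines)} not a multiple of 4)")
    for i in range(0, len(lines), 4):
        head, seq, plus, qual = lines[i : i + 4]
        lineno = i + 1
        if not head.startswith("@"):
            raise ParseError(f"{path}:{lineno}: expected '@' header, got {head[:20]!r}")
        if not plus.startswith("+"):
            raise ParseError(f"{path}:{lineno + 2}: expected '+' separator")
        if len(seq) != len(qual):
            raise ParseError(
                f"{path}:{lineno + 3}: quality length {len(qual)} != sequence length {len(seq)}"
            )
        records.append(SequenceRecord(id=head[1:].split()[0], seq=seq.upper(), qual=qual))
    return records


def write_fastq(records: Sequence[SequenceRecord], path) -> None:
    with _open_text(path, "wt") as fh:
        for r in records:
            qual = r.qual if r.qual is not None else "I" * len(r.seq)
            fh.write(f"@{r.id}\n{r.seq}\n+\n{qual}\n")


# ------------------------------------------------------------------ SAM

def read_sam_min(path, lib_index: int = 0, n_libraries: int = 1) -> List[AlignmentRecord]:
    """Minimal SAM import: primary/secondary ungapped alignments only.

    SAM 1-based POS becomes the internal 0-based half-open interval;
    FLAG 0x10 becomes strand "-" (the read sequence is stored 5'->3' as
    sequenced, i.e. reverse-complemented back from the SAM field).
    Unmapped and gapped records are skipped with a logged count. Each
    record carries a count of 1 in ``lib_index``; collapsing happens
    downstream.
    """
    records: List[AlignmentRecord] = []
    n_skipped = 0
    try:
        sam = pysam.AlignmentFile(str(path), "r", check_sq=True)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    with sam:
        if not sam.header.get("SQ"):
            raise ParseError(f"{path}: SAM header has no @SQ lines")
        for a in sam:
            if a.is_unmapped or a.is_supplementary:
                n_skipped += 1
                continue
            cig = a.cigartuples
            if cig is None or any(op not in (0, 7, 8) for op, _ in cig):
                n_skipped += 1  # gapped/clipped: outside the minimal subset
                continue
            qs = a.query_sequence
            if qs is None:
                n_skipped += 1
                continue
            from .sequences import revcomp

            seq = revcomp(qs) if a.is_reverse else qs.upper()
            counts = [0] * n_libraries
            counts[lib_index] = 1
            records.append(
                AlignmentRecord(
                    read=UniqueRead(seq=seq, counts=counts),
                    chrom=a.reference_name,
                    start=a.reference_start,
                    end=a.reference_end,
                    strand="-" if a.is_reverse else "+",
                )
            )
    if n_skipped:
        logger.info("%s: skipped %d unmapped/gapped SAM records", path, n_skipped)
    return records


def merge_sam_libraries(paths: Sequence) -> Tuple[List[AlignmentRecord], List[UniqueRead]]:
    """Combine one SAM per library into per-library-counted alignments.

    Identical (sequence, placement) records are collapsed; counts are
    per-library vectors in the order of ``paths``.
    """
    n = len(paths)
    read_counts: Dict[str, List[int]] = {}
    placements: Dict[str, set] = {}
    for lib, p in enumerate(paths):
        for rec in read_sam_min(p, lib_index=lib, n_libraries=n):
            s = rec.read.seq
            if s not in read_counts:
                read_counts[s] = [0] * n
                placements[s] = set()
            read_counts[s][lib] += 1
            placements[s].add((rec.chrom, rec.start, rec.end, rec.strand))
    uniq = [UniqueRead(seq=s, counts=c) for s, c in read_counts.items()]
    uniq.sort(key=lambda u: (-u.total, u.seq))
    alignments: List[AlignmentRecord] = []
    for ur in uniq:
        locs = sorted(placements[ur.seq])
        for chrom, start, end, strand in locs:
            alignments.append(
                AlignmentRecord(
                    read=ur, chrom=chrom, start=start, end=end,
                    strand=strand, n_placements=len(locs),
                )
            )
    return alignments, uniq


# ----------------------------------------------------------------- GFF3

def write_candidates_gff3(candidates: Sequence, path) -> None:
    """One hairpin feature per candidate with mature/star child arms.

    GFF3 columns 4/5 are 1-based inclusive: internal [start, end) maps
    to (start + 1, end).
    """
    with _open_text(path, "wt") as fh:
        fh.write("##gff-version 3\n")
        for c in candidates:
            pid = c.id
            fh.write(
                "\t".join(
                    [
                        c.chrom, "redoxmir", "miRNA_primary_transcript",
                        str(c.precursor_start + 1), str(c.precursor_end),
                        ".", c.strand, ".", f"ID={pid}",
                    ]
                )
                + "\n"
            )
            for role, arm in (("mature", c.mature_cluster), ("star", c.star_cluster)):
                fh.write(
                    "\t".join(
                        [
                            c.chrom, "redoxmir", "miRNA",
                            str(arm.start + 1), str(arm.end),
                            ".", c.strand, ".", f"ID={pid}.{role};Parent={pid}",
                        ]
                    )
                    + "\n"
                )


def read_gff3_features(path) -> List[dict]:
    """Read back GFF3 features as dicts with internal 0-based intervals."""
    feats: List[dict] = []
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 GFF3 columns")
            attrs = dict(
                kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv
            )
            feats.append(
                {
                    "chrom": cols[0], "type": cols[2],
                    "start": int(cols[3]) - 1, "end": int(cols[4]),
                    "strand": cols[6], "attrs": attrs,
                }
            )
    return feats
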