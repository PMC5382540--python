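"""Pipeline configuration: every numeric threshold the workflow applies.

All coordinates inside the package are 0-based half-open; conversions to the
1-based conventions of SAM and GFF3 happen only at the I/O boundary.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Tuple

import yaml

# Illumina TruSeq small-RNA 3' adapter; overridable per run.
DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"


@dataclass
class PipelineConfig:
    """Thresholds and knobs for every stage of the small-RNA pipeline.

    Lengths are nucleotides. ``max_pair_gap`` is exclusive: two read
    clusters form a hairpin candidate only when the gap between them is
    strictly below it. ``de_min_abs_log2fc``/``de_alpha`` implement the
    "at least 2-fold change and raw p < alpha" differential-expression
    call; ``target_max_expectation`` is the plant target-site penalty
    cutoff (0 = perfect complementarity).
    """

    adapter: str = DEFAULT_ADAPTER
    min_adapter_overlap: int = 8
    read_len_min: int = 18
    read_len_max: int = 30
    mirna_len_min: int = 20
    mirna_len_max: int = 24
    cluster_upstream_flank: int = 3
    cluster_downstream_flank: int = 5
    max_pair_gap: int = 150
    # clusters entering arm pairing need at least this many reads;
    # singleton clusters are degradation background, not miRNA arms
    min_cluster_total: int = 5
    de_min_abs_log2fc: float = 1.0
    de_alpha: float = 0.05
    target_max_expectation: float = 2.0
    hspsize: int = 20
    central_mismatch_range: Tuple[int, int] = (9, 11)
    flank_up: int = 17
    flank_down: int = 13
    keygene_fold_cutoff: float = 2.0
    enrichment_alpha: float = 0.05
    rng_seed: int = 0

    def validate(self) -> "PipelineConfig":
        if self.min_adapter_overlap < 1:
            raise ValueError("min_adapter_overlap must be >= 1")
        for lo, hi, name in (
            (self.read_len_min, self.read_len_max, "read_len"),
            (self.mirna_len_min, self.mirna_len_max, "mirna_len"),
        ):
            if lo < 0 or lo > hi:
                raise ValueError(f"{name} range invalid: [{lo}, {hi}]")
        if self.cluster_upstream_flank < 0 or self.cluster_downstream_flank < 0:
            raise ValueError("cluster flanks must be >= 0")
        if self.max_pair_gap < 0:
            raise ValueError("max_pair_gap must be >= 0")
        for a, name in ((self.de_alpha, "de_alpha"), (self.enrichment_alpha, "enrichment_alpha")):
            if not (0.0 < a < 1.0):
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.flank_up < 0 or self.flank_down < 0:
            raise ValueError("flanks must be >= 0")
        lo, hi = self.central_mismatch_range
        if lo > hi or lo < 1:
            raise ValueError("central_mismatch_range invalid")
        return self

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "central_mismatch_range" in data:
            data["central_mismatch_range"] = tuple(data["central_mismatch_range"])
        return cls(**data).validate()

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        data["central_mismatch_range"] = list(self.central_mismatch_range)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)
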