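"""Pipeline-wide thresholds, collected in one place.

Defaults follow the analysis conventions this package implements: family
edges need alignment coverage strictly above 0.60, young duplicates need
intra-species identity strictly above 0.90, Ks values are retained below
saturation (< 1), Ks histograms use 0.1 bins, chromosomes are profiled in
1-Mb windows, collinear blocks need at least 5 anchors with rank gaps of at
most 25, and bootstrap support must exceed 50 out of 1000 replicates.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    # similarity search
    match_score: float = 2.0
    mismatch_score: float = -3.0
    gap_open: float = 5.0
    gap_extend: float = 2.0
    min_score: float = 100.0
    kmer_size: int = 12
    min_shared_kmers: int = 3
    coverage_denominator: str = "shorter"  # or "query"
    # family building
    min_coverage: float = 0.60
    min_identity: float = 0.90
    identity_scope: str = "intraspecies"  # or "family"
    # orthogroup surrogate
    ortho_factor: float = 0.5
    # evolutionary statistics
    ks_retain_max: float = 1.0
    ks_bin_width: float = 0.1
    gap_policy: str = "pairwise"  # pairwise deletion of gapped codon columns
    # windows
    window_size: int = 1_000_000
    # collinearity / duplication typing
    min_anchors: int = 5
    max_gap: int = 25
    tandem_max_gap: int = 0
    proximal_max_gap: int = 10
    proximal_as_tandem: bool = False
    # trees
    bootstrap_reps: int = 1000
    min_support: float = 50.0

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
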