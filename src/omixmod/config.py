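"""Run configuration: input paths plus every tunable downstream parameter.

Defaults follow the study design this pipeline reproduces: stage-1 selection at
FDR 0.05, stage-2 stepwise at alpha 0.05 with R-squared > 0.6, volcano curve
c = 3.65 / x0 = 1.75, tryptic peptide length window 7-30 aa, mean-TPM > 1
transcript filter, k-mer enrichment at adjusted p < 0.05, stability estimation
with linear bias mode at 0.99 stringency, and polysome thresholds
|log2FC| >= 1 at FDR 0.1.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import yaml

from .containers import OmixError


@dataclass
class RunConfig:
    # --- input paths (optional; the simulate subcommand fills them in) ---
    rna_tpm: str | None = None
    rna_counts: str | None = None
    rna_meta: str | None = None
    protein_batches: list[str] = field(default_factory=list)
    protein_meta: str | None = None
    protein_fasta: str | None = None
    transcript_fasta: str | None = None
    mapping: str | None = None
    gene_lists: dict[str, str] = field(default_factory=dict)
    exon_counts: str | None = None
    intron_counts: str | None = None
    exin_meta: str | None = None
    polysome_counts: str | None = None
    polysome_meta: str | None = None
    coding_list: str | None = None
    bridge_channels: dict[str, str] = field(default_factory=dict)

    # --- integration ---
    tpm_pseudocount: float = 1.0
    protein_pseudocount: float = 0.0

    # --- module discovery ---
    stage1_fdr: float = 0.05
    stage2_alpha: float = 0.05
    r2_min: float = 0.6
    poly_degree: int = 2
    k_min: int = 4
    k_max: int = 15
    gap_bootstraps: int = 50
    min_module_size: int = 0  # optional post-filter, off by default

    # --- proteomics ---
    digest_min_len: int = 7
    digest_max_len: int = 30
    missed_cleavages: int = 0
    proline_rule: bool = True
    volcano_c: float = 3.65
    volcano_x0: float = 1.75
    volcano_form: str = "as_printed"

    # --- transcript features / enrichment ---
    min_mean_tpm: float = 1.0
    kmer_ks: tuple = (6, 7)
    enrich_alpha: float = 0.05
    pairwise_alpha: float = 0.01

    # --- stability / polysome ---
    stability_stringency: float = 0.99
    polysome_min_reads: int = 2
    polysome_min_samples: int = 2
    polysome_lfc: float = 1.0
    polysome_fdr: float = 0.1

    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "stage1_fdr", "stage2_alpha", "r2_min", "volcano_c", "volcano_x0",
            "min_mean_tpm", "enrich_alpha", "stability_stringency",
            "polysome_lfc", "polysome_fdr",
        ):
            v = getattr(self, name)
            if not (v == v and abs(v) != float("inf")):
                raise OmixError(f"config parameter {name} must be finite, got {v}")
        if self.k_min < 2 or self.k_max < self.k_min:
            raise OmixError("need 2 <= k_min <= k_max")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["kmer_ks"] = list(self.kmer_ks)
        return d

    def hash(self) -> str:
        """Short stable digest of all parameters, recorded in every output."""
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise OmixError(f"unknown config keys: {sorted(unknown)}")
        if "kmer_ks" in data:
            data["kmer_ks"] = tuple(data["kmer_ks"])
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
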