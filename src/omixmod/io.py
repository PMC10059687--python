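"""Readers and writers for the pipeline's external formats.

Everything on disk is plain text: dense TSV matrices with a single header row,
FASTA sequence files (read through Biopython), one-id-per-line gene lists and
a YAML run configuration.  All sequence handling is internally in the DNA
alphabet (U mapped to T); coordinates are 0-based half-open.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .containers import ExpressionMatrix, OmixError, TranscriptModel, validate_meta

log = logging.getLogger("omixmod")

REGIONS = ("utr5", "cds", "utr3")


def read_meta_tsv(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype=str).set_index("sample_id")
    if "day" in meta.columns:
        meta["day"] = pd.to_numeric(meta["day"])
    return validate_meta(meta)


def read_expression_tsv(path, meta_path, unit: str) -> ExpressionMatrix:
    """Read a genes x samples TSV plus its sample-metadata TSV.

    The first column of the matrix file holds feature ids; remaining column
    headers are sample ids that must each appear in the metadata file.  Columns
    are returned in metadata order.  Non-numeric cells are a hard error.
    """
    meta = read_meta_tsv(meta_path)
    raw = pd.read_csv(path, sep="\t", index_col=0)
    raw.index = raw.index.astype(str)
    missing = [c for c in raw.columns if c not in meta.index]
    if missing:
        raise OmixError(f"matrix columns missing from metadata: {missing}")
    try:
        raw = raw.astype(float)
    except (TypeError, ValueError) as exc:
        raise OmixError(f"unparseable numeric cell in {path}: {exc}") from exc
    order = [s for s in meta.index if s in raw.columns]
    return ExpressionMatrix(raw[order], meta.loc[order], unit)


def write_expression_tsv(matrix: ExpressionMatrix, path, meta_path=None) -> None:
    out = matrix.values.copy()
    out.index.name = "feature_id"
    out.to_csv(path, sep="\t", float_format="%.10g")
    if meta_path is not None:
        write_meta_tsv(matrix.meta, meta_path)


def write_meta_tsv(meta: pd.DataFrame, path) -> None:
    out = meta.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def _normalize_seq(seq: str) -> tuple[str, bool]:
    s = str(seq).upper()
    was_rna = "U" in s
    return s.replace("U", "T"), was_rna


def read_transcript_fasta(path, gene_map: dict | None = None) -> dict[str, TranscriptModel]:
    """Read transcript regions from FASTA records named ``<transcript_id>|<region>``.

    Region must be one of ``utr5``, ``cds``, ``utr3``.  A transcript missing a
    UTR record gets an empty string for that region with the gap flagged; a CDS
    whose length is not a multiple of 3 is flagged (annotation dialects vary)
    but not rejected.  ``gene_map`` optionally maps transcript id -> gene id
    (defaults to the transcript id itself).
    """
    regions: dict[str, dict[str, str]] = {}
    rna_flags: dict[str, bool] = {}
    order: list[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        name = rec.id
        if "|" not in name:
            raise OmixError(f"FASTA record {name!r} not named <transcript_id>|<region>")
        tid, region = name.rsplit("|", 1)
        if region not in REGIONS:
            raise OmixError(f"FASTA record {name!r} has unknown region {region!r}")
        seq, was_rna = _normalize_seq(str(rec.seq))
        if tid not in regions:
            regions[tid] = {}
            order.append(tid)
        if region in regions[tid]:
            raise OmixError(f"duplicate region {region!r} for transcript {tid!r}")
        regions[tid][region] = seq
        rna_flags[tid] = rna_flags.get(tid, False) or was_rna
    models: dict[str, TranscriptModel] = {}
    for tid in order:
        recs = regions[tid]
        missing = tuple(r for r in REGIONS if r not in recs)
        if "cds" in missing:
            raise OmixError(f"transcript {tid!r} has no CDS record")
        cds = recs.get("cds", "")
        frame_warn = len(cds) % 3 != 0
        if frame_warn:
            log.warning("transcript %s: CDS length %d not divisible by 3", tid, len(cds))
        if missing:
            log.warning("transcript %s: missing region(s) %s", tid, ",".join(missing))
        models[tid] = TranscriptModel(
            transcript_id=tid,
            gene_id=(gene_map or {}).get(tid, tid),
            utr5=recs.get("utr5", ""),
            cds=cds,
            utr3=recs.get("utr3", ""),
            was_rna_alphabet=rna_flags[tid],
            missing_regions=missing,
            cds_frame_warning=frame_warn,
        )
    return models


def write_transcript_fasta(models, path) -> None:
    with open(path, "w") as fh:
        for m in models.values() if isinstance(models, dict) else models:
            for region in REGIONS:
                seq = getattr(m, region)
                if seq:
                    fh.write(f">{m.transcript_id}|{region}\n{seq}\n")


def read_protein_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_protein_fasta(seqs: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for pid, seq in seqs.items():
            fh.write(f">{pid}\n{seq}\n")


def read_gene_list(path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip() and not line.startswith("#")]


def write_gene_list(genes, path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in genes))


def read_mapping_tsv(path) -> pd.DataFrame:
    """Gene <-> protein id mapping table with columns gene_id, protein_id."""
    mapping = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("gene_id", "protein_id"):
        if col not in mapping.columns:
            raise OmixError(f"mapping file missing column {col!r}")
    return mapping[["gene_id", "protein_id"]]
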