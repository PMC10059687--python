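"""RNA-protein integration: aggregation, z-scoring, joining, PCA.

RNA-seq TPM and normalized reporter intensities live on incommensurable
scales; a PCA on the raw combination is dominated by platform, not biology.
Gene-by-gene z-scoring of log10 abundances within each assay removes the unit
mismatch so the combined matrix groups by cell class and developmental age.
Z-scores are computed per assay across all of that assay's samples jointly
(classes, days and batches pooled).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, IntegratedMatrix, OmixError

log = logging.getLogger("omixmod")


def aggregate_tpm_by_protein(tpm: ExpressionMatrix, mapping: pd.DataFrame) -> ExpressionMatrix:
    """Sum TPM rows of genes that encode the same protein; re-key by protein id.

    Genes absent from the mapping are dropped (and counted in the log) — a
    transcript with no detected protein product cannot enter the joined matrix.
    """
    mapping = mapping.drop_duplicates()
    mapped = mapping[mapping["gene_id"].isin(tpm.values.index)]
    n_dropped = len(set(tpm.feature_ids) - set(mapped["gene_id"]))
    if n_dropped:
        log.info("aggregate_tpm_by_protein: %d unmapped genes dropped", n_dropped)
    rows = tpm.values.loc[mapped["gene_id"]]
    rows.index = pd.Index(mapped["protein_id"], name="protein_id")
    summed = rows.groupby(level=0, sort=True).sum()
    return ExpressionMatrix(summed, tpm.meta, tpm.unit)


def zscore_rows(m: ExpressionMatrix, pseudocount: float = 0.0) -> tuple[ExpressionMatrix, frozenset]:
    """Per-row z = (log10(v + pseudocount) - mean) / sd, sd with n-1 denominator.

    Rows with zero variance are emitted as all-zero and returned in the
    constant-row set.
    """
    arr = np.log10(m.values.to_numpy(dtype=float) + pseudocount)
    if not np.all(np.isfinite(arr)):
        raise OmixError("log10 produced non-finite values; check pseudocount")
    mu = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, ddof=1, keepdims=True)
    const = sd[:, 0] == 0
    sd[const] = 1.0
    z = (arr - mu) / sd
    z[const] = 0.0
    constant = frozenset(m.values.index[const])
    if constant:
        log.info("zscore_rows: %d constant rows flagged", len(constant))
    out = ExpressionMatrix(pd.DataFrame(z, index=m.values.index, columns=m.values.columns),
                           m.meta, "zscore")
    return out, constant


def combine_omics(
    rna_z: ExpressionMatrix,
    prot_z: ExpressionMatrix,
    mapping: pd.DataFrame | None = None,
    constant_rows: frozenset = frozenset(),
) -> IntegratedMatrix:
    """Join the z-scored assays by protein id, keeping only shared genes."""
    for name, m in (("rna", rna_z), ("protein", prot_z)):
        if m.unit != "zscore":
            raise OmixError(f"{name} input to combine_omics must be z-scored")
        if m.values.index.has_duplicates:
            raise OmixError(f"duplicate protein id in {name} input")
    shared = rna_z.values.index.intersection(prot_z.values.index)
    n_rna_only = len(rna_z.values.index) - len(shared)
    n_prot_only = len(prot_z.values.index) - len(shared)
    if len(shared) == 0:
        raise OmixError("no genes in common between the two assays")
    log.info("combine_omics: %d integrated, %d rna-only, %d protein-only",
             len(shared), n_rna_only, n_prot_only)
    values = pd.concat([rna_z.values.loc[shared], prot_z.values.loc[shared]], axis=1)
    meta = pd.concat([rna_z.meta, prot_z.meta])
    if mapping is not None:
        gene_map = mapping[mapping["protein_id"].isin(shared)][["protein_id", "gene_id"]]
    else:
        gene_map = pd.DataFrame({"protein_id": shared, "gene_id": shared})
    return IntegratedMatrix(values, meta, gene_map.reset_index(drop=True),
                            constant_rows=frozenset(constant_rows) & set(shared))


def pca_scores(m: IntegratedMatrix, n_components: int = 2):
    """PCA of samples over the integrated gene space.

    Returns (scores: samples x components, loadings: genes x components,
    variance fractions).  Components are ordered by decreasing explained
    variance; each component's sign is fixed so its largest-magnitude gene
    loading is positive.
    """
    X = m.values.to_numpy(dtype=float).T  # samples x genes
    n_components = min(n_components, min(X.shape))
    Xc = X - X.mean(axis=0, keepdims=True)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = S**2 / (X.shape[0] - 1)
    frac = var / var.sum()
    signs = np.sign(Vt[np.arange(Vt.shape[0]), np.abs(Vt).argmax(axis=1)])
    signs[signs == 0] = 1.0
    Vt = Vt * signs[:, None]
    U = U * signs[None, : U.shape[1]]
    scores = pd.DataFrame(
        (U * S)[:, :n_components], index=m.values.columns,
        columns=[f"PC{i+1}" for i in range(n_components)],
    )
    loadings = pd.DataFrame(
        Vt[:n_components].T, index=m.values.index,
        columns=[f"PC{i+1}" for i in range(n_components)],
    )
    return scores, loadings, frac[:n_components]
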