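"""End-to-end orchestration: dataset on disk in, result tables out.

``run_pipeline`` reads every input named in the :class:`~omixmod.config.RunConfig`,
runs proteomics normalization, integration, module discovery, transcript
feature analysis, enrichment, stability estimation and polysome statistics,
and writes one TSV per stage into the output directory.  Every output file
carries the configuration hash and seed on a leading comment line, and
``run_info.json`` records the per-stage gene accounting (total = clustered +
not-clustered + not-fit + dropped).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import enrich, features, integrate, io, proteomics, translation
from .config import RunConfig
from .containers import OmixError
from .modules import discover_modules
from .simulate import MultiomicsData, SimParams, generate_exon_intron, \
    generate_multiomics, generate_polysome, generate_sequences

log = logging.getLogger("omixmod")


def _write_table(df: pd.DataFrame, path: Path, config: RunConfig, index_label="gene_id"):
    with open(path, "w") as fh:
        fh.write(f"# omixmod config={config.hash()} seed={config.seed}\n")
        df.to_csv(fh, sep="\t", index_label=index_label, float_format="%.10g")


def read_output_table(path, index_col=0) -> pd.DataFrame:
    """Read back a pipeline output TSV (skipping the provenance comment)."""
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)


def modules_by_gene(module_table: pd.DataFrame, gene_map: pd.DataFrame) -> pd.Series:
    """Translate protein-keyed module labels to gene ids via the mapping."""
    lab = module_table["label"]
    merged = gene_map.merge(lab.rename("label"), left_on="protein_id", right_index=True)
    return merged.set_index("gene_id")["label"]


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise OmixError(f"stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Run every stage the configuration has inputs for; return a results dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    results: dict = {"config_hash": config.hash(), "seed": config.seed}
    info: dict = {"config": config.to_dict(), "config_hash": config.hash(),
                  "seed": config.seed, "stages": {}}

    # --- proteomics normalization -----------------------------------------
    tpm = io.read_expression_tsv(config.rna_tpm, config.rna_meta, "tpm")
    mapping = io.read_mapping_tsv(config.mapping)
    protein_seqs = io.read_protein_fasta(config.protein_fasta)
    digest = proteomics.DigestParams(
        min_len=config.digest_min_len, max_len=config.digest_max_len,
        missed_cleavages=config.missed_cleavages, proline_rule=config.proline_rule)
    pep_counts = {pid: proteomics.count_observable_peptides(s, digest)
                  for pid, s in protein_seqs.items()}
    batches = {name: io.read_expression_tsv(path, config.protein_meta, "reporter_intensity")
               for name, path in zip_batch_names(config.protein_batches)}
    bridge = dict(config.bridge_channels)
    protein = _stage("proteomics_norm")(proteomics.normalize_protein_abundance)(
        batches, pep_counts, bridge)
    info["stages"]["proteomics"] = {"proteins": len(protein.feature_ids),
                                    "channels": len(protein.sample_ids)}

    # --- integration -------------------------------------------------------
    agg = _stage("integration")(integrate.aggregate_tpm_by_protein)(tpm, mapping)
    rna_z, const_rna = integrate.zscore_rows(agg, pseudocount=config.tpm_pseudocount)
    prot_z, const_prot = integrate.zscore_rows(protein, pseudocount=config.protein_pseudocount)
    integrated = _stage("integration")(integrate.combine_omics)(
        rna_z, prot_z, mapping, const_rna | const_prot)
    _write_table(integrated.values, outdir / "integrated_zscores.tsv", config, "protein_id")
    info["stages"]["integration"] = {
        "rna_features": len(rna_z.feature_ids), "protein_features": len(prot_z.feature_ids),
        "integrated": len(integrated.values)}

    # --- module discovery --------------------------------------------------
    disc = _stage("module_discovery")(discover_modules)(
        integrated, fdr=config.stage1_fdr, alpha=config.stage2_alpha,
        r2_min=config.r2_min, degree=config.poly_degree,
        k_range=(config.k_min, config.k_max), gap_B=config.gap_bootstraps,
        min_module_size=config.min_module_size, rng=rng)
    _write_table(disc.table, outdir / "module_table.tsv", config, "protein_id")
    counts = disc.counts
    assert counts["total"] == counts["clustered"] + counts["not_clustered"] \
        + counts["not_fit"] + counts["dropped"], "stage bookkeeping identity violated"
    info["stages"]["module_discovery"] = dict(counts)
    if disc.k_selection is not None:
        info["stages"]["module_discovery"]["k"] = disc.k_selection.k
        info["stages"]["module_discovery"]["k_votes"] = disc.k_selection.votes
    results["modules"] = disc

    gene_labels = modules_by_gene(disc.table, integrated.gene_map)
    clustered = gene_labels[gene_labels.str.fullmatch(r"\d+")]

    # --- transcript features ----------------------------------------------
    transcripts = io.read_transcript_fasta(config.transcript_fasta)
    ftab = _stage("transcript_features")(features.feature_table)(
        transcripts, tpm, min_mean_tpm=config.min_mean_tpm)
    _write_table(ftab, outdir / "feature_table.tsv", config, "transcript_id")
    results["features"] = ftab
    pairwise = {}
    if len(clustered.unique()) >= 2:
        for feat in ("kozak_score", "uorf_count", "len_utr5", "are_density"):
            P, marks = features.pairwise_module_tests(
                ftab, clustered, feat, alpha=config.pairwise_alpha)
            _write_table(P, outdir / f"pairwise_{feat}.tsv", config, "module")
            pairwise[feat] = P
    results["pairwise"] = pairwise
    info["stages"]["features"] = {"transcripts": len(ftab)}

    # --- enrichment ---------------------------------------------------------
    utr3 = {t.gene_id: t.utr3 for t in transcripts.values()}
    kmer_tables = []
    bg = [utr3[g] for g in clustered.index if g in utr3]
    for k in config.kmer_ks:
        for mod in sorted(clustered.unique(), key=int):
            fg = [utr3[g] for g in clustered.index[clustered == mod] if g in utr3]
            kt = enrich.kmer_enrichment(fg, bg, k=int(k), alpha=config.enrich_alpha)
            kt = kt.assign(module=mod, k=int(k))
            kmer_tables.append(kt[kt["adj_p"] < config.enrich_alpha])
    kmer_all = pd.concat(kmer_tables) if kmer_tables else pd.DataFrame()
    _write_table(kmer_all, outdir / "kmer_enrichment.tsv", config, "kmer")
    results["kmer"] = kmer_all

    gene_sets = {name: set(io.read_gene_list(path))
                 for name, path in config.gene_lists.items()}
    if gene_sets and len(clustered):
        ora = _stage("enrichment")(enrich.set_overrepresentation)(gene_sets, clustered)
        _write_table(ora, outdir / "ora.tsv", config, index_label=None)
        results["ora"] = ora
    info["stages"]["enrichment"] = {"significant_kmers": len(kmer_all)}

    # --- stability ----------------------------------------------------------
    if config.exon_counts and config.intron_counts:
        meta_path = config.exin_meta or config.rna_meta
        exon = io.read_expression_tsv(config.exon_counts, meta_path, "raw_count")
        intron = io.read_expression_tsv(config.intron_counts, meta_path, "raw_count")
        stab = _stage("stability")(translation.stability_estimates)(
            exon, intron, stringency=config.stability_stringency)
        _write_table(stab.scores, outdir / "stability.tsv", config)
        results["stability"] = stab
        info["stages"]["stability"] = {"genes_scored": len(stab.scores)}

    # --- polysome -----------------------------------------------------------
    if config.polysome_counts:
        poly = io.read_expression_tsv(config.polysome_counts, config.polysome_meta, "raw_count")
        coding = set(io.read_gene_list(config.coding_list)) if config.coding_list \
            else set(poly.feature_ids)
        filtered = translation.filter_polysome_genes(
            poly, coding, min_reads=config.polysome_min_reads,
            min_samples=config.polysome_min_samples)
        da = _stage("polysome")(translation.differential_association)(
            filtered, lfc_threshold=config.polysome_lfc, fdr=config.polysome_fdr)
        _write_table(da, outdir / "polysome_da.tsv", config, index_label=None)
        results["polysome_da"] = da
        shift = {}
        top_list = config.gene_lists.get("top_classical")
        if top_list:
            res = translation.polysome_shift_test(
                filtered, io.read_gene_list(top_list))
            shift = {k: v for k, v in res.items() if k != "per_gene"}
            _write_table(res["per_gene"], outdir / "polysome_shift.tsv", config)
            results["shift"] = res
        info["stages"]["polysome"] = {
            "genes_tested": filtered.values.shape[0],
            "dags": int(da["dag_flag"].sum()), **shift}

    with open(outdir / "run_info.json", "w") as fh:
        json.dump(info, fh, indent=2, default=str)
    results["info"] = info
    return results


def integrate_multiomics(data: MultiomicsData, peptide_counts: dict | None = None,
                         tpm_pseudocount: float = 1.0):
    """Normalize, z-score and join an in-memory synthetic dataset.

    Convenience wrapper over the proteomics + integration stages for callers
    that work with :class:`~omixmod.simulate.MultiomicsData` directly.  When
    ``peptide_counts`` is omitted a uniform count is used (the bridge ratio
    cancels it anyway).
    """
    if peptide_counts is None:
        peptide_counts = {p: 10 for p in data.mapping["protein_id"]}
    prot = proteomics.normalize_protein_abundance(
        data.protein_batches, peptide_counts, data.bridge_channels)
    agg = integrate.aggregate_tpm_by_protein(data.rna_tpm, data.mapping)
    rna_z, c1 = integrate.zscore_rows(agg, pseudocount=tpm_pseudocount)
    prot_z, c2 = integrate.zscore_rows(prot, pseudocount=0.0)
    return integrate.combine_omics(rna_z, prot_z, data.mapping, c1 | c2)


def zip_batch_names(paths):
    for p in paths:
        yield Path(p).stem, p


# ---------------------------------------------------------------------------
# dataset writing (simulate subcommand)


def write_dataset(params: SimParams, outdir, rng: np.random.Generator | None = None) -> RunConfig:
    """Generate the full synthetic dataset, write it to ``outdir`` and return a
    ready-to-run configuration pointing at the files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = rng or np.random.default_rng(params.seed)
    data: MultiomicsData = generate_multiomics(params, rng)
    truth = data.truth
    transcripts, proteins = generate_sequences(truth, params, rng)
    exon, intron = generate_exon_intron(truth, params, rng)
    poly = generate_polysome(truth, params, rng)

    io.write_expression_tsv(data.rna_tpm, outdir / "rna_tpm.tsv", outdir / "rna_meta.tsv")
    io.write_expression_tsv(data.rna_counts, outdir / "rna_counts.tsv")
    prot_meta = pd.concat([m.meta for m in data.protein_batches.values()])
    io.write_meta_tsv(prot_meta, outdir / "protein_meta.tsv")
    batch_paths = []
    for name, mat in data.protein_batches.items():
        p = outdir / f"{name}.tsv"
        io.write_expression_tsv(mat, p)
        batch_paths.append(str(p))
    data.mapping.to_csv(outdir / "mapping.tsv", sep="\t", index=False)
    io.write_transcript_fasta(transcripts, outdir / "transcripts.fa")
    io.write_protein_fasta(proteins, outdir / "proteins.fa")
    io.write_expression_tsv(exon, outdir / "exon_counts.tsv", outdir / "exin_meta.tsv")
    io.write_expression_tsv(intron, outdir / "intron_counts.tsv")
    io.write_expression_tsv(poly, outdir / "polysome_counts.tsv", outdir / "polysome_meta.tsv")

    top = truth.genes_of_template("3")
    n_cl = max(1, int(0.8 * len(top)))
    classical = sorted(rng.choice(top, size=n_cl, replace=False))
    nulls = truth.genes_of_template("null")
    predicted = sorted(top) + sorted(rng.choice(nulls, size=min(15, len(nulls)), replace=False))
    io.write_gene_list(classical, outdir / "top_classical.txt")
    io.write_gene_list(predicted, outdir / "top_predicted.txt")
    io.write_gene_list(truth.table.index, outdir / "coding_genes.txt")
    truth.table.to_csv(outdir / "truth.tsv", sep="\t")

    config = RunConfig(
        rna_tpm=str(outdir / "rna_tpm.tsv"),
        rna_counts=str(outdir / "rna_counts.tsv"),
        rna_meta=str(outdir / "rna_meta.tsv"),
        protein_batches=batch_paths,
        protein_meta=str(outdir / "protein_meta.tsv"),
        protein_fasta=str(outdir / "proteins.fa"),
        transcript_fasta=str(outdir / "transcripts.fa"),
        mapping=str(outdir / "mapping.tsv"),
        gene_lists={"top_classical": str(outdir / "top_classical.txt"),
                    "top_predicted": str(outdir / "top_predicted.txt")},
        exon_counts=str(outdir / "exon_counts.tsv"),
        intron_counts=str(outdir / "intron_counts.tsv"),
        exin_meta=str(outdir / "exin_meta.tsv"),
        polysome_counts=str(outdir / "polysome_counts.tsv"),
        polysome_meta=str(outdir / "polysome_meta.tsv"),
        coding_list=str(outdir / "coding_genes.txt"),
        bridge_channels=dict(data.bridge_channels),
        seed=params.seed,
    )
    config.to_yaml(outdir / "config.yaml")
    return config
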