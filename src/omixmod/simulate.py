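"""Synthetic multi-omics data with planted ground truth.

The generator emulates the study design every downstream stage assumes:
two sorted cell classes (progenitors, neurons) sampled at days 40/60/90/120
across replicate differentiation batches, profiled by RNA-seq (negative-
binomial counts, TPM) and TMT proteomics (log-normal reporter intensities
with per-batch offsets and a pooled bridge channel).  Gene expression follows
nine planted module templates spanning the C/T/A taxonomy — five cell-class-
dominant, two temporal with a protein class offset, and two RNA-protein
discordant — plus unstructured null genes.  Companion generators plant
sequence features (5'TOP starts, Kozak contexts, uORFs, per-module 3'UTR
6-mers, AU-rich pentamers, miRNA seed sites), class-specific decay rates for
exon/intron counts, and a genotype-dependent 5'TOP translation shift for
polysome counts.  The planted truth table is sufficient to score every
downstream stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CELL_CLASSES, DAYS, ExpressionMatrix, OmixError

log = logging.getLogger("omixmod")

_T = np.linspace(0.0, 1.0, 4)  # scaled time over the four sampling days


def _profile(prog, neur):
    return np.vstack([np.asarray(prog, dtype=float), np.asarray(neur, dtype=float)])


_RISE = -1.0 + 2.4 * _T                 # linear rise
_FALL = 1.4 - 2.4 * _T                  # linear fall
_EARLY = -1.0 + 2.4 * np.sqrt(_T)       # saturating early rise
_FLAT_HI = 1.0 + 0 * _T
_FLAT_LO = -1.0 + 0 * _T

#: Nine module templates: id -> (assay, class, day) mean log2 profile.
#: Assay order (rna, protein); class order (progenitor, neuron).  The five
#: class-dominant templates differ in their temporal signatures (flat,
#: saturating onset, progenitor shut-down) so the planted modules are
#: mutually separable after per-gene z-scoring.
TEMPLATES: dict[str, np.ndarray] = {
    # C modules: concordant, cell-class dominant
    "1": np.stack([_profile(_FLAT_HI, _FLAT_LO)] * 2),        # prog-high, flat
    "2": np.stack([_profile(_EARLY, _FLAT_LO)] * 2),          # prog-high onset
    "7": np.stack([_profile(_FLAT_LO, _FLAT_HI)] * 2),        # neuron-high, flat
    "8": np.stack([_profile(_FLAT_LO, _EARLY)] * 2),          # neuron-high onset
    "9": np.stack([_profile(0.8 - 2.8 * _T, 0.8 + 0.6 * _T**2)] * 2),  # prog shut-down
    # T modules: temporal RNA shared by classes, protein class-offset
    "4": np.stack([
        _profile(_FALL, _FALL),
        _profile(_FALL + 0.7, _FALL - 0.7),
    ]),
    "6": np.stack([
        _profile(_RISE, _RISE),
        _profile(_RISE - 0.7, _RISE + 0.7),
    ]),
    # A modules: RNA-protein discordant
    "3": np.stack([                                            # 5'TOP-like
        _profile(1.6 - 1.6 * _T, _FLAT_LO),
        _profile(0.35 - 0.5 * _T, 0.05 - 0.5 * _T),
    ]),
    "5": np.stack([
        _profile(-1.2 + 1.6 * _T, -1.2 + 2.6 * _T),
        _profile(1.1 - 0.5 * _T, -1.1 + 0.5 * _T),
    ]),
}

TOP_TEMPLATE = "3"
ARE_TEMPLATE = "6"
MIRNA_TEMPLATES = ("6", "8")
CLASS_DOMINANT = ("1", "2", "7", "8", "9")
STABILITY_SLOW_NEURON = ("1", "3")   # faster decay in neurons (prog-stable)
STABILITY_SLOW_PROG = ("9",)         # faster decay in progenitors

DEFAULT_PLANTED_KMERS = {
    "1": "TGCATG",
    "2": "TTTGTT",
    "7": "ACACAC",
    "8": "GGACTA",
    "9": "CCGCGG",
}


@dataclass
class SimParams:
    """All knobs of the generators; the defaults are the study conditions."""

    n_genes_per_template: int = 100
    n_null_genes: int = 300
    n_unmapped_genes: int = 10
    n_batches: int = 3
    days: tuple = DAYS

    # RNA assay
    rna_dispersion: float = 0.1        # NB dispersion; 0 -> noiseless limit
    rna_depth: float = 1e6
    library_sigma: float = 0.1
    tpm_base_log_mean: float = np.log(30.0)
    tpm_base_log_sigma: float = 1.0

    # protein assay
    protein_sigma: float = 0.25        # log-normal channel noise (natural log)
    batch_sigma: float = 0.5           # per-batch offset (natural log)
    protein_base_log_mean: float = np.log(1e4)
    protein_base_log_sigma: float = 1.0
    tmt_compression: float = 1.0       # multiplicative ratio compression; 1 = off

    amplitude: float = 1.0             # log2 units per template unit

    # sequences
    planted_kmers: dict = field(default_factory=lambda: dict(DEFAULT_PLANTED_KMERS))
    kmer_copies: int = 3
    are_rate: float = 4.0              # planted ATTTA pentamers in the ARE module
    mirna_seeds: tuple = ("AAGGCAC",)
    mirna_copies: int = 2
    top_run_min: int = 5
    top_run_max: int = 12

    # exon/intron
    decay_base: float = 0.2            # 1/hour
    decay_fold: float = 2.0            # planted between-class decay ratio
    exin_dispersion: float = 0.05
    intron_fraction: float = 0.1
    intron_slope_range: tuple = (0.85, 1.15)

    # polysome
    polysome_reps: int = 3
    polysome_base_log_mean: float = np.log(200.0)
    polysome_base_log_sigma: float = 1.0
    polysome_dispersion: float = 0.05
    translation_shift: float = 1.0     # log2 high-polysome shift for TOP genes
    fraction_scale: dict = field(default_factory=lambda: {
        "monosome": 1.0, "low_poly": 1.3, "high_poly": 1.6})

    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes_per_template <= 0 or self.n_batches <= 0:
            raise OmixError("counts must be positive")
        if self.rna_dispersion < 0 or self.protein_sigma < 0:
            raise OmixError("noise parameters must be >= 0")
        kmers = list(self.planted_kmers.values())
        if len(set(kmers)) != len(kmers):
            raise OmixError("planted 6-mers collide between templates")

    @property
    def noiseless(self) -> bool:
        return self.rna_dispersion == 0 and self.protein_sigma == 0

    @property
    def n_genes(self) -> int:
        return (len(TEMPLATES) * self.n_genes_per_template
                + self.n_null_genes + self.n_unmapped_genes)


@dataclass
class SyntheticTruth:
    """Planted ground truth: the acceptance oracle for every stage."""

    table: pd.DataFrame            # indexed by gene_id
    planted_kmers: dict
    mirna_templates: tuple = MIRNA_TEMPLATES
    k_true: int = len(TEMPLATES)

    def genes_of_template(self, template: str) -> list[str]:
        return list(self.table.index[self.table["template"] == str(template)])

    @property
    def top_genes(self) -> list[str]:
        return list(self.table.index[self.table["top_flag"]])

    def protein_of(self, genes) -> list[str]:
        return list(self.table.loc[list(genes), "protein_id"].dropna())


@dataclass
class MultiomicsData:
    rna_tpm: ExpressionMatrix
    rna_counts: ExpressionMatrix
    protein_batches: dict
    bridge_channels: dict
    mapping: pd.DataFrame
    truth: SyntheticTruth


def build_truth(params: SimParams, rng: np.random.Generator) -> SyntheticTruth:
    rows = []
    gi = 0

    def gene_id():
        nonlocal gi
        gi += 1
        return f"g{gi:05d}"

    for tpl in TEMPLATES:
        for _ in range(params.n_genes_per_template):
            g = gene_id()
            rows.append({
                "gene_id": g, "protein_id": f"P_{g}", "template": tpl, "mapped": True,
                "kozak_class": "strong" if tpl in ("3", "4", "5") else "weak",
                "uorf_planted": 0,
                "top_flag": tpl == TOP_TEMPLATE,
                "are_class": "high" if tpl == ARE_TEMPLATE else "background",
                "planted_kmer": params.planted_kmers.get(tpl, ""),
            })
    for _ in range(params.n_null_genes):
        g = gene_id()
        rows.append({
            "gene_id": g, "protein_id": f"P_{g}", "template": "null", "mapped": True,
            "kozak_class": "weak", "uorf_planted": 0, "top_flag": False,
            "are_class": "background", "planted_kmer": "",
        })
    for _ in range(params.n_unmapped_genes):
        g = gene_id()
        rows.append({
            "gene_id": g, "protein_id": pd.NA, "template": "null", "mapped": False,
            "kozak_class": "weak", "uorf_planted": 0, "top_flag": False,
            "are_class": "background", "planted_kmer": "",
        })
    table = pd.DataFrame(rows).set_index("gene_id")

    # planted uORF counts for scrubbed-UTR templates (A/T modules, few uORFs)
    scrubbed = table["template"].isin(["3", "4", "5"])
    lam = np.where(table["template"] == TOP_TEMPLATE, 0.3, 1.0)
    planted = rng.poisson(lam)
    table["uorf_planted"] = np.where(scrubbed, planted, 0)

    # class-specific decay rates
    base = params.decay_base
    decay_p = np.full(len(table), base)
    decay_n = np.full(len(table), base)
    slow_n = table["template"].isin(STABILITY_SLOW_NEURON)
    slow_p = table["template"].isin(STABILITY_SLOW_PROG)
    decay_n[slow_n] = base * params.decay_fold
    decay_p[slow_p] = base * params.decay_fold
    table["decay_progenitor"] = decay_p
    table["decay_neuron"] = decay_n
    table["translation_shift"] = np.where(table["top_flag"], params.translation_shift, 0.0)
    return SyntheticTruth(table=table, planted_kmers=dict(params.planted_kmers))


def _template_log2(truth: SyntheticTruth, assay: str, params: SimParams) -> np.ndarray:
    """Genes x (class, day) planted log2 deviation for one assay."""
    a = 0 if assay == "rna" else 1
    out = np.zeros((len(truth.table), 2, 4))
    for tpl, prof in TEMPLATES.items():
        mask = (truth.table["template"] == tpl).to_numpy()
        out[mask] = prof[a] * params.amplitude
    return out


def _nb_sample(rng, mu, dispersion):
    if dispersion == 0:
        return mu.copy()
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mu * dispersion)
    return rng.poisson(lam).astype(float)


def generate_multiomics(params: SimParams, rng: np.random.Generator | None = None) -> MultiomicsData:
    """RNA (counts + TPM) and per-batch TMT reporter matrices with truth."""
    rng = rng or np.random.default_rng(params.seed)
    if params.n_batches < 1:
        raise OmixError("need at least one replicate batch (design unestimable)")
    truth = build_truth(params, rng)
    genes = list(truth.table.index)
    n = len(genes)

    tpm_base = np.exp(rng.normal(params.tpm_base_log_mean, params.tpm_base_log_sigma, n))
    rna_t = _template_log2(truth, "rna", params)

    rna_cols, rna_meta = {}, {}
    noiseless = params.rna_dispersion == 0
    for b in range(1, params.n_batches + 1):
        for ci, cls in enumerate(CELL_CLASSES):
            for di, day in enumerate(params.days):
                sid = f"rna_{cls}_d{day}_b{b}"
                lib = 1.0 if noiseless else np.exp(rng.normal(0, params.library_sigma))
                mu_tpm = tpm_base * 2 ** rna_t[:, ci, di]
                mu_counts = mu_tpm / 1e6 * params.rna_depth * lib
                rna_cols[sid] = _nb_sample(rng, mu_counts, params.rna_dispersion)
                rna_meta[sid] = {"cell_class": cls, "day": day, "batch": f"b{b}",
                                 "assay": "rna", "fraction": pd.NA, "genotype": pd.NA}
    counts_df = pd.DataFrame(rna_cols, index=genes)
    meta_df = pd.DataFrame(rna_meta).T
    meta_df.index.name = "sample_id"
    if noiseless:
        # noiseless limit: TPM reduces exactly to the template equations
        tpm_df = pd.DataFrame(
            {sid: tpm_base * 2 ** rna_t[:, list(CELL_CLASSES).index(m["cell_class"]),
                                        list(params.days).index(m["day"])]
             for sid, m in rna_meta.items()}, index=genes)
    else:
        tpm_df = counts_df / counts_df.sum(axis=0) * 1e6
    rna_counts = ExpressionMatrix(counts_df, meta_df, "raw_count")
    rna_tpm = ExpressionMatrix(tpm_df, meta_df, "tpm")

    # protein: only mapped genes are detected on the proteome
    mapped = truth.table["mapped"].to_numpy()
    prot_ids = truth.table.loc[mapped, "protein_id"].tolist()
    prot_base = np.exp(rng.normal(params.protein_base_log_mean,
                                  params.protein_base_log_sigma, int(mapped.sum())))
    prot_t = _template_log2(truth, "protein", params)[mapped]

    batches, bridges = {}, {}
    for b in range(1, params.n_batches + 1):
        bname = f"batch{b}"
        offset = 1.0 if params.protein_sigma == 0 else np.exp(rng.normal(0, params.batch_sigma))
        cols, meta = {}, {}
        for ci, cls in enumerate(CELL_CLASSES):
            for di, day in enumerate(params.days):
                sid = f"prot_{cls}_d{day}_b{b}"
                signal = prot_t[:, ci, di] * params.tmt_compression
                noise = (0.0 if params.protein_sigma == 0
                         else rng.normal(0, params.protein_sigma, len(prot_ids)))
                cols[sid] = prot_base * 2**signal * np.exp(noise) * offset
                meta[sid] = {"cell_class": cls, "day": day, "batch": bname,
                             "assay": "protein", "fraction": pd.NA, "genotype": pd.NA}
        vals = pd.DataFrame(cols, index=prot_ids)
        bridge_id = f"prot_bridge_b{b}"
        vals[bridge_id] = vals.mean(axis=1)  # pooled mix of all samples
        meta[bridge_id] = {"cell_class": pd.NA, "day": pd.NA, "batch": bname,
                           "assay": "protein", "fraction": pd.NA, "genotype": pd.NA}
        mdf = pd.DataFrame(meta).T
        mdf.index.name = "sample_id"
        batches[bname] = ExpressionMatrix(vals, mdf, "reporter_intensity")
        bridges[bname] = bridge_id

    mapping = truth.table.loc[mapped].reset_index()[["gene_id", "protein_id"]]
    return MultiomicsData(rna_tpm=rna_tpm, rna_counts=rna_counts,
                          protein_batches=batches, bridge_channels=bridges,
                          mapping=mapping, truth=truth)


# ---------------------------------------------------------------------------
# sequences


_PYR = "CT"
AA20 = "ACDEFGHILMNQSTVWY"  # without K, R, P (handled separately)


def _random_seq(rng, length: int) -> np.ndarray:
    return rng.integers(0, 4, size=max(0, length))


def _to_str(arr) -> str:
    return "".join("ACGT"[i] for i in arr)


def _scrub_uorfs(seq: list, rng) -> list:
    """Remove all [ACT]TG occurrences by re-rolling the G (iterate to fixpoint)."""
    s = list(seq)
    changed = True
    while changed:
        changed = False
        for i in range(len(s) - 2):
            if s[i] in "ACT" and s[i + 1] == "T" and s[i + 2] == "G":
                s[i + 2] = "ACT"[rng.integers(0, 3)]
                changed = True
    return s


def _plant(seq: list, motif: str, copies: int, rng, lo: int = 0) -> list:
    s = list(seq)
    if len(s) - lo < len(motif):
        return s
    for _ in range(copies):
        pos = int(rng.integers(lo, len(s) - len(motif) + 1))
        s[pos : pos + len(motif)] = list(motif)
    return s


_COMP = str.maketrans("ACGT", "TGCA")


def generate_sequences(truth: SyntheticTruth, params: SimParams,
                       rng: np.random.Generator | None = None):
    """Transcript 5'UTR/CDS/3'UTR and protein sequences with planted features.

    Returns (transcripts: gene_id -> TranscriptModel, proteins: protein_id ->
    amino-acid sequence).  One transcript per gene; the transcript id equals
    the gene id.
    """
    from .containers import TranscriptModel

    rng = rng or np.random.default_rng(params.seed + 1)
    kmers = list(params.planted_kmers.values())
    if len(set(kmers)) != len(kmers):
        raise OmixError("planted 6-mers collide between templates")
    seed_targets = [s.upper().replace("U", "T").translate(_COMP)[::-1]
                    for s in params.mirna_seeds]

    transcripts, proteins = {}, {}
    for gene, row in truth.table.iterrows():
        tpl = row["template"]
        is_top = bool(row["top_flag"])
        short = tpl == TOP_TEMPLATE
        long_utr = tpl in ("8", "9")
        len5 = int(max(20, rng.normal(35 if short else (250 if long_utr else 150),
                                      5 if short else 30)))
        len_cds = 3 * int(max(60, rng.normal(150 if short else 500, 30)))
        len3 = int(max(60, rng.normal(200 if short else (1200 if long_utr else 800),
                                      30 if short else 100)))

        utr5 = list(_to_str(_random_seq(rng, len5)))
        if is_top:
            run = int(rng.integers(params.top_run_min, params.top_run_max + 1))
            utr5[0] = "C"
            for i in range(1, min(run, len(utr5))):
                utr5[i] = _PYR[rng.integers(0, 2)]
        if row["kozak_class"] == "strong":
            utr5[-6:] = list("GCCACC")
        if tpl in ("3", "4", "5"):
            utr5 = _scrub_uorfs(utr5, rng)
            if is_top:  # scrubbing may touch the pyrimidine run; restore it
                utr5[0] = "C"
            uorf_spots = [i for i in range(5 if is_top else 1, len(utr5) - 8)]
            for _ in range(int(row["uorf_planted"])):
                pos = int(rng.choice(uorf_spots))
                utr5[pos : pos + 3] = ["ACT"[rng.integers(0, 3)], "T", "G"]

        cds = ["A", "T", "G"] + list(_to_str(_random_seq(rng, len_cds - 6))) + ["T", "A", "A"]
        if row["kozak_class"] == "strong":
            cds[3] = "G"

        utr3 = list(_to_str(_random_seq(rng, len3)))
        if row["planted_kmer"]:
            utr3 = _plant(utr3, row["planted_kmer"], params.kmer_copies, rng)
        if row["are_class"] == "high":
            utr3 = _plant(utr3, "ATTTA", rng.poisson(params.are_rate), rng)
        if tpl in MIRNA_TEMPLATES:
            for target in seed_targets:
                utr3 = _plant(utr3, target, params.mirna_copies, rng)

        transcripts[gene] = TranscriptModel(
            transcript_id=gene, gene_id=gene,
            utr5="".join(utr5), cds="".join(cds), utr3="".join(utr3))

        if row["mapped"]:
            n_aa = len_cds // 3 - 1
            kr = rng.uniform(0.05, 0.2)
            draws = rng.random(n_aa)
            aa = np.where(
                draws < kr / 2, "K",
                np.where(draws < kr, "R",
                         np.array(list(AA20))[rng.integers(0, len(AA20), n_aa)]))
            proteins[row["protein_id"]] = "M" + "".join(aa[1:])
    return transcripts, proteins


# ---------------------------------------------------------------------------
# exon / intron counts


def generate_exon_intron(truth: SyntheticTruth, params: SimParams,
                         rng: np.random.Generator | None = None):
    """Exonic and intronic count matrices with class-specific decay.

    Intron counts track transcription; exon counts track transcription/decay.
    Both share a per-sample library factor; the intron channel additionally
    gets a sample-specific linear distortion of its log abundance, so naive
    exon-intron differencing is biased and the per-sample bias fit matters.
    """
    rng = rng or np.random.default_rng(params.seed + 2)
    genes = list(truth.table.index)
    txn = np.exp(rng.normal(params.tpm_base_log_mean + 3, params.tpm_base_log_sigma, len(genes)))
    decay = {
        "progenitor": truth.table["decay_progenitor"].to_numpy(),
        "neuron": truth.table["decay_neuron"].to_numpy(),
    }
    noiseless = params.exin_dispersion == 0
    exon_cols, intron_cols, meta = {}, {}, {}
    center = np.log2(txn * params.intron_fraction).mean()
    for b in range(1, params.n_batches + 1):
        for cls in CELL_CLASSES:
            for day in params.days:
                sid = f"exin_{cls}_d{day}_b{b}"
                lib = 1.0 if noiseless else np.exp(rng.normal(0, params.library_sigma))
                slope = 1.0 if noiseless else rng.uniform(*params.intron_slope_range)
                mu_e = txn / (decay[cls] / params.decay_base) * lib
                log2_i = np.log2(txn * params.intron_fraction)
                mu_i = 2 ** (center + slope * (log2_i - center)) * lib
                exon_cols[sid] = _nb_sample(rng, mu_e, params.exin_dispersion)
                intron_cols[sid] = _nb_sample(rng, mu_i, params.exin_dispersion)
                meta[sid] = {"cell_class": cls, "day": day, "batch": f"b{b}",
                             "assay": "rna", "fraction": pd.NA, "genotype": pd.NA}
    mdf = pd.DataFrame(meta).T
    mdf.index.name = "sample_id"
    exon = ExpressionMatrix(pd.DataFrame(exon_cols, index=genes), mdf, "raw_count")
    intron = ExpressionMatrix(pd.DataFrame(intron_cols, index=genes), mdf, "raw_count")
    return exon, intron


# ---------------------------------------------------------------------------
# polysome counts


def generate_polysome(truth: SyntheticTruth, params: SimParams,
                      rng: np.random.Generator | None = None) -> ExpressionMatrix:
    """Polysome-fraction counts for two genotypes with a planted 5'TOP shift.

    Under the TSC2-knockout genotype the high-polysome means of TOP-flagged
    genes are scaled by 2**shift while monosome (and low-polysome) means stay
    fixed; all other genes are generated identically in both genotypes.
    """
    rng = rng or np.random.default_rng(params.seed + 3)
    genes = list(truth.table.index)
    base = np.exp(rng.normal(params.polysome_base_log_mean,
                             params.polysome_base_log_sigma, len(genes)))
    shift = truth.table["translation_shift"].to_numpy()
    cols, meta = {}, {}
    for genotype in ("control", "tsc2_ko"):
        for fraction, scale in params.fraction_scale.items():
            for r in range(1, params.polysome_reps + 1):
                sid = f"poly_{genotype}_{fraction}_r{r}"
                lib = (1.0 if params.polysome_dispersion == 0
                       else np.exp(rng.normal(0, params.library_sigma)))
                mu = base * scale * lib
                if genotype == "tsc2_ko" and fraction == "high_poly":
                    mu = mu * 2**shift
                cols[sid] = _nb_sample(rng, mu, params.polysome_dispersion)
                meta[sid] = {"cell_class": pd.NA, "day": pd.NA, "batch": f"r{r}",
                             "assay": "rna", "fraction": fraction, "genotype": genotype}
    mdf = pd.DataFrame(meta).T
    mdf.index.name = "sample_id"
    return ExpressionMatrix(pd.DataFrame(cols, index=genes), mdf, "raw_count")
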