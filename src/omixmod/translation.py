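"""Relative mRNA stability and polysome differential-association statistics.

Stability: intronic reads track transcription (pre-mRNA), exonic reads track
the mature pool (transcription / decay), so after removing each sample's
technical bias the deviation of exonic from intronic log abundance is a
relative decay-rate proxy.  Per sample a stability-free linear bias
Delta-exon = a_s + b_s * Delta-intron is fit over high-agreement genes (the
``stringency`` fraction with smallest absolute residuals, refit iteratively),
and the gene's stability score is its residual from that line.

Polysome statistics: per ribosome fraction, a negative-binomial Wald test of
genotype effect on size-factor-normalized counts, with method-of-moments
dispersions shrunk toward a fraction-wide 1/mean trend, BH adjustment across
genes, and the study thresholds |log2FC| >= 1 at FDR 0.1 for calling
differentially associated genes (DAGs).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix, OmixError

log = logging.getLogger("omixmod")


# ---------------------------------------------------------------------------
# relative mRNA stability


@dataclass
class StabilityEstimate:
    scores: pd.DataFrame          # genes x samples, gene-centered
    bias: pd.DataFrame            # per sample: intercept, slope
    included: pd.Index            # genes usable (no zero counts)
    fit_genes: pd.Index           # genes retained for the final bias fit


def stability_estimates(
    exon: ExpressionMatrix,
    intron: ExpressionMatrix,
    stringency: float = 0.99,
    n_iter: int = 5,
) -> StabilityEstimate:
    """Per-sample linear-bias-corrected exon/intron stability scores.

    Genes with any zero exonic or intronic count are excluded (logged).  The
    per-sample bias line is fit by least squares over included genes, then
    iteratively refit on the ``stringency`` fraction of genes with smallest
    absolute residuals (summed over samples); all included genes are scored
    against the final line and gene-centered.
    """
    if list(exon.values.index) != list(intron.values.index) or \
       list(exon.values.columns) != list(intron.values.columns):
        common_g = exon.values.index.intersection(intron.values.index)
        common_s = exon.values.columns.intersection(intron.values.columns)
        if len(common_g) == 0 or len(common_s) == 0:
            raise OmixError("exon and intron matrices share no genes/samples")
        exon = ExpressionMatrix(exon.values.loc[common_g, common_s], exon.meta, exon.unit)
        intron = ExpressionMatrix(intron.values.loc[common_g, common_s], intron.meta, intron.unit)
    E = exon.values.to_numpy(dtype=float)
    I = intron.values.to_numpy(dtype=float)
    usable = (E > 0).all(axis=1) & (I > 0).all(axis=1)
    n_drop = int((~usable).sum())
    if n_drop:
        log.info("stability: %d genes with zero exon/intron counts excluded", n_drop)
    genes = exon.values.index[usable]
    if len(genes) < 10:
        raise OmixError(f"only {len(genes)} genes usable for bias fitting (need >= 10)")
    dE = np.log2(E[usable])
    dI = np.log2(I[usable])
    dE -= dE.mean(axis=1, keepdims=True)
    dI -= dI.mean(axis=1, keepdims=True)

    fit_mask = np.ones(len(genes), dtype=bool)
    a = b = None
    for _ in range(n_iter):
        a = np.empty(dE.shape[1])
        b = np.empty(dE.shape[1])
        for s in range(dE.shape[1]):
            x, y = dI[fit_mask, s], dE[fit_mask, s]
            vx = np.var(x)
            b[s] = np.cov(x, y, bias=True)[0, 1] / vx if vx > 0 else 0.0
            a[s] = y.mean() - b[s] * x.mean()
        resid = dE - (a[None, :] + dI * b[None, :])
        if stringency >= 1.0:
            break
        score = np.abs(resid).sum(axis=1)
        keep = max(10, int(np.floor(stringency * len(genes))))
        new_mask = np.zeros(len(genes), dtype=bool)
        new_mask[np.argsort(score, kind="stable")[:keep]] = True
        if np.array_equal(new_mask, fit_mask):
            break
        fit_mask = new_mask
    resid = dE - (a[None, :] + dI * b[None, :])
    resid -= resid.mean(axis=1, keepdims=True)  # gene-centering
    scores = pd.DataFrame(resid, index=genes, columns=exon.values.columns)
    bias = pd.DataFrame({"intercept": a, "slope": b}, index=exon.values.columns)
    return StabilityEstimate(scores=scores, bias=bias, included=genes,
                             fit_genes=genes[fit_mask])


# ---------------------------------------------------------------------------
# polysome differential association


def filter_polysome_genes(
    counts: ExpressionMatrix,
    coding_genes: set,
    min_reads: int = 2,
    min_samples: int = 2,
) -> ExpressionMatrix:
    """Keep protein-coding genes detected in multiple samples of a condition.

    A condition is a (fraction, genotype) combination; a gene is retained iff
    it is coding and at least one condition has >= ``min_samples`` samples
    with >= ``min_reads`` reads.
    """
    meta = counts.meta
    conds = meta.groupby(["fraction", "genotype"], observed=True).groups
    arr = counts.values
    keep = pd.Series(False, index=arr.index)
    for _, samples in conds.items():
        sub = arr[list(samples)]
        keep |= (sub >= min_reads).sum(axis=1) >= min_samples
    keep &= arr.index.isin(coding_genes)
    log.info("polysome filter: %d of %d genes retained", int(keep.sum()), len(keep))
    return counts.subset_features(arr.index[keep])


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios library-size factors (geometric-mean reference)."""
    arr = counts.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        logs = np.log(arr)
    ref_ok = np.isfinite(logs).all(axis=1)
    if ref_ok.sum() < 1:
        raise OmixError("no gene with all-positive counts for size-factor estimation")
    log_ref = logs[ref_ok].mean(axis=1, keepdims=True)
    sf = np.exp(np.median(logs[ref_ok] - log_ref, axis=0))
    return pd.Series(sf, index=counts.columns, name="size_factor")


def _nb_dispersions(q: np.ndarray, groups: list[np.ndarray], shrink: float = 0.5) -> np.ndarray:
    """Method-of-moments dispersions from normalized counts, shrunk toward a
    fraction-wide a0 + a1/mean trend (log-space averaging)."""
    means = q.mean(axis=1)
    # pooled within-group variance
    ss, df = np.zeros(q.shape[0]), 0
    for idx in groups:
        sub = q[:, idx]
        ss += ((sub - sub.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        df += len(idx) - 1
    var = ss / max(df, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (var - means) / means**2
    alpha = np.clip(alpha, 1e-8, 10.0)
    ok = (means > 0) & np.isfinite(alpha) & (alpha > 1e-8)
    if ok.sum() >= 10:
        A = np.column_stack([np.ones(ok.sum()), 1.0 / means[ok]])
        coef, *_ = np.linalg.lstsq(A, alpha[ok], rcond=None)
        trend = np.clip(coef[0] + coef[1] / np.maximum(means, 1e-8), 1e-8, 10.0)
    else:
        trend = np.full_like(alpha, np.median(alpha[ok]) if ok.any() else 0.1)
    return np.exp(shrink * np.log(alpha) + (1 - shrink) * np.log(trend))


def _nb_wald(counts: np.ndarray, genotype: np.ndarray, sf: np.ndarray,
             alpha: np.ndarray, n_iter: int = 25):
    """Vectorized NB GLM (log link, design [1, genotype]) Wald test per gene.

    Returns (log2fc, se_log2, p).  ``genotype`` is 0/1 per sample; the
    coefficient tested is the genotype effect.
    """
    n_genes, n_samp = counts.shape
    X = np.column_stack([np.ones(n_samp), genotype.astype(float)])
    off = np.log(sf)[None, :]
    # initialize from group means of normalized counts
    q = counts / sf[None, :]
    m0 = q[:, genotype == 0].mean(axis=1)
    m1 = q[:, genotype == 1].mean(axis=1)
    pc = 0.5
    beta = np.column_stack([np.log(m0 + pc), np.log(m1 + pc) - np.log(m0 + pc)])
    for _ in range(n_iter):
        eta = off + beta @ X.T
        mu = np.exp(np.clip(eta, -30, 30))
        W = mu / (1.0 + alpha[:, None] * mu)
        z = eta - off + (counts - mu) / mu
        # per-gene weighted least squares for a 2-column design, closed form
        Sw = W.sum(axis=1)
        Swx = (W * X[:, 1]).sum(axis=1)
        Swxx = (W * X[:, 1] ** 2).sum(axis=1)
        Swz = (W * z).sum(axis=1)
        Swxz = (W * X[:, 1] * z).sum(axis=1)
        det = Sw * Swxx - Swx**2
        det = np.where(np.abs(det) < 1e-12, np.nan, det)
        b0 = (Swxx * Swz - Swx * Swxz) / det
        b1 = (Sw * Swxz - Swx * Swz) / det
        new = np.column_stack([b0, b1])
        new = np.where(np.isfinite(new), new, beta)
        if np.nanmax(np.abs(new - beta)) < 1e-8:
            beta = new
            break
        beta = new
    eta = off + beta @ X.T
    mu = np.exp(np.clip(eta, -30, 30))
    W = mu / (1.0 + alpha[:, None] * mu)
    Sw = W.sum(axis=1)
    Swx = (W * X[:, 1]).sum(axis=1)
    Swxx = (W * X[:, 1] ** 2).sum(axis=1)
    det = Sw * Swxx - Swx**2
    var_b1 = np.where(det > 0, Sw / det, np.nan)
    se = np.sqrt(var_b1)
    lfc = beta[:, 1] / np.log(2)
    se2 = se / np.log(2)
    with np.errstate(invalid="ignore"):
        z = beta[:, 1] / se
    p = 2 * stats.norm.sf(np.abs(z))
    return lfc, se2, p


def differential_association(
    counts: ExpressionMatrix,
    lfc_threshold: float = 1.0,
    fdr: float = 0.1,
) -> pd.DataFrame:
    """Per-fraction NB Wald test of genotype effect on polysome counts.

    Fractions are analyzed independently with their own size factors and
    dispersion trend.  Output columns: fraction, log2fc (ko over control),
    se, p, adj_p, dag_flag (|log2fc| >= ``lfc_threshold`` and adj_p <= ``fdr``).
    """
    meta = counts.meta
    out = []
    for fraction in meta["fraction"].dropna().unique():
        samples = meta.index[meta["fraction"] == fraction]
        genos = meta.loc[samples, "genotype"]
        levels = sorted(genos.dropna().unique())
        if len(levels) < 2:
            log.warning("fraction %s: genotype missing, skipped", fraction)
            continue
        gvec = (genos == "tsc2_ko").to_numpy().astype(int)
        if min((gvec == 0).sum(), (gvec == 1).sum()) < 2:
            raise OmixError(f"fraction {fraction}: need >= 2 replicates per genotype")
        sub = counts.values[list(samples)].to_numpy(dtype=float)
        sf = size_factors(counts.values[list(samples)]).to_numpy()
        q = sub / sf[None, :]
        groups = [np.where(gvec == g)[0] for g in (0, 1)]
        alpha = _nb_dispersions(q, groups)
        lfc, se, p = _nb_wald(sub, gvec, sf, alpha)
        adj = np.full_like(p, np.nan)
        ok = np.isfinite(p)
        adj[ok] = multipletests(p[ok], method="fdr_bh")[1]
        df = pd.DataFrame({
            "gene_id": counts.values.index, "fraction": fraction,
            "log2fc": lfc, "se": se, "p": p, "adj_p": adj,
        })
        df["dag_flag"] = (np.abs(df["log2fc"]) >= lfc_threshold) & (df["adj_p"] <= fdr)
        out.append(df)
    if not out:
        raise OmixError("no fraction had both genotypes")
    return pd.concat(out, ignore_index=True)


# ---------------------------------------------------------------------------
# high:mono shift test


def polysome_shift_test(
    counts: ExpressionMatrix,
    gene_set,
    high_fraction: str = "high_poly",
    mono_fraction: str = "monosome",
) -> dict:
    """Per-genotype log2(high-polysome / monosome) for a gene set, paired test.

    Size-factor normalization is per fraction across both genotypes;
    replicates are averaged after normalization.  The paired t-test compares
    each gene's shift between genotypes (two-sided).  Genes with a zero
    normalized monosome mean are excluded from the pairing (logged).
    """
    meta = counts.meta
    genes = [g for g in gene_set if g in counts.values.index]
    if not genes:
        raise OmixError("gene set empty after filtering")
    ratios = {}
    for genotype in ("control", "tsc2_ko"):
        means = {}
        for fraction in (high_fraction, mono_fraction):
            fsamples = meta.index[meta["fraction"] == fraction]
            sf = size_factors(counts.values[list(fsamples)])
            sel = [s for s in fsamples if meta.loc[s, "genotype"] == genotype]
            norm = counts.values.loc[genes, sel].div(sf[sel], axis=1)
            means[fraction] = norm.mean(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratios[genotype] = np.log2(means[high_fraction] / means[mono_fraction])
    table = pd.DataFrame(ratios).replace([np.inf, -np.inf], np.nan)
    dropped = table.index[table.isna().any(axis=1)]
    if len(dropped):
        log.info("shift test: %d genes excluded (zero monosome/high mean)", len(dropped))
    table = table.dropna()
    diff = table["tsc2_ko"] - table["control"]
    result = {
        "per_gene": table,
        "mean_difference": float(diff.mean()),
        "n_genes": len(table),
        "p": np.nan,
        "degenerate": len(table) < 2,
    }
    if len(table) >= 2:
        result["p"] = float(stats.ttest_rel(table["tsc2_ko"], table["control"]).pvalue)
    else:
        log.warning("shift test: set of size %d, p undefined", len(table))
    return result
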