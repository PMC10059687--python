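"""Two-stage time-course regression and module clustering.

The selection follows the classic two-stage time-series strategy: a first
global regression of each gene's z-profile on a group x polynomial(time) model
(groups = assay x cell class, four series) tests for *any* temporal or
between-group structure at a gene-level FDR; survivors go through a backward
stepwise refit, and genes whose final model explains R-squared > 0.6 of their
variance are hierarchically clustered (Ward, Euclidean) on their 16
condition-mean z-scores into expression modules.  The cluster number is
estimated by majority vote of within-cluster sum of squares (elbow), average
silhouette width, and the gap statistic.

Every integrated gene ends with exactly one terminal label: a module id,
``not_clustered`` (significant but poorly modeled), or ``not_fit``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.metrics import silhouette_score
from statsmodels.stats.multitest import multipletests

from .containers import ASSAYS, CELL_CLASSES, DAYS, IntegratedMatrix, OmixError, condition_profiles

log = logging.getLogger("omixmod")


# ---------------------------------------------------------------------------
# design


@dataclass
class DesignSpec:
    """Group x centered-polynomial(time) design for the four assay/class series."""

    groups: pd.Series            # sample id -> group label "assay.class"
    time: pd.Series              # sample id -> scaled centered time
    degree: int = 2

    @classmethod
    def from_meta(cls, meta: pd.DataFrame, degree: int = 2) -> "DesignSpec":
        groups = meta["assay"].astype(str) + "." + meta["cell_class"].astype(str)
        days = meta["day"].astype(float)
        t = (days - days.mean()) / (days.max() - days.min()) * 2.0
        return cls(groups=groups, time=t, degree=degree)

    def full_matrix(self) -> pd.DataFrame:
        """Saturated coding: per-group intercept and polynomial terms."""
        cols = {}
        for g in sorted(self.groups.unique()):
            ind = (self.groups == g).astype(float)
            cols[g] = ind
            for d in range(1, self.degree + 1):
                cols[f"{g}:t{d}"] = ind * self.time**d
        X = pd.DataFrame(cols, index=self.groups.index)
        if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
            raise OmixError("design matrix is rank deficient; add replicates or lower degree")
        return X

    def reference_terms(self) -> pd.DataFrame:
        """Reference-coded terms for stepwise elimination.

        Columns: intercept; t^d main effects; per non-reference group a dummy
        and its interactions with each power of time.
        """
        groups = sorted(self.groups.unique())
        ref = groups[0]
        cols = {"intercept": pd.Series(1.0, index=self.groups.index)}
        for d in range(1, self.degree + 1):
            cols[f"t{d}"] = self.time**d
        for g in groups[1:]:
            ind = (self.groups == g).astype(float)
            cols[g] = ind
            for d in range(1, self.degree + 1):
                cols[f"{g}:t{d}"] = ind * self.time**d
        return pd.DataFrame(cols, index=self.groups.index)


# ---------------------------------------------------------------------------
# stage 1: global F-test per gene


def stage1_fit(m: IntegratedMatrix, design: DesignSpec | None = None, fdr: float = 0.05) -> pd.DataFrame:
    """F-test of the full group x polynomial model against intercept-only.

    Returns a DataFrame indexed by gene with columns p, adj_p, selected,
    not_fit.  Genes with a constant (flagged) all-zero profile, or zero
    variance both under and around the model, are labeled not_fit; the
    Benjamini-Hochberg adjustment runs across the fitted genes.
    """
    design = design or DesignSpec.from_meta(m.meta)
    X = design.full_matrix().to_numpy()
    Y = m.values.to_numpy(dtype=float).T  # samples x genes
    n, p1 = X.shape
    if n - p1 <= 0:
        raise OmixError("no residual degrees of freedom for stage-1 model")
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    rss1 = ((Y - X @ beta) ** 2).sum(axis=0)
    tss = ((Y - Y.mean(axis=0, keepdims=True)) ** 2).sum(axis=0)
    eps = 1e-12
    not_fit = tss <= eps
    not_fit |= np.array([g in m.constant_rows for g in m.values.index])
    with np.errstate(divide="ignore", invalid="ignore"):
        F = ((tss - rss1) / (p1 - 1)) / (rss1 / (n - p1))
    pvals = np.full(Y.shape[1], np.nan)
    perfect = (rss1 <= eps) & ~not_fit
    ok = ~not_fit & ~perfect
    pvals[ok] = stats.f.sf(F[ok], p1 - 1, n - p1)
    pvals[perfect] = np.finfo(float).tiny  # zero-noise signal: p underflows
    adj = np.full_like(pvals, np.nan)
    fit_mask = ~not_fit
    if fit_mask.any():
        adj[fit_mask] = multipletests(pvals[fit_mask], method="fdr_bh")[1]
    out = pd.DataFrame(
        {"p": pvals, "adj_p": adj, "selected": (adj <= fdr) & fit_mask, "not_fit": not_fit},
        index=m.values.index,
    )
    log.info("stage1: %d genes, %d fit, %d selected at FDR %.3g, %d not_fit",
             len(out), int(fit_mask.sum()), int(out["selected"].sum()), fdr, int(not_fit.sum()))
    return out


# ---------------------------------------------------------------------------
# stage 2: backward stepwise per gene


def _children(term: str, terms: list[str], degree: int) -> list[str]:
    """Terms that must be dropped before ``term`` (model hierarchy)."""
    kids = []
    if ":" in term:               # interaction: no children
        return kids
    if term.startswith("t"):      # time main effect t{d}
        d = term[1:]
        kids += [t for t in terms if t.endswith(f":t{d}")]
        nxt = f"t{int(d) + 1}"
        if nxt in terms:
            kids.append(nxt)
    elif term != "intercept":     # group dummy
        kids += [t for t in terms if t.startswith(term + ":")]
    return kids


def stage2_stepwise(
    m: IntegratedMatrix,
    genes,
    design: DesignSpec | None = None,
    alpha: float = 0.05,
    r2_min: float = 0.6,
) -> pd.DataFrame:
    """Backward elimination from the full reference-coded model per gene.

    While any droppable term (one whose interactions have all been removed)
    has a coefficient p-value above ``alpha``, the least significant such term
    is dropped and the model refit.  Returns r2, the retained term list and
    pass flag (strict R-squared > r2_min) per gene.
    """
    design = design or DesignSpec.from_meta(m.meta)
    terms_df = design.reference_terms()
    all_terms = list(terms_df.columns)
    Xfull = terms_df.to_numpy()
    col_of = {t: i for i, t in enumerate(all_terms)}
    Y = m.values.loc[list(genes)].to_numpy(dtype=float)
    n = Xfull.shape[0]
    records = []
    for gi, gene in enumerate(genes):
        y = Y[gi]
        tss = ((y - y.mean()) ** 2).sum()
        terms = list(all_terms)
        while len(terms) > 1:
            X = Xfull[:, [col_of[t] for t in terms]]
            beta, rss, se = _ols(X, y)
            if rss <= 1e-12 * max(tss, 1.0):  # noiseless perfect fit
                break
            df = n - len(terms)
            if df <= 0:
                raise OmixError("stage-2 model has no residual degrees of freedom")
            tstat = np.divide(beta, se, out=np.zeros_like(beta), where=se > 0)
            pvals = 2 * stats.t.sf(np.abs(tstat), df)
            droppable = [
                (pvals[i], t) for i, t in enumerate(terms)
                if t != "intercept" and not any(k in terms for k in _children(t, all_terms, design.degree))
            ]
            worst = max(droppable, default=None)
            if worst is None or worst[0] <= alpha or np.isnan(worst[0]):
                break
            terms.remove(worst[1])
        X = Xfull[:, [col_of[t] for t in terms]]
        beta, rss, _ = _ols(X, y)
        r2 = 0.0 if tss <= 0 or terms == ["intercept"] else max(0.0, 1.0 - rss / tss)
        records.append((gene, r2, ",".join(t for t in terms if t != "intercept"), r2 > r2_min))
    out = pd.DataFrame(records, columns=["gene_id", "r2", "terms", "passed"]).set_index("gene_id")
    log.info("stage2: %d genes refit, %d passed R2 > %.2f", len(out), int(out["passed"].sum()), r2_min)
    return out


def _ols(X: np.ndarray, y: np.ndarray):
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    df = X.shape[0] - X.shape[1]
    sigma2 = rss / df if df > 0 else np.nan
    XtX_inv = np.linalg.pinv(X.T @ X)
    se = np.sqrt(np.clip(np.diag(XtX_inv) * sigma2, 0, None))
    return beta, rss, se


# ---------------------------------------------------------------------------
# cluster-number estimation


@dataclass
class KSelection:
    k: int
    votes: dict
    curves: pd.DataFrame
    low_confidence: bool = False


def _wss_from_labels(Z: np.ndarray, labels: np.ndarray) -> float:
    w = 0.0
    for lab in np.unique(labels):
        pts = Z[labels == lab]
        w += ((pts - pts.mean(axis=0)) ** 2).sum()
    return w


def _hierarchical_labels(Z: np.ndarray, ks) -> dict[int, np.ndarray]:
    link = linkage(Z, method="ward")
    return {k: fcluster(link, t=k, criterion="maxclust") for k in ks}


def estimate_k(
    profiles: pd.DataFrame,
    k_range: tuple[int, int] = (4, 15),
    methods: tuple = ("wss", "silhouette", "gap"),
    B: int = 50,
    rng: np.random.Generator | None = None,
) -> KSelection:
    """Estimate the cluster number by majority vote of three internal criteria.

    * silhouette: argmax of the average silhouette width;
    * wss: elbow of the total within sum of squares (largest second difference);
    * gap: smallest k with gap(k) >= gap(k+1) - se(k+1) (uniform reference over
      per-feature ranges, B bootstrap datasets).

    Ties are broken by the silhouette choice.  A dataset where the gap curve
    never satisfies its criterion within the range is flagged low-confidence.
    """
    rng = rng or np.random.default_rng(0)
    Z = np.asarray(profiles, dtype=float)
    n = Z.shape[0]
    if np.allclose(Z, Z[0]):
        raise OmixError("no cluster structure: all profiles identical")
    kmin, kmax = k_range
    if kmin < 2 or kmax > n - 1:
        raise OmixError(f"k_range {k_range} outside [2, n_genes-1]")
    ks = list(range(kmin, kmax + 1))
    # extended range so the elbow second difference and the gap(k+1) rule are
    # defined at both ends of the requested range
    ks_ext = list(range(max(2, kmin - 1), min(n - 1, kmax + 1) + 1))
    labels = _hierarchical_labels(Z, ks_ext)

    curves = pd.DataFrame(index=ks_ext)
    curves["wss"] = [_wss_from_labels(Z, labels[k]) for k in ks_ext]
    curves["silhouette"] = [
        silhouette_score(Z, labels[k]) if len(np.unique(labels[k])) > 1 else np.nan
        for k in ks_ext
    ]

    votes: dict[str, int] = {}
    low_conf = False
    if "silhouette" in methods:
        votes["silhouette"] = int(curves.loc[ks, "silhouette"].idxmax())
    if "wss" in methods:
        w = curves["wss"]
        second = {
            k: (w.get(k - 1, np.nan) - w[k]) - (w[k] - w.get(k + 1, np.nan))
            for k in ks
        }
        sd = pd.Series(second).dropna()
        votes["wss"] = int(sd.idxmax()) if len(sd) else ks[0]
    if "gap" in methods:
        lo, hi = Z.min(axis=0), Z.max(axis=0)
        log_w_ref = np.empty((B, len(ks_ext)))
        for b in range(B):
            R = rng.uniform(lo, hi, size=Z.shape)
            rlabels = _hierarchical_labels(R, ks_ext)
            log_w_ref[b] = [np.log(_wss_from_labels(R, rlabels[k])) for k in ks_ext]
        gap = log_w_ref.mean(axis=0) - np.log(curves["wss"].to_numpy())
        se = log_w_ref.std(axis=0, ddof=1) * np.sqrt(1 + 1.0 / B)
        curves["gap"], curves["gap_se"] = gap, se
        pick = None
        for i, k in enumerate(ks_ext):
            if k not in ks or k + 1 not in ks_ext:
                continue
            if gap[i] >= gap[i + 1] - se[i + 1]:
                pick = k
                break
        if pick is None:
            pick = int(curves.loc[ks, "gap"].idxmax())
            low_conf = True
        votes["gap"] = pick

    tally = pd.Series(votes).value_counts()
    if tally.iloc[0] > 1:
        k_sel = int(tally.index[0])
    else:
        k_sel = votes.get("silhouette", next(iter(votes.values())))
    log.info("estimate_k: votes %s -> k=%d%s", votes, k_sel, " (low confidence)" if low_conf else "")
    return KSelection(k=k_sel, votes=votes, curves=curves.loc[ks], low_confidence=low_conf)


# ---------------------------------------------------------------------------
# clustering and characterization


def cluster_genes(profiles: pd.DataFrame, k: int) -> pd.Series:
    """Ward/Euclidean agglomerative clustering of condition-mean z-profiles.

    Modules are renumbered by descending size (ties by first occurrence), so
    labels are stable under permutation of the input gene order up to the
    renumbering itself.
    """
    Z = np.asarray(profiles, dtype=float)
    if k > len(np.unique(Z, axis=0)):
        raise OmixError(f"k={k} exceeds the number of distinct profiles")
    raw = fcluster(linkage(Z, method="ward"), t=k, criterion="maxclust")
    sizes = pd.Series(raw).value_counts()
    remap = {old: new + 1 for new, old in enumerate(sizes.index)}
    return pd.Series([remap[r] for r in raw], index=profiles.index, name="module")


def rna_protein_correlation(m: IntegratedMatrix) -> pd.Series:
    """Per-gene Pearson r between the 8 RNA and 8 protein class x day means."""
    prof = condition_profiles(m)
    rna = prof[[c for c in prof.columns if c.startswith("rna.")]].to_numpy()
    prot = prof[[c for c in prof.columns if c.startswith("protein.")]].to_numpy()
    if rna.shape[1] != prot.shape[1]:
        raise OmixError("assays cover different class x day conditions")
    rc = rna - rna.mean(axis=1, keepdims=True)
    pc = prot - prot.mean(axis=1, keepdims=True)
    denom = np.sqrt((rc**2).sum(axis=1) * (pc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (rc * pc).sum(axis=1) / denom
    r[denom == 0] = np.nan  # constant profile in either assay: undefined
    return pd.Series(r, index=prof.index, name="rna_protein_r")


def module_category(
    modules: pd.Series,
    profiles: pd.DataFrame,
    rna_protein_r: pd.Series,
    r_threshold: float = 0.5,
) -> pd.Series:
    """Classify each module as C (cell class), T (temporal) or A (ambiguous).

    The module's mean 16-condition profile is decomposed per assay into a
    class component (variance of the two class means) and a time component
    (variance of the four day means).  Class-dominant in both assays with mean
    RNA-protein correlation >= ``r_threshold`` -> C; time-dominant in both
    assays -> T; anything else (including RNA-protein discordance) -> A.
    """
    cats = {}
    for mod in sorted(modules.unique()):
        members = modules.index[modules == mod]
        mean_prof = profiles.loc[members].mean(axis=0)
        dominant = {}
        for assay in ASSAYS:
            grid = np.array([
                [mean_prof[f"{assay}.{cls}.d{day}"] for day in DAYS] for cls in CELL_CLASSES
            ])
            class_var = np.var(grid.mean(axis=1))
            time_var = np.var(grid.mean(axis=0))
            dominant[assay] = "class" if class_var > time_var else "time"
        rbar = rna_protein_r.loc[members].mean()
        if all(d == "class" for d in dominant.values()) and rbar >= r_threshold:
            cats[mod] = "C"
        elif all(d == "time" for d in dominant.values()):
            cats[mod] = "T"
        else:
            cats[mod] = "A"
    return pd.Series(cats, name="category")


# ---------------------------------------------------------------------------
# orchestration


@dataclass
class ModuleDiscoveryResult:
    table: pd.DataFrame          # per gene: label, category, p, adj_p, r2
    k_selection: KSelection | None
    categories: pd.Series
    profiles: pd.DataFrame
    counts: dict = field(default_factory=dict)


def discover_modules(
    m: IntegratedMatrix,
    fdr: float = 0.05,
    alpha: float = 0.05,
    r2_min: float = 0.6,
    degree: int = 2,
    k: int | None = None,
    k_range: tuple[int, int] = (4, 15),
    gap_B: int = 50,
    min_module_size: int = 0,
    rng: np.random.Generator | None = None,
) -> ModuleDiscoveryResult:
    """Run the full selection -> stepwise -> clustering -> labeling cascade."""
    rng = rng or np.random.default_rng(0)
    design = DesignSpec.from_meta(m.meta, degree=degree)
    s1 = stage1_fit(m, design, fdr=fdr)
    selected = list(s1.index[s1["selected"]])
    s2 = stage2_stepwise(m, selected, design, alpha=alpha, r2_min=r2_min)
    clusterable = list(s2.index[s2["passed"]])

    profiles = condition_profiles(m)
    ksel = None
    if clusterable:
        if k is None:
            ksel = estimate_k(profiles.loc[clusterable], k_range=k_range, B=gap_B, rng=rng)
            k = ksel.k
        modules = cluster_genes(profiles.loc[clusterable], k)
        if min_module_size > 0:
            small = modules.value_counts()
            drop = small.index[small < min_module_size]
            modules = modules[~modules.isin(drop)]
    else:
        modules = pd.Series(dtype=int)

    rpr = rna_protein_correlation(m)
    categories = (
        module_category(modules, profiles, rpr) if len(modules) else pd.Series(dtype=object)
    )

    # Terminal labels mirror the study's accounting: genes not carried past
    # the first regression (fit failure or below the FDR cut) are "not_fit";
    # carried genes missing a module are "not_clustered", so that
    # not_fit = total - fit and not_clustered = fit - significant.
    label = pd.Series("not_fit", index=m.values.index, dtype=object)
    label[selected] = "not_clustered"
    label[modules.index] = modules.astype(str)
    table = pd.DataFrame({
        "label": label,
        "p": s1["p"],
        "adj_p": s1["adj_p"],
        "r2": s2["r2"].reindex(m.values.index),
        "rna_protein_r": rpr,
    })
    table["category"] = table["label"].map(
        {str(mod): cat for mod, cat in categories.items()}
    )
    counts = {
        "total": len(table),
        "fit": len(selected),
        "significant": int(s2["passed"].sum()),
        "clustered": int(table["label"].str.fullmatch(r"\d+").sum()),
        "not_clustered": int((table["label"] == "not_clustered").sum()),
        "not_fit": int((table["label"] == "not_fit").sum()),
    }
    counts["dropped"] = counts["total"] - (
        counts["clustered"] + counts["not_clustered"] + counts["not_fit"]
    )
    log.info("module accounting: %s", counts)
    return ModuleDiscoveryResult(table=table, k_selection=ksel, categories=categories,
                                 profiles=profiles, counts=counts)
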