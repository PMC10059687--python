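import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from omixmod import (
    DesignSpec,
    IntegratedMatrix,
    OmixError,
    SimParams,
    cluster_genes,
    condition_profiles,
    estimate_k,
    generate_multiomics,
    integrate_multiomics,
    module_category,
    rna_protein_correlation,
    stage1_fit,
    stage2_stepwise,
)
from omixmod.simulate import TEMPLATES


def design_meta(n_batches=3):
    rows = {}
    for assay in ("rna", "protein"):
        for cls in ("progenitor", "neuron"):
            for day in (40, 60, 90, 120):
                for b in range(1, n_batches + 1):
                    rows[f"{assay}_{cls}_{day}_b{b}"] = {
                        "cell_class": cls, "day": day, "batch": f"b{b}",
                        "assay": assay, "fraction": pd.NA, "genotype": pd.NA}
    return pd.DataFrame(rows).T


def integrated_from(values: pd.DataFrame, meta, constant=frozenset()):
    gm = pd.DataFrame({"protein_id": values.index, "gene_id": values.index})
    return IntegratedMatrix(values, meta, gm, constant_rows=constant)


def test_stage1_perfect_signal_selected_and_constant_not_fit(rng):
    meta = design_meta()
    design = DesignSpec.from_meta(meta)
    groups = design.groups
    signal = (groups == "rna.progenitor").astype(float) * design.time
    Y = pd.DataFrame({
        "perfect": signal,
        "noise": rng.normal(size=len(meta)),
        "constant": np.zeros(len(meta)),
    }).T
    Y.columns = meta.index
    m = integrated_from(Y, meta, constant=frozenset({"constant"}))
    res = stage1_fit(m, design)
    assert res.loc["perfect", "selected"]
    assert res.loc["perfect", "p"] <= np.finfo(float).tiny
    assert res.loc["constant", "not_fit"]
    assert not res.loc["constant", "selected"]


def test_stage1_null_calibration(rng):
    meta = design_meta()
    Y = pd.DataFrame(rng.normal(size=(500, len(meta))), columns=meta.index,
                     index=[f"g{i}" for i in range(500)])
    res = stage1_fit(integrated_from(Y, meta))
    se = np.sqrt(0.05 * 0.95 / 500)
    assert res["selected"].mean() <= 0.05 + 3 * se


def test_stage2_noiseless_template_r2_one():
    params = SimParams(seed=5, rna_dispersion=0.0, protein_sigma=0.0,
                       n_genes_per_template=2, n_null_genes=0, n_unmapped_genes=0,
                       n_batches=1)
    data = generate_multiomics(params, np.random.default_rng(5))
    m = integrate_multiomics(data)
    genes = list(m.values.index[:5])
    # degree 3 saturates the four time points, so noiseless templates fit exactly
    design = DesignSpec.from_meta(m.meta, degree=3)
    res = stage2_stepwise(m, genes, design)
    assert (res["r2"] > 0.999999).all()
    assert res["passed"].all()


def test_stage2_noise_gene_fails_r2(rng):
    meta = design_meta()
    Y = pd.DataFrame(rng.normal(size=(30, len(meta))), columns=meta.index,
                     index=[f"n{i}" for i in range(30)])
    res = stage2_stepwise(integrated_from(Y, meta), list(Y.index))
    assert res["passed"].mean() < 0.2


def test_stage2_snr_matches_analytic_r2(rng):
    """R-squared approaches signal_var / (signal_var + noise_var)."""
    meta = design_meta(n_batches=12)
    design = DesignSpec.from_meta(meta)
    signal = ((design.groups == "rna.neuron").astype(float) * 2.0
              + design.time * 1.0).to_numpy()
    sig_var = signal.var()
    noise_sd = 0.8
    expect = sig_var / (sig_var + noise_sd**2)
    Y = pd.DataFrame(
        signal + rng.normal(0, noise_sd, size=(40, len(meta))),
        columns=meta.index, index=[f"g{i}" for i in range(40)])
    res = stage2_stepwise(integrated_from(Y, meta), list(Y.index))
    assert abs(res["r2"].mean() - expect) < 0.1


def blobs(rng, k=3, n=60, sep=30.0, dim=6):
    centers = rng.normal(scale=sep, size=(k, dim))
    pts = np.vstack([c + rng.normal(size=(n, dim)) for c in centers])
    labels = np.repeat(np.arange(k), n)
    return pd.DataFrame(pts, index=[f"g{i}" for i in range(k * n)]), labels


def test_estimate_k_recovers_separated_blobs(rng):
    profiles, _ = blobs(rng)
    sel = estimate_k(profiles, k_range=(2, 6), B=20, rng=rng)
    assert sel.k == 3
    assert all(v == 3 for v in sel.votes.values())


def test_estimate_k_single_blob_prefers_low_end(rng):
    profiles = pd.DataFrame(rng.normal(size=(120, 6)),
                            index=[f"g{i}" for i in range(120)])
    sel = estimate_k(profiles, k_range=(2, 8), B=20, rng=rng)
    assert sel.votes["gap"] <= 3


def test_estimate_k_identical_profiles_error(rng):
    profiles = pd.DataFrame(np.ones((20, 6)))
    with pytest.raises(OmixError, match="cluster structure"):
        estimate_k(profiles, k_range=(2, 5), rng=rng)


def test_cluster_antipodal_split(rng):
    a = np.tile([3.0, -3.0, 3.0], (20, 1)) + rng.normal(scale=0.1, size=(20, 3))
    b = -a
    profiles = pd.DataFrame(np.vstack([a, b]), index=[f"g{i}" for i in range(40)])
    labels = cluster_genes(profiles, 2)
    assert len(set(labels.iloc[:20])) == 1
    assert set(labels.iloc[:20]) != set(labels.iloc[20:])


def test_cluster_permutation_invariance(rng):
    profiles, _ = blobs(rng, k=4, n=30)
    lab1 = cluster_genes(profiles, 4)
    perm = rng.permutation(len(profiles))
    lab2 = cluster_genes(profiles.iloc[perm], 4)
    assert adjusted_rand_score(lab1.iloc[perm], lab2) == 1.0


def test_cluster_scale_invariance(rng):
    profiles, _ = blobs(rng, k=3, n=30)
    lab1 = cluster_genes(profiles, 3)
    lab2 = cluster_genes(profiles * 7.5, 3)
    assert adjusted_rand_score(lab1, lab2) == 1.0


def test_cluster_modules_numbered_by_descending_size(rng):
    a = rng.normal(loc=10, size=(30, 4))
    b = rng.normal(loc=-10, size=(10, 4))
    profiles = pd.DataFrame(np.vstack([a, b]), index=[f"g{i}" for i in range(40)])
    labels = cluster_genes(profiles, 2)
    counts = labels.value_counts()
    assert counts.loc[1] >= counts.loc[2]


def test_cluster_k_exceeding_distinct_profiles_errors():
    profiles = pd.DataFrame(np.tile([1.0, 2.0], (5, 1)))
    with pytest.raises(OmixError):
        cluster_genes(profiles, 3)


def _template_profiles(noise=0.02, n_per=5, seed=0):
    """Condition-mean profiles drawn directly from the planted templates."""
    rng = np.random.default_rng(seed)
    cols, rows, labels = None, [], []
    for tpl, prof in TEMPLATES.items():
        flat = prof.reshape(-1)  # (assay, class, day) -> 16 dims
        for i in range(n_per):
            rows.append(flat + rng.normal(scale=noise, size=16))
            labels.append(tpl)
    cols = [f"{assay}.{cls}.d{day}" for assay in ("rna", "protein")
            for cls in ("progenitor", "neuron") for day in (40, 60, 90, 120)]
    idx = [f"g{i}" for i in range(len(rows))]
    return pd.DataFrame(rows, index=idx, columns=cols), pd.Series(labels, index=idx)


def test_module_category_matches_planted_taxonomy():
    profiles, planted = _template_profiles()
    modules = pd.Series(pd.factorize(planted)[0] + 1, index=planted.index)
    # concordant templates get r=1; discordant ones computed from the template
    rbar = {}
    for g, tpl in planted.items():
        prof = TEMPLATES[tpl]
        rbar[g] = np.corrcoef(prof[0].ravel(), prof[1].ravel())[0, 1]
    cats = module_category(modules, profiles, pd.Series(rbar))
    by_template = {planted[modules.index[modules == mod][0]]: cat
                   for mod, cat in cats.items()}
    assert {t: by_template[t] for t in "12789"} == {t: "C" for t in "12789"}
    assert by_template["4"] == "T" and by_template["6"] == "T"
    assert by_template["3"] == "A" and by_template["5"] == "A"


def test_rna_protein_correlation_limits(default_integrated):
    r = rna_protein_correlation(default_integrated)
    prof = condition_profiles(default_integrated)
    # identical and sign-flipped constructed profiles
    m = default_integrated
    vals = m.values.copy()
    rna_cols = m.assay_samples("rna")
    prot_cols = m.assay_samples("protein")
    g0, g1 = vals.index[:2]
    base = np.linspace(-1, 1, len(rna_cols))
    vals.loc[g0, rna_cols] = base
    vals.loc[g0, prot_cols] = np.linspace(-1, 1, len(prot_cols))
    vals.loc[g1, rna_cols] = base
    vals.loc[g1, prot_cols] = -np.linspace(-1, 1, len(prot_cols))
    m2 = IntegratedMatrix(vals, m.meta, m.gene_map)
    r2 = rna_protein_correlation(m2)
    assert r2[g0] == pytest.approx(1.0)
    assert r2[g1] == pytest.approx(-1.0)
    assert r.abs().max() <= 1.0 + 1e-12


def test_c_modules_more_concordant_than_a_modules(default_data, default_integrated):
    r = rna_protein_correlation(default_integrated)
    truth = default_data.truth.table
    pid = truth.dropna(subset=["protein_id"]).set_index("protein_id")
    tpl = pid["template"].reindex(r.index)
    c_mean = r[tpl.isin(list("12789"))].mean()
    a_mean = r[tpl.isin(list("35"))].mean()
    assert c_mean > a_mean
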