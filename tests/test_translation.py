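import numpy as np
import pandas as pd
import pytest
from scipy import stats

from omixmod import (
    ExpressionMatrix,
    OmixError,
    SimParams,
    differential_association,
    filter_polysome_genes,
    generate_exon_intron,
    generate_polysome,
    polysome_shift_test,
    size_factors,
    stability_estimates,
)
from omixmod.simulate import build_truth


def exin_matrix(values: pd.DataFrame):
    meta = pd.DataFrame({
        "cell_class": ["progenitor", "neuron"] * (values.shape[1] // 2),
        "day": 40, "batch": "b1", "assay": "rna",
    }, index=values.columns)
    return ExpressionMatrix(values, meta, "raw_count")


def test_stability_null_exon_equals_intron(rng):
    vals = pd.DataFrame(rng.integers(10, 1000, size=(50, 4)).astype(float),
                        index=[f"g{i}" for i in range(50)],
                        columns=[f"s{i}" for i in range(4)])
    est = stability_estimates(exin_matrix(vals), exin_matrix(vals.copy()))
    np.testing.assert_allclose(est.scores, 0.0, atol=1e-10)


def test_stability_invariant_to_per_sample_scaling(rng):
    genes = [f"g{i}" for i in range(60)]
    cols = [f"s{i}" for i in range(6)]
    exon = pd.DataFrame(rng.uniform(50, 500, size=(60, 6)), index=genes, columns=cols)
    intron = pd.DataFrame(rng.uniform(5, 50, size=(60, 6)), index=genes, columns=cols)
    est1 = stability_estimates(exin_matrix(exon), exin_matrix(intron))
    scale = pd.Series(rng.uniform(0.5, 2.0, 6), index=cols)
    est2 = stability_estimates(exin_matrix(exon * scale), exin_matrix(intron * scale))
    np.testing.assert_allclose(est1.scores, est2.scores, atol=1e-8)


def test_stability_scores_gene_centered(rng):
    genes = [f"g{i}" for i in range(40)]
    cols = [f"s{i}" for i in range(6)]
    exon = pd.DataFrame(rng.uniform(50, 500, size=(40, 6)), index=genes, columns=cols)
    intron = pd.DataFrame(rng.uniform(5, 50, size=(40, 6)), index=genes, columns=cols)
    est = stability_estimates(exin_matrix(exon), exin_matrix(intron))
    np.testing.assert_allclose(est.scores.mean(axis=1), 0.0, atol=1e-10)


def test_stability_needs_enough_genes():
    vals = pd.DataFrame(np.ones((5, 4)), columns=[f"s{i}" for i in range(4)])
    with pytest.raises(OmixError, match="10"):
        stability_estimates(exin_matrix(vals), exin_matrix(vals))


def test_stability_zero_count_genes_excluded(rng):
    genes = [f"g{i}" for i in range(30)]
    cols = [f"s{i}" for i in range(4)]
    exon = pd.DataFrame(rng.uniform(50, 500, size=(30, 4)), index=genes, columns=cols)
    intron = exon.copy()
    exon.iloc[0, 0] = 0.0
    est = stability_estimates(exin_matrix(exon), exin_matrix(intron))
    assert "g0" not in est.scores.index and len(est.scores) == 29


def test_stability_recovers_planted_decay_difference():
    params = SimParams(seed=21)
    rng = np.random.default_rng(21)
    truth = build_truth(params, rng)
    exon, intron = generate_exon_intron(truth, params, rng)
    est = stability_estimates(exon, intron, stringency=0.99)
    meta = exon.meta
    neuron = [s for s in est.scores.columns if meta.loc[s, "cell_class"] == "neuron"]
    prog = [s for s in est.scores.columns if meta.loc[s, "cell_class"] == "progenitor"]
    diff = est.scores[neuron].mean(axis=1) - est.scores[prog].mean(axis=1)
    planted = truth.table["template"].reindex(est.scores.index)
    # templates 1 and 3: neurons decay 2x faster -> ~-1 log2
    assert abs(diff[planted.isin(["1", "3"])].mean() + 1.0) < 0.2
    # template 9: progenitors decay 2x faster -> ~+1 log2
    assert abs(diff[planted == "9"].mean() - 1.0) < 0.2
    assert abs(diff[planted == "null"].mean()) < 0.1


def poly_matrix(values: pd.DataFrame, genotypes, fraction="high_poly"):
    meta = pd.DataFrame({
        "cell_class": pd.NA, "day": pd.NA, "batch": "b1", "assay": "rna",
        "fraction": fraction, "genotype": genotypes,
    }, index=values.columns)
    return ExpressionMatrix(values, meta, "raw_count")


def test_filter_polysome_rules():
    genes = ["coding_lo", "coding_ok", "noncoding", "coding_spread"]
    vals = pd.DataFrame(
        [[5, 1, 1, 1], [2, 2, 0, 0], [900, 900, 900, 900], [1, 1, 1, 1]],
        index=genes, columns=[f"s{i}" for i in range(4)])
    m = poly_matrix(vals, ["control"] * 4)
    coding = {"coding_lo", "coding_ok", "coding_spread"}
    out = filter_polysome_genes(m, coding, min_reads=2, min_samples=2)
    assert set(out.values.index) == {"coding_ok"}


def test_size_factors_absorb_scaling(rng):
    counts = pd.DataFrame(rng.integers(10, 1000, size=(100, 4)).astype(float),
                          columns=list("abcd"))
    counts["d"] *= 2.0
    sf = size_factors(counts)
    assert sf["d"] / sf["a"] == pytest.approx(2.0, rel=0.05)


def test_differential_association_null_calibrated():
    params = SimParams(seed=31, translation_shift=0.0)
    rng = np.random.default_rng(31)
    truth = build_truth(params, rng)
    counts = generate_polysome(truth, params, rng)
    da = differential_association(counts)
    n = len(da)
    se = np.sqrt(0.1 * 0.9 / n)
    assert da["dag_flag"].mean() <= 0.1 + 3 * se


def test_differential_association_pvalues_uniform_at_large_n():
    """Wald p-values approach uniformity as replication grows."""
    params = SimParams(seed=32, translation_shift=0.0, polysome_reps=8)
    rng = np.random.default_rng(32)
    truth = build_truth(params, rng)
    counts = generate_polysome(truth, params, rng)
    da = differential_association(counts)
    p = da["p"].dropna()
    assert stats.kstest(p, "uniform").pvalue > 0.01


def test_differential_association_library_size_confound(rng):
    genes = [f"g{i}" for i in range(300)]
    base = rng.negative_binomial(20, 20 / (20 + 200.0), size=(300, 6)).astype(float)
    vals = pd.DataFrame(base, index=genes, columns=[f"s{i}" for i in range(6)])
    genotypes = ["control"] * 3 + ["tsc2_ko"] * 3
    vals.iloc[:, 3:] *= 2.0  # pure library-size difference
    da = differential_association(poly_matrix(vals, genotypes))
    assert da["dag_flag"].sum() == 0
    # size factors absorb the global scaling: estimates center on 0, not on 1
    assert abs(da["log2fc"].mean()) < 0.06


def test_differential_association_needs_replicates():
    vals = pd.DataFrame([[10.0, 12.0]], index=["g"], columns=["a", "b"])
    m = poly_matrix(vals, ["control", "tsc2_ko"])
    with pytest.raises(OmixError, match="replicates"):
        differential_association(m)


def test_shift_test_null_and_planted():
    # identical genotypes: mean paired difference ~ 0
    params = SimParams(seed=41, translation_shift=0.0)
    rng = np.random.default_rng(41)
    truth = build_truth(params, rng)
    counts = generate_polysome(truth, params, rng)
    res = polysome_shift_test(counts, truth.top_genes)
    assert abs(res["mean_difference"]) < 0.1
    # planted +1 log2 shift recovered
    params = SimParams(seed=42, translation_shift=1.0)
    rng = np.random.default_rng(42)
    truth = build_truth(params, rng)
    counts = generate_polysome(truth, params, rng)
    res = polysome_shift_test(counts, truth.top_genes)
    assert abs(res["mean_difference"] - 1.0) < 0.15
    assert res["p"] < 0.01


def test_shift_test_degenerate_set():
    params = SimParams(seed=43)
    rng = np.random.default_rng(43)
    truth = build_truth(params, rng)
    counts = generate_polysome(truth, params, rng)
    res = polysome_shift_test(counts, truth.top_genes[:1])
    assert res["degenerate"] and np.isnan(res["p"])
    assert np.isfinite(res["mean_difference"])


def test_shift_test_empty_set_errors():
    params = SimParams(seed=44)
    rng = np.random.default_rng(44)
    truth = build_truth(params, rng)
    counts = generate_polysome(truth, params, rng)
    with pytest.raises(OmixError, match="empty"):
        polysome_shift_test(counts, ["not_a_gene"])
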