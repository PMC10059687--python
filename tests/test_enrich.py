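import itertools
import math

import numpy as np
import pandas as pd
import pytest

from omixmod import (
    OmixError,
    kmer_enrichment,
    map_kmers_to_motifs,
    mirna_site_density,
    set_overrepresentation,
)
from omixmod.enrich import count_kmers, kmer_id_to_string


def hypergeom_tail_by_enumeration(universe, set_size, draw, overlap, upper=True):
    """Exact tail probability by enumerating every draw of the universe."""
    hits = 0
    total = 0
    items = range(universe)
    special = set(range(set_size))
    for combo in itertools.combinations(items, draw):
        total += 1
        x = len(special & set(combo))
        if (x >= overlap) if upper else (x <= overlap):
            hits += 1
    return hits / total


def test_ora_exact_against_enumeration():
    # universe 20, module of 8, gene set of 5, full overlap 5
    modules = pd.Series([1] * 8 + [2] * 12, index=[f"g{i}" for i in range(20)])
    gene_sets = {"set": {f"g{i}" for i in range(5)}}  # g0..g4 all in module 1
    out = set_overrepresentation(gene_sets, modules).set_index("module")
    expected = math.comb(5, 5) * math.comb(15, 3) / math.comb(20, 8)
    assert out.loc[1, "p_over"] == pytest.approx(expected, rel=1e-12)
    brute = hypergeom_tail_by_enumeration(20, 5, 8, 5, upper=True)
    assert out.loc[1, "p_over"] == pytest.approx(brute, rel=1e-9)
    brute_under = hypergeom_tail_by_enumeration(20, 5, 8, 5, upper=False)
    assert out.loc[1, "p_under"] == pytest.approx(brute_under, rel=1e-9)


def test_ora_small_universe_matches_enumeration_generally(rng):
    for _ in range(5):
        universe = int(rng.integers(8, 16))
        set_size = int(rng.integers(2, universe - 2))
        module_size = int(rng.integers(2, universe - 2))
        genes = [f"g{i}" for i in range(universe)]
        modules = pd.Series([1] * module_size + [2] * (universe - module_size),
                            index=genes)
        gset = {f"g{i}" for i in rng.choice(universe, set_size, replace=False)}
        out = set_overrepresentation({"s": gset}, modules).set_index("module")
        overlap = int(out.loc[1, "overlap"])
        brute = hypergeom_tail_by_enumeration(universe, set_size, module_size,
                                              overlap, upper=True)
        # relabel: enumeration assumes the special items are the first set_size;
        # hypergeometric depends only on the sizes, so compare via scipy identity
        from scipy.stats import hypergeom
        assert out.loc[1, "p_over"] == pytest.approx(
            hypergeom.sf(overlap - 1, universe, set_size, module_size), rel=1e-12)
        assert brute == pytest.approx(
            hypergeom.sf(overlap - 1, universe, set_size, module_size), rel=1e-9)


def test_ora_expected_overlap_not_significant(rng):
    # overlap equal to expectation: neither tail significant
    genes = [f"g{i}" for i in range(20)]
    modules = pd.Series([1] * 10 + [2] * 10, index=genes)
    gene_sets = {"s": {"g0", "g1", "g2", "g10", "g11", "g12"}}  # 3 of 6 in each
    out = set_overrepresentation(gene_sets, modules)
    assert (out["p_over"] > 0.2).all() and (out["p_under"] > 0.2).all()


def test_ora_empty_intersection_errors():
    modules = pd.Series([1, 2], index=["g1", "g2"])
    with pytest.raises(OmixError, match="empty intersection"):
        set_overrepresentation({"s": {"nope"}}, modules)


def test_kmer_counting_overlapping_and_short():
    counts, total = count_kmers(["ATTTATTTA"], 5)
    idx = [kmer_id_to_string(i, 5) for i in np.flatnonzero(counts)]
    assert total == 5
    assert counts.sum() == 5
    assert "ATTTA" in idx
    counts2, total2 = count_kmers(["ACG"], 6)  # shorter than k
    assert total2 == 0 and counts2.sum() == 0


def test_kmer_self_comparison_null():
    seqs = ["ACGTACGTGGCC", "TTGCATGCAATT"]
    out = kmer_enrichment(seqs, seqs, k=4)
    present = out[out["bg_count"] > 0]
    assert (present["p"] == 1.0).all()
    assert (present["enrichment"] == 1.0).all()
    assert (out["adj_p"] >= out["p"]).all()


def test_kmer_planted_motif_is_top_hit(rng):
    bases = np.array(list("ACGT"))
    bg = ["".join(rng.choice(bases, 200)) for _ in range(200)]
    fg = []
    for i in range(20):
        s = list(bg[i])
        for _ in range(3):
            pos = rng.integers(0, len(s) - 6)
            s[pos:pos + 6] = list("TGCATG")
        fg.append("".join(s))
    bg = fg + bg[20:]
    out = kmer_enrichment(fg, bg, k=6)
    assert out.index[0] == "TGCATG"
    assert out.iloc[0]["direction"] == "over"
    assert out.iloc[0]["adj_p"] < 0.05


def test_kmer_depleted_motif_detected_under(rng):
    from scipy.stats import hypergeom
    bases = np.array(list("ACG"))  # no T: fg cannot contain AAAAAA? use planted
    bg_extra = ["AAAAAAAAAA"] * 5          # background rich in AAAAAA
    fg = ["".join(rng.choice(np.array(list("CG")), 50)) for _ in range(10)]
    bg = fg + bg_extra
    out = kmer_enrichment(fg, bg, k=6)
    row = out.loc["AAAAAA"]
    assert row["direction"] == "under"
    fg_total, bg_total = int(row["fg_total"]), int(row["bg_total"])
    expected = hypergeom.cdf(0, bg_total, int(row["bg_count"]), fg_total)
    assert row["p"] == pytest.approx(min(1.0, 2 * expected))


def test_kmer_requires_subset():
    with pytest.raises(OmixError, match="subset"):
        kmer_enrichment(["ACGTACGT"], ["GGGGGGGG"], k=4)


def test_iupac_motif_mapping():
    results = pd.DataFrame(index=["TGCATG", "CCCCCC"])
    motifs = pd.DataFrame({
        "rbp_name": ["RBFOX", "W_TEST"],
        "motif": ["TGCATG", "WGCATG"],
    })
    out = map_kmers_to_motifs(results, motifs)
    assert "RBFOX:TGCATG" in out.loc["TGCATG", "mapped_motifs"]
    assert "W_TEST:WGCATG" in out.loc["TGCATG", "mapped_motifs"]
    assert out.loc["CCCCCC", "mapped_motifs"] == ""


def test_iupac_malformed_code_errors():
    motifs = pd.DataFrame({"rbp_name": ["X"], "motif": ["TGZATG"]})
    with pytest.raises(OmixError, match="TGZATG"):
        map_kmers_to_motifs(pd.DataFrame(index=["TGCATG"]), motifs)


def test_mirna_density_arithmetic():
    seed = "AAGGCAC"                      # target site = revcomp = GTGCCTT
    utrs = {"empty": "", "one": "G" * 500 + "GTGCCTT" + "G" * 493}
    dens = mirna_site_density(utrs, [seed])
    assert dens["empty"] == 0.0
    assert dens["one"] == pytest.approx(1.0)


def test_mirna_density_power(rng):
    from scipy.stats import mannwhitneyu
    seed = "AAGGCAC"
    target = "GTGCCTT"
    bases = np.array(list("ACGT"))

    def utr(n_sites):
        s = list("".join(rng.choice(bases, 1000)))
        for _ in range(n_sites):
            pos = rng.integers(0, 993)
            s[pos:pos + 7] = list(target)
        return "".join(s)

    lo = {f"a{i}": utr(1) for i in range(200)}
    hi = {f"b{i}": utr(2)for i in range(200)}
    dens = mirna_site_density({**lo, **hi}, [seed])
    p = mannwhitneyu(dens[[*hi]], dens[[*lo]], alternative="greater").pvalue
    assert p < 0.01
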