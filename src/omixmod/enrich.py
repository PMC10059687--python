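"""k-mer motif enrichment, miRNA seed-site density, and gene-set ORA.

The k-mer method compares, for every k-mer of length k, its occurrence
frequency among the overlapping scan positions of a foreground UTR set
(a module) against a background set (the whole gene set, of which the
foreground is a subset).  Significance is hypergeometric on positions, with
over/under direction taken from the sign of the deviation, and
Benjamini-Hochberg adjustment across all k-mers.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import OmixError

log = logging.getLogger("omixmod")

_BASE = {"A": 0, "C": 1, "G": 2, "T": 3}
_BASES = "ACGT"

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMP = str.maketrans("ACGT", "TGCA")


def _encode(seq: str) -> np.ndarray:
    return np.array([_BASE.get(ch, -1) for ch in seq.upper()], dtype=np.int64)


def count_kmers(seqs, k: int) -> tuple[np.ndarray, int]:
    """Occurrence count per k-mer id (base-4 encoding) plus total positions.

    Overlapping scan of every sequence; windows containing non-ACGT characters
    are skipped.  Sequences shorter than k contribute zero positions.
    """
    counts = np.zeros(4**k, dtype=np.int64)
    total = 0
    powers = 4 ** np.arange(k - 1, -1, -1)
    short_warned = False
    for seq in seqs:
        enc = _encode(seq)
        if len(enc) < k:
            if not short_warned and len(seq) > 0:
                log.warning("sequence shorter than k=%d contributes no positions", k)
                short_warned = True
            continue
        windows = np.lib.stride_tricks.sliding_window_view(enc, k)
        valid = (windows >= 0).all(axis=1)
        ids = windows[valid] @ powers
        np.add.at(counts, ids, 1)
        total += int(valid.sum())
    return counts, total


def kmer_id_to_string(i: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append(_BASES[i % 4])
        i //= 4
    return "".join(reversed(out))


def kmer_enrichment(fg_seqs, bg_seqs, k: int = 6, alpha: float = 0.05) -> pd.DataFrame:
    """Per-k-mer over/underrepresentation of a foreground UTR set vs background.

    The foreground must be a subset of the background (module over the entire
    gene set).  Test: hypergeometric on k-mer positions — of ``bg_total``
    positions, ``bg_count`` contain the k-mer and ``fg_total`` were drawn into
    the foreground; two-sidedness via doubling the smaller one-sided tail.
    """
    fg_counts, fg_total = count_kmers(fg_seqs, k)
    bg_counts, bg_total = count_kmers(bg_seqs, k)
    if fg_total > bg_total or np.any(fg_counts > bg_counts):
        raise OmixError("foreground is not a subset of the background")
    if bg_total == 0:
        raise OmixError("background contributes no scan positions")
    p_over = stats.hypergeom.sf(fg_counts - 1, bg_total, bg_counts, fg_total)
    p_under = stats.hypergeom.cdf(fg_counts, bg_total, bg_counts, fg_total)
    with np.errstate(divide="ignore", invalid="ignore"):
        enr = (fg_counts / fg_total) / np.where(bg_counts > 0, bg_counts / bg_total, np.nan)
    direction = np.where(fg_counts / fg_total >= bg_counts / bg_total, "over", "under")
    p = np.minimum(1.0, 2 * np.minimum(p_over, p_under))
    adj = multipletests(p, method="fdr_bh")[1]
    out = pd.DataFrame({
        "kmer": [kmer_id_to_string(i, k) for i in range(4**k)],
        "fg_count": fg_counts, "bg_count": bg_counts,
        "fg_total": fg_total, "bg_total": bg_total,
        "enrichment": enr, "p": p, "adj_p": np.maximum(adj, p),
        "direction": direction,
    }).set_index("kmer")
    return out.sort_values(["adj_p", "p"])


def iupac_regex(motif: str) -> str:
    try:
        return "".join(f"[{IUPAC[ch]}]" if len(IUPAC[ch]) > 1 else IUPAC[ch]
                       for ch in motif.upper())
    except KeyError as exc:
        raise OmixError(f"malformed IUPAC code {exc.args[0]!r} in motif {motif!r}") from exc


def map_kmers_to_motifs(results: pd.DataFrame, motif_table: pd.DataFrame) -> pd.DataFrame:
    """Annotate each k-mer with every RBP motif whose IUPAC consensus matches.

    ``motif_table`` columns: rbp_name, motif.  A motif matches a k-mer if its
    consensus (length <= k) matches at any offset.
    """
    patterns = [
        (row["rbp_name"], row["motif"], re.compile(iupac_regex(row["motif"])))
        for _, row in motif_table.iterrows()
    ]
    annotated = results.copy()
    annotated["mapped_motifs"] = [
        ";".join(f"{name}:{motif}" for name, motif, pat in patterns if pat.search(kmer))
        for kmer in annotated.index
    ]
    return annotated


def mirna_site_density(utr3_by_gene: dict[str, str], seeds) -> pd.Series:
    """Per-gene density (sites/kb of 3'UTR) of miRNA seed matches.

    ``seeds`` are 7-mer seed-match sequences given in miRNA orientation; the
    3'UTR is scanned for their reverse complements, overlapping occurrences
    counted.
    """
    targets = [s.upper().replace("U", "T").translate(_COMP)[::-1] for s in seeds]
    dens = {}
    for gene, utr in utr3_by_gene.items():
        s = utr.upper()
        if not s:
            dens[gene] = 0.0
            continue
        n = sum(
            sum(1 for i in range(len(s) - len(t) + 1) if s[i : i + len(t)] == t)
            for t in targets
        )
        dens[gene] = n * 1000.0 / len(s)
    return pd.Series(dens, name="mirna_sites_per_kb")


@dataclass
class OraResult:
    gene_set: str
    module: object
    overlap: int
    set_size: int
    module_size: int
    universe_size: int
    odds_ratio: float
    p_over: float
    p_under: float


def set_overrepresentation(
    gene_sets: dict[str, set],
    modules: pd.Series,
    universe: set | None = None,
) -> pd.DataFrame:
    """Hypergeometric over/underrepresentation of gene sets across modules.

    Universe defaults to all genes carrying a module label.  One-sided upper
    (over) and lower (under) tail p-values per module x set, BH-adjusted
    jointly across all module x set combinations; odds ratio from the 2x2
    table with a Haldane 0.5 correction when a margin is zero.
    """
    if universe is None:
        universe = set(modules.index)
    rows = []
    for name, gset in gene_sets.items():
        gset = set(gset) & universe
        if not gset:
            raise OmixError(f"gene set {name!r} has empty intersection with the universe")
        for mod in sorted(modules.unique()):
            members = set(modules.index[modules == mod]) & universe
            x = len(gset & members)
            M, n, N = len(universe), len(gset), len(members)
            p_over = float(stats.hypergeom.sf(x - 1, M, n, N))
            p_under = float(stats.hypergeom.cdf(x, M, n, N))
            a, b = x, n - x
            c, d = N - x, M - n - N + x
            if min(a, b, c, d) == 0:
                a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
            rows.append(OraResult(name, mod, x, n, N, M, (a * d) / (b * c), p_over, p_under))
    out = pd.DataFrame([vars(r) for r in rows])
    out["adj_p_over"] = multipletests(out["p_over"], method="fdr_bh")[1]
    out["adj_p_under"] = multipletests(out["p_under"], method="fdr_bh")[1]
    return out
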