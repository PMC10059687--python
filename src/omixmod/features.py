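"""Per-transcript cis-regulatory features and module-wise comparisons.

Features computed per transcript (DNA alphabet, 0-based):

* Kozak context score — similarity of the 11-nt window around the start codon
  (positions -6..+4) to the consensus GCCRCCATGG, scored as the fraction of
  the seven informative positions (-6..-1 and +4) that match; R = A or G.
* uORF count — occurrences of the trinucleotide [ACT]TG anywhere upstream of
  the main ORF (bare occurrence rule; overlapping matches all count).
* 5'TOP flag — transcript 5' terminus starts with C followed by at least four
  further pyrimidines (an initial C + pyrimidine run of length >= 5).
* ARE density — overlapping ATTTA pentamers per kb of 3'UTR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix, OmixError, TranscriptModel

log = logging.getLogger("omixmod")

KOZAK_CONSENSUS = "GCCRCC"  # positions -6..-1; +4 consensus is G
PYRIMIDINES = set("CT")


def kozak_context_score(context: str) -> float:
    """Score the 10-nt window GCCRCCATGG (-6..+4, A of ATG is +1).

    ``context`` must carry ATG at offsets 6..8; shorter 5'UTRs are padded with
    N on the left (N never matches).  Returns matches/7 over the scored
    positions -6..-1 and +4.
    """
    context = context.upper()
    if len(context) != 10 or context[6:9] != "ATG":
        raise OmixError(f"expected 10-nt window with ATG at +1..+3, got {context!r}")
    score = 0
    for i, cons in enumerate(KOZAK_CONSENSUS):  # positions -6..-1
        base = context[i]
        if cons == "R":
            score += base in "AG"
        else:
            score += base == cons
    score += context[9] == "G"  # position +4
    return score / 7.0


def kozak_window(utr5: str, cds: str) -> str:
    """Build the -6..+4 window from a transcript's 5'UTR and CDS."""
    if not cds.upper().startswith("ATG"):
        raise OmixError("CDS does not start with ATG; no start-codon context")
    left = utr5[-6:].rjust(6, "N")
    return (left + cds[:4].ljust(4, "N")).upper()


def count_uorfs(utr5: str) -> int:
    """Number of (possibly overlapping) [ACT]TG matches in the 5'UTR."""
    s = utr5.upper()
    return sum(1 for i in range(len(s) - 2) if s[i] in "ACT" and s[i + 1 : i + 3] == "TG")


def detect_top_motif(seq: str) -> tuple[bool, int]:
    """5'TOP call on a transcript's 5' terminus.

    True iff the first base is C and the initial pyrimidine run is at least 5
    long.  Returns (flag, run length).
    """
    s = seq.upper()
    run = 0
    for ch in s:
        if ch in PYRIMIDINES:
            run += 1
        else:
            break
    return bool(s[:1] == "C" and run >= 5), run


def are_density(utr3: str) -> float:
    """Overlapping ATTTA pentamers per kb of 3'UTR (0 for an empty UTR)."""
    s = utr3.upper()
    if not s:
        return 0.0
    n = sum(1 for i in range(len(s) - 4) if s[i : i + 5] == "ATTTA")
    return n * 1000.0 / len(s)


@dataclass
class FeatureVector:
    transcript_id: str
    gene_id: str
    kozak_score: float
    uorf_count: int
    top_flag: bool
    top_run: int
    are_density: float
    len_utr5: int
    len_cds: int
    len_utr3: int
    mean_tpm: float


def feature_table(
    transcripts: dict[str, TranscriptModel],
    tpm: ExpressionMatrix,
    transcript_gene: dict[str, str] | None = None,
    min_mean_tpm: float = 1.0,
) -> pd.DataFrame:
    """Compute the per-transcript feature table for detected transcripts.

    Transcripts whose gene's mean TPM is not strictly above ``min_mean_tpm``
    are excluded.  Genes with no surviving transcript are logged.
    """
    mean_tpm = tpm.values.mean(axis=1)
    rows = []
    lost_genes = set()
    for tid, tm in transcripts.items():
        gid = (transcript_gene or {}).get(tid, tm.gene_id)
        mt = float(mean_tpm.get(gid, 0.0))
        if not mt > min_mean_tpm:
            lost_genes.add(gid)
            continue
        try:
            kozak = kozak_context_score(kozak_window(tm.utr5, tm.cds))
        except OmixError:
            kozak = np.nan
        top, run = detect_top_motif(tm.utr5 if tm.utr5 else tm.cds)
        rows.append(FeatureVector(
            transcript_id=tid, gene_id=gid,
            kozak_score=kozak,
            uorf_count=count_uorfs(tm.utr5),
            top_flag=top, top_run=run,
            are_density=are_density(tm.utr3),
            len_utr5=tm.len_utr5, len_cds=tm.len_cds, len_utr3=tm.len_utr3,
            mean_tpm=mt,
        ))
    out = pd.DataFrame([vars(r) for r in rows]).set_index("transcript_id") if rows else pd.DataFrame()
    surviving = set(out["gene_id"]) if len(out) else set()
    truly_lost = lost_genes - surviving
    if truly_lost:
        log.info("feature_table: %d genes with no transcript above mean TPM %.3g",
                 len(truly_lost), min_mean_tpm)
    return out


def pairwise_module_tests(
    features: pd.DataFrame,
    modules: pd.Series,
    feature: str,
    alpha: float = 0.01,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-sided rank-sum (Wilcoxon) test of a feature between every module pair.

    Returns (symmetric p-value matrix, boolean significance marks at
    ``alpha``).  Diagonal is p = 1 by convention; modules with fewer than two
    members get NaN rows/columns.
    """
    by_gene = features.groupby("gene_id")[feature].mean()
    groups = {}
    for mod in sorted(modules.unique()):
        vals = by_gene.reindex(modules.index[modules == mod]).dropna().to_numpy()
        groups[mod] = vals
    mods = list(groups)
    if sum(len(v) >= 2 for v in groups.values()) < 2:
        raise OmixError("need at least two modules with >= 2 members")
    P = pd.DataFrame(np.ones((len(mods), len(mods))), index=mods, columns=mods)
    for i, a in enumerate(mods):
        for b in mods[i + 1:]:
            if len(groups[a]) < 2 or len(groups[b]) < 2:
                P.loc[a, b] = P.loc[b, a] = np.nan
                continue
            p = stats.mannwhitneyu(groups[a], groups[b], alternative="two-sided").pvalue
            P.loc[a, b] = P.loc[b, a] = p
    small = [m for m in mods if len(groups[m]) < 2]
    for m in small:
        P.loc[m, :] = np.nan
        P.loc[:, m] = np.nan
    marks = P < alpha
    return P, marks
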