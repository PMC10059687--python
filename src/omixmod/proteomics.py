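"""TMT proteomics normalization and volcano significance.

Raw reporter-ion intensities are turned into cross-batch-comparable abundances
in two steps, following the iBAQ-style convention: each protein's summed
intensity is divided by its number of theoretically observable tryptic
peptides (fully tryptic products of length 7-30 aa), then referenced to the
batch's bridge channel — a pooled mix of all samples carried in every TMT
batch — making channels comparable across batches.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, OmixError

log = logging.getLogger("omixmod")

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWYX")


@dataclass
class DigestParams:
    """Tryptic-digest settings for theoretical peptide counting."""

    min_len: int = 7
    max_len: int = 30
    missed_cleavages: int = 0
    proline_rule: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.min_len <= self.max_len):
            raise OmixError("need 0 < min_len <= max_len")
        if self.missed_cleavages < 0:
            raise OmixError("missed_cleavages must be >= 0")


@dataclass
class VolcanoParams:
    """Curved volcano-plot significance rule.

    ``as_printed`` applies -log10(p) >= c*|x| - x0 directly; ``hyperbolic``
    requires |x| > x0 and -log10(p) >= c / (|x| - x0).  The linear form admits
    significance at x = 0 whenever p <= 10^x0 is combined with x0 > 0, which
    sits oddly with x0 being a *minimum* enrichment; the hyperbolic reading is
    the conventional curve and is available for that reason.
    """

    c: float = 3.65
    x0: float = 1.75
    form: str = "as_printed"

    def __post_init__(self) -> None:
        if self.c <= 0:
            raise OmixError("curvature c must be > 0")
        if self.x0 < 0:
            raise OmixError("x0 must be >= 0")
        if self.form not in ("as_printed", "hyperbolic"):
            raise OmixError(f"unknown volcano form {self.form!r}")


def tryptic_fragments(seq: str) -> list[str]:
    """Fully tryptic fragments: cleave C-terminal to K/R, not before P.

    X is tolerated as an unknown residue and never a cleavage site.
    """
    bad = [(i, ch) for i, ch in enumerate(seq) if ch not in AMINO_ACIDS]
    if bad:
        i, ch = bad[0]
        raise OmixError(f"illegal amino-acid character {ch!r} at position {i}")
    frags, start = [], 0
    for i, ch in enumerate(seq):
        if ch in "KR" and (i + 1 >= len(seq) or seq[i + 1] != "P"):
            frags.append(seq[start : i + 1])
            start = i + 1
    if start < len(seq):
        frags.append(seq[start:])
    return frags


def count_observable_peptides(seq: str, params: DigestParams | None = None) -> int:
    """Number of theoretically observable tryptic peptides of a protein.

    Counts fully tryptic peptides (with up to ``missed_cleavages`` internal
    uncleaved sites) whose length falls in [min_len, max_len].
    """
    params = params or DigestParams()
    seq = str(seq).upper()
    if not seq:
        log.warning("empty protein sequence: observable peptide count 0")
        return 0
    frags = tryptic_fragments(seq) if params.proline_rule else _fragments_no_proline(seq)
    n = 0
    for i in range(len(frags)):
        for j in range(i, min(i + params.missed_cleavages + 1, len(frags))):
            length = sum(len(f) for f in frags[i : j + 1])
            if params.min_len <= length <= params.max_len:
                n += 1
    return n


def _fragments_no_proline(seq: str) -> list[str]:
    bad = [(i, ch) for i, ch in enumerate(seq) if ch not in AMINO_ACIDS]
    if bad:
        i, ch = bad[0]
        raise OmixError(f"illegal amino-acid character {ch!r} at position {i}")
    frags = [f for f in re.split(r"(?<=[KR])", seq) if f]
    return frags


def normalize_protein_abundance(
    batches: dict[str, ExpressionMatrix],
    peptide_counts: dict[str, int] | pd.Series,
    bridge_channels: dict[str, str],
) -> ExpressionMatrix:
    """Peptide-count and bridge-channel normalization across TMT batches.

    Per protein and channel: intensity / observable-peptide count, then divided
    by the same protein's (peptide-normalized) value in that batch's bridge
    channel.  The two divisions commute; peptide count first is the order used.
    Bridge columns are removed from the output.  Proteins with a zero or
    missing peptide count, or zero bridge intensity in any batch, are dropped
    with a warning (never silently divided).
    """
    counts = pd.Series(peptide_counts, dtype=float)
    pieces, metas = [], []
    dropped: set[str] = set()
    common = None
    for name, mat in batches.items():
        common = set(mat.feature_ids) if common is None else common & set(mat.feature_ids)
    common = sorted(common or set())
    no_count = [p for p in common if p not in counts.index or counts[p] <= 0]
    if no_count:
        log.warning("%d proteins excluded: zero/missing observable peptide count (%s...)",
                    len(no_count), no_count[:3])
        dropped.update(no_count)
    kept = [p for p in common if p not in dropped]
    for name, mat in batches.items():
        bridge = bridge_channels[name]
        if bridge not in mat.sample_ids:
            raise OmixError(f"bridge channel {bridge!r} not found in batch {name!r}")
        vals = mat.values.loc[kept].div(counts[kept], axis=0)
        zero_bridge = vals.index[vals[bridge] <= 0].tolist()
        if zero_bridge:
            log.warning("batch %s: %d proteins dropped for zero bridge intensity: %s...",
                        name, len(zero_bridge), zero_bridge[:3])
            dropped.update(zero_bridge)
        ratio = vals.div(vals[bridge], axis=0).drop(columns=[bridge])
        pieces.append(ratio)
        metas.append(mat.meta.drop(index=[bridge]))
    kept = [p for p in kept if p not in dropped]
    merged = pd.concat([p.loc[kept] for p in pieces], axis=1)
    meta = pd.concat(metas)
    return ExpressionMatrix(merged, meta, "reporter_intensity")


def volcano_significant(x, p, params: VolcanoParams | None = None):
    """Significance call(s) for enrichment x (log2 fold change) and p-value."""
    params = params or VolcanoParams()
    x = np.asarray(x, dtype=float)
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0) or np.any(p > 1):
        raise OmixError("p-values must lie in (0, 1]")
    neglogp = -np.log10(p)
    ax = np.abs(x)
    if params.form == "as_printed":
        sig = neglogp >= params.c * ax - params.x0
    else:
        with np.errstate(divide="ignore"):
            sig = (ax > params.x0) & (neglogp >= params.c / np.where(ax > params.x0, ax - params.x0, np.inf))
    return bool(sig) if sig.ndim == 0 else sig
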