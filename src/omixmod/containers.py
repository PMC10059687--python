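"""Core in-memory containers shared across the pipeline.

The pipeline works on dense gene x sample matrices (study scale is roughly
10^4 genes by at most a few dozen samples), so plain :class:`pandas.DataFrame`
objects wrapped in light dataclasses are used throughout.  Sample metadata is
kept as a DataFrame indexed by sample id whose columns mirror the experimental
design: cell class (progenitor vs neuron), organoid age in days, differentiation
batch, assay platform, and — for polysome experiments — ribosome fraction and
genotype.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CELL_CLASSES = ("progenitor", "neuron")
DAYS = (40, 60, 90, 120)
ASSAYS = ("rna", "protein")
FRACTIONS = ("monosome", "low_poly", "high_poly")
GENOTYPES = ("control", "tsc2_ko")
UNITS = ("tpm", "raw_count", "reporter_intensity", "zscore")

#: Columns every sample-metadata table must carry (fraction/genotype may be NA).
META_COLUMNS = ("cell_class", "day", "batch", "assay", "fraction", "genotype")


class OmixError(ValueError):
    """Raised on contract violations (bad input files, inconsistent metadata)."""


def validate_meta(meta: pd.DataFrame, *, time_grid=DAYS) -> pd.DataFrame:
    """Validate and canonicalize a sample-metadata table.

    Index must be unique sample ids; missing optional columns are added as NA.
    """
    if meta.index.has_duplicates:
        dupes = meta.index[meta.index.duplicated()].unique().tolist()
        raise OmixError(f"duplicate sample ids in metadata: {dupes}")
    meta = meta.copy()
    for col in META_COLUMNS:
        if col not in meta.columns:
            if col in ("fraction", "genotype"):
                meta[col] = pd.NA
            else:
                raise OmixError(f"metadata missing required column {col!r}")
    bad_class = set(meta["cell_class"].dropna()) - set(CELL_CLASSES)
    if bad_class:
        raise OmixError(f"unknown cell_class values: {sorted(bad_class)}")
    bad_assay = set(meta["assay"].dropna()) - set(ASSAYS)
    if bad_assay:
        raise OmixError(f"unknown assay values: {sorted(bad_assay)}")
    days = meta["day"].dropna()
    bad_day = set(days.astype(int)) - set(time_grid)
    if bad_day:
        raise OmixError(f"day values outside declared time grid {time_grid}: {sorted(bad_day)}")
    bad_frac = set(meta["fraction"].dropna()) - set(FRACTIONS)
    if bad_frac:
        raise OmixError(f"unknown fraction values: {sorted(bad_frac)}")
    bad_geno = set(meta["genotype"].dropna()) - set(GENOTYPES)
    if bad_geno:
        raise OmixError(f"unknown genotype values: {sorted(bad_geno)}")
    return meta[list(META_COLUMNS)]


@dataclass
class ExpressionMatrix:
    """A genes x samples abundance matrix with per-column sample metadata.

    Parameters
    ----------
    values
        DataFrame, rows indexed by feature id, columns by sample id.
    meta
        DataFrame indexed by sample id (same order as ``values.columns``).
    unit
        One of ``tpm``, ``raw_count``, ``reporter_intensity``, ``zscore``.
        Non-z-score units must be non-negative.
    """

    values: pd.DataFrame
    meta: pd.DataFrame
    unit: str

    def __post_init__(self) -> None:
        if self.unit not in UNITS:
            raise OmixError(f"unknown unit {self.unit!r}; expected one of {UNITS}")
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise OmixError(f"duplicate feature ids: {dupes[:5]}")
        if self.values.columns.has_duplicates:
            raise OmixError("duplicate sample ids in matrix columns")
        missing = [c for c in self.values.columns if c not in self.meta.index]
        if missing:
            raise OmixError(f"samples without metadata: {missing}")
        self.meta = validate_meta(self.meta.loc[list(self.values.columns)])
        arr = self.values.to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)):
            raise OmixError("non-finite values in expression matrix")
        if self.unit != "zscore" and (arr < 0).any():
            r, c = np.argwhere(arr < 0)[0]
            raise OmixError(
                f"negative value under unit={self.unit!r} at "
                f"feature {self.values.index[r]!r}, sample {self.values.columns[c]!r}"
            )

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        sample_ids = list(sample_ids)
        return ExpressionMatrix(self.values[sample_ids], self.meta.loc[sample_ids], self.unit)

    def subset_features(self, feature_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(feature_ids)], self.meta, self.unit)


@dataclass
class TranscriptModel:
    """Per-transcript sequence regions in the DNA alphabet (U mapped to T)."""

    transcript_id: str
    gene_id: str
    utr5: str = ""
    cds: str = ""
    utr3: str = ""
    was_rna_alphabet: bool = False
    missing_regions: tuple = ()
    cds_frame_warning: bool = False

    @property
    def len_utr5(self) -> int:
        return len(self.utr5)

    @property
    def len_cds(self) -> int:
        return len(self.cds)

    @property
    def len_utr3(self) -> int:
        return len(self.utr3)

    @property
    def mrna(self) -> str:
        """Full transcript sequence (5'UTR + CDS + 3'UTR)."""
        return self.utr5 + self.cds + self.utr3


@dataclass
class IntegratedMatrix:
    """Z-scored genes x samples matrix spanning both assays.

    Rows are keyed by protein id (the join key between assays); ``gene_map``
    records the underlying gene id(s) per row.  Within each assay every
    non-constant row has mean ~0 and sd ~1 over that assay's samples.
    """

    values: pd.DataFrame
    meta: pd.DataFrame
    gene_map: pd.DataFrame  # columns: protein_id, gene_id
    constant_rows: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.meta = validate_meta(self.meta.loc[list(self.values.columns)])

    def assay_samples(self, assay: str) -> list[str]:
        return list(self.meta.index[self.meta["assay"] == assay])


def condition_profiles(integrated: IntegratedMatrix) -> pd.DataFrame:
    """Mean z-score per (assay, cell class, day) cell — the 16-condition profile.

    Replicates (batches) are averaged within each condition.  Columns are
    ordered assay-major then class then day so that profiles from different
    datasets align positionally.
    """
    meta = integrated.meta
    cols = {}
    for assay in ASSAYS:
        for cls in CELL_CLASSES:
            for day in DAYS:
                sel = meta.index[
                    (meta["assay"] == assay)
                    & (meta["cell_class"] == cls)
                    & (meta["day"].astype(int) == day)
                ]
                if len(sel) == 0:
                    continue
                cols[f"{assay}.{cls}.d{day}"] = integrated.values[list(sel)].mean(axis=1)
    return pd.DataFrame(cols, index=integrated.values.index)
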