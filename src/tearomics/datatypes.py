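"""Core in-memory containers shared across the pipeline stages.

All tabular payloads are pandas objects; protein/taxon identifiers live on
the index, sample identifiers on the columns, so every stage can rely on
label alignment rather than positional bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

GROUPS = ("patient", "control")
SEXES = ("female", "male")


@dataclass
class ProteinGroupTable:
    """Protein-group quantification matrix (proteins x samples).

    ``intensities`` holds NaN wherever a protein was not quantified in a
    sample; the missingness mask is derived from it, so mask and matrix can
    never disagree.  ``scale`` flags whether values are raw label-free
    quantification intensities or log2-transformed ones.
    """

    intensities: pd.DataFrame
    peptide_counts: pd.Series
    contaminant: pd.Series
    scale: str = "log2"  # "log2" | "raw"

    def __post_init__(self) -> None:
        if self.scale not in ("log2", "raw"):
            raise ValueError(f"scale must be 'log2' or 'raw', got {self.scale!r}")
        if not self.peptide_counts.index.equals(self.intensities.index):
            raise ValueError("peptide_counts index does not match intensity rows")
        if not self.contaminant.index.equals(self.intensities.index):
            raise ValueError("contaminant index does not match intensity rows")
        if (self.peptide_counts.dropna() < 0).any():
            raise ValueError("peptide_counts must be >= 0")
        if self.intensities.index.has_duplicates:
            dup = self.intensities.index[self.intensities.index.duplicated()][0]
            raise ValueError(f"duplicate protein id: {dup!r}")

    @property
    def protein_ids(self) -> pd.Index:
        return self.intensities.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.intensities.columns

    @property
    def missing_mask(self) -> pd.DataFrame:
        """True where the intensity is absent."""
        return self.intensities.isna()

    @property
    def n_proteins(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[1]

    def to_raw(self) -> "ProteinGroupTable":
        """Return the same table on the raw intensity scale (2**log2)."""
        if self.scale == "raw":
            return self
        return ProteinGroupTable(
            intensities=np.exp2(self.intensities),
            peptide_counts=self.peptide_counts.copy(),
            contaminant=self.contaminant.copy(),
            scale="raw",
        )

    def to_log2(self) -> "ProteinGroupTable":
        if self.scale == "log2":
            return self
        if (self.intensities.stack() <= 0).any():
            raise ValueError("non-positive raw intensities cannot be log2-transformed")
        return ProteinGroupTable(
            intensities=np.log2(self.intensities),
            peptide_counts=self.peptide_counts.copy(),
            contaminant=self.contaminant.copy(),
            scale="log2",
        )

    def subset(self, protein_ids) -> "ProteinGroupTable":
        return ProteinGroupTable(
            intensities=self.intensities.loc[protein_ids],
            peptide_counts=self.peptide_counts.loc[protein_ids],
            contaminant=self.contaminant.loc[protein_ids],
            scale=self.scale,
        )


@dataclass
class SampleAnnotation:
    """Per-sample metadata: disease group, sex, age."""

    table: pd.DataFrame  # index = sample_id; columns: group, sex, age

    def __post_init__(self) -> None:
        required = {"group", "sex", "age"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"annotation missing columns: {sorted(missing)}")
        bad_group = set(self.table["group"]) - set(GROUPS)
        if bad_group:
            raise ValueError(f"unknown group labels: {sorted(bad_group)}")
        bad_sex = set(self.table["sex"]) - set(SEXES)
        if bad_sex:
            raise ValueError(f"unknown sex labels: {sorted(bad_sex)}")

    @property
    def sample_ids(self) -> pd.Index:
        return self.table.index

    def samples_in(self, *, group: Optional[str] = None, sex: Optional[str] = None) -> pd.Index:
        mask = pd.Series(True, index=self.table.index)
        if group is not None:
            mask &= self.table["group"] == group
        if sex is not None:
            mask &= self.table["sex"] == sex
        return self.table.index[mask]

    def groups_vector(self, sample_ids) -> np.ndarray:
        return self.table.loc[sample_ids, "group"].to_numpy()


@dataclass
class TaxonAbundanceTable:
    """Taxa x samples relative abundances with profiler-style lineage rows.

    Row index entries are pipe-separated, rank-prefixed lineage strings
    (``k__...|p__...|...|s__...``).  ``unit`` flags percent (totals near 100)
    versus fraction (totals near 1) scale.
    """

    abundances: pd.DataFrame
    unit: str = "percent"  # "percent" | "fraction"

    def __post_init__(self) -> None:
        if self.unit not in ("percent", "fraction"):
            raise ValueError(f"unit must be 'percent' or 'fraction', got {self.unit!r}")
        if (self.abundances.to_numpy() < 0).any():
            raise ValueError("abundances must be non-negative")
        cap = 100.0 if self.unit == "percent" else 1.0
        totals = self.abundances.sum(axis=0)
        if (totals > cap + 1e-6 * cap).any():
            bad = totals.index[totals > cap + 1e-6 * cap][0]
            raise ValueError(f"sample {bad!r} total abundance exceeds {cap}")

    @property
    def taxa(self) -> pd.Index:
        return self.abundances.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.abundances.columns

    def to_fraction(self) -> "TaxonAbundanceTable":
        if self.unit == "fraction":
            return self
        return TaxonAbundanceTable(self.abundances / 100.0, unit="fraction")

    def to_percent(self) -> "TaxonAbundanceTable":
        if self.unit == "percent":
            return self
        return TaxonAbundanceTable(self.abundances * 100.0, unit="percent")


@dataclass
class SimTruth:
    """Ground truth attached to simulated data for recovery testing."""

    is_differential: Optional[pd.Series] = None  # bool per protein
    true_log2fc: Optional[pd.Series] = None
    true_within_variance: Optional[pd.Series] = None
    censor_params: Optional[tuple] = None  # (midpoint, slope)
    marker_presence: Optional[pd.Series] = None  # bool per sample (microbiome)

    def __post_init__(self) -> None:
        if self.is_differential is not None and self.true_log2fc is not None:
            null = ~self.is_differential.astype(bool)
            if (self.true_log2fc[null] != 0).any():
                raise ValueError("true_log2fc must be 0 for non-differential proteins")


@dataclass
class ModeratedTestResult:
    """Per-protein moderated-t output plus the global variance prior."""

    table: pd.DataFrame  # columns: log2fc, s2, t_mod, df_total, p_raw, p_adj
    d0_hat: float
    s0sq_hat: float
    n1: int
    n2: int


@dataclass
class DEResultTable:
    """Volcano-ready differential-expression table with stability flags."""

    table: pd.DataFrame  # ModeratedTestResult columns + significant, stable
    d0_hat: float
    s0sq_hat: float
    cycle_calls: pd.DataFrame = field(repr=False, default=None)  # proteins x cycles bool
    params: dict = field(default_factory=dict)

    @property
    def n_significant(self) -> int:
        return int(self.table["significant"].sum())

    @property
    def n_stable(self) -> int:
        return int(self.table["stable"].sum())
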