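"""Core in-memory containers shared across pipeline stages.

The substrate of every stage is an :class:`ExpressionDataset`: a probe x
sample matrix of expression intensities plus a per-sample metadata table
(genotype, differentiation day, replicate, batch). Both are pandas
DataFrames so that probe and sample identity travel with the values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

REQUIRED_META_COLUMNS = ("genotype", "day", "replicate", "batch")


class ExpressionLoadError(ValueError):
    """Raised when an expression matrix / metadata pair fails validation."""


@dataclass
class ExpressionDataset:
    """Probe x sample expression matrix with per-sample metadata.

    Parameters
    ----------
    values
        DataFrame indexed by probe ID with one column per sample ID.
    sample_meta
        DataFrame indexed by sample ID with at least the columns
        ``genotype``, ``day``, ``replicate`` and ``batch``.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ---------------------------------------------------
    def validate(self) -> None:
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ExpressionLoadError(f"duplicated probe IDs: {dup}")
        if self.values.columns.duplicated().any():
            dup = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ExpressionLoadError(f"duplicated sample IDs: {dup}")
        if self.values.isna().any().any():
            n = int(self.values.isna().sum().sum())
            raise ExpressionLoadError(
                f"expression matrix contains {n} missing values; "
                "missing data must be resolved upstream, not imputed here"
            )
        missing = [s for s in self.values.columns if s not in self.sample_meta.index]
        if missing:
            raise ExpressionLoadError(f"samples missing from metadata: {missing}")
        extra = [s for s in self.sample_meta.index if s not in self.values.columns]
        if extra:
            raise ExpressionLoadError(f"metadata rows without matrix columns: {extra}")
        absent = [c for c in REQUIRED_META_COLUMNS if c not in self.sample_meta.columns]
        if absent:
            raise ExpressionLoadError(f"metadata missing required columns: {absent}")
        # keep metadata in matrix column order
        self.sample_meta = self.sample_meta.loc[self.values.columns]

    # -- convenience --------------------------------------------------
    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, keep: list[str]) -> "ExpressionDataset":
        """Return a copy restricted to the given samples (matrix order kept)."""
        keep_ordered = [s for s in self.sample_ids if s in set(keep)]
        return ExpressionDataset(
            self.values[keep_ordered].copy(), self.sample_meta.loc[keep_ordered].copy()
        )

    # -- I/O -----------------------------------------------------------
    def to_tsv(self, matrix_path: str | Path, meta_path: str | Path) -> None:
        self.values.to_csv(matrix_path, sep="\t", index_label="probe_id")
        self.sample_meta.to_csv(meta_path, sep="\t", index_label="sample_id")


@dataclass
class ModuleSet:
    """Module labels plus eigengene summaries for a clustered dataset.

    ``labels`` maps every probe to a module name or ``None`` (unassigned).
    ``eigengenes`` is a module x sample DataFrame of unit-variance first
    principal component scores; ``var_explained`` is the fraction of the
    standardized within-module variance each eigengene captures.
    ``merge_log`` records every eigengene-similarity merge in order.
    """

    labels: pd.Series
    cut_height: float
    min_size: int
    eigengenes: pd.DataFrame | None = None
    var_explained: dict[str, float] = field(default_factory=dict)
    merge_log: list[dict] = field(default_factory=list)

    @property
    def module_names(self) -> list[str]:
        if self.eigengenes is not None:
            return list(self.eigengenes.index)
        return sorted({m for m in self.labels.dropna().unique()})

    def members(self, module: str) -> list[str]:
        return list(self.labels.index[self.labels == module])

    def sizes(self) -> pd.Series:
        return self.labels.dropna().value_counts()
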