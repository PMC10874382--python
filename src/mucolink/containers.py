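"""Shared in-memory containers.

Two light wrappers around :class:`pandas.DataFrame` carry the conventions used
throughout the package: feature matrices are stored features x samples with a
feature *kind* (gene / taxon / celltype) and a *unit* tag recording what scale
the values are on, and sample metadata is stored one row per biopsy with a
patient column expressing the repeated-measures grouping.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

FEATURE_KINDS = ("gene", "taxon", "celltype")
UNITS = ("counts", "clr", "log", "score", "residual")


@dataclass
class OmicsMatrix:
    """A features x samples numeric matrix.

    Parameters
    ----------
    data
        DataFrame with feature IDs as the index and sample IDs as columns.
    kind
        One of ``gene``, ``taxon``, ``celltype``.
    unit
        One of ``counts``, ``clr``, ``log``, ``score``, ``residual``.
    """

    data: pd.DataFrame
    kind: str
    unit: str

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}; expected one of {FEATURE_KINDS}")
        if self.unit not in UNITS:
            raise ValueError(f"unknown unit {self.unit!r}; expected one of {UNITS}")
        if not isinstance(self.data, pd.DataFrame):
            raise TypeError("data must be a pandas DataFrame (features x samples)")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature IDs: {dups}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample IDs: {dups}")
        bad = [c for c, dt in self.data.dtypes.items() if not np.issubdtype(dt, np.number)]
        if bad:
            raise ValueError(f"non-numeric sample columns: {bad}")

    @property
    def features(self) -> pd.Index:
        return self.data.index

    @property
    def samples(self) -> pd.Index:
        return self.data.columns

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_features(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset_samples(self, sample_ids: Sequence[str]) -> "OmicsMatrix":
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise KeyError(f"samples not present in matrix: {missing[:5]}")
        return replace(self, data=self.data.loc[:, list(sample_ids)])

    def subset_features(self, feature_ids: Sequence[str]) -> "OmicsMatrix":
        missing = [f for f in feature_ids if f not in self.data.index]
        if missing:
            raise KeyError(f"features not present in matrix: {missing[:5]}")
        return replace(self, data=self.data.loc[list(feature_ids)])


@dataclass
class SampleMetadata:
    """Per-biopsy covariate table indexed by sample ID.

    The ``patient_col`` column groups repeated biopsies from the same patient
    and drives every random-intercept model in the package.
    """

    data: pd.DataFrame
    patient_col: str = "patient"

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            raise TypeError("data must be a pandas DataFrame indexed by sample ID")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample IDs in metadata: {dups}")
        if self.patient_col not in self.data.columns:
            raise ValueError(f"metadata lacks patient column {self.patient_col!r}")

    @property
    def samples(self) -> pd.Index:
        return self.data.index

    @property
    def patients(self) -> pd.Series:
        return self.data[self.patient_col]

    def require(self, columns: Iterable[str]) -> None:
        missing = [c for c in columns if c not in self.data.columns]
        if missing:
            raise KeyError(f"metadata is missing required columns: {missing}")

    def subset(self, sample_ids: Sequence[str]) -> "SampleMetadata":
        missing = [s for s in sample_ids if s not in self.data.index]
        if missing:
            raise KeyError(f"samples not present in metadata: {missing[:5]}")
        return SampleMetadata(self.data.loc[list(sample_ids)], patient_col=self.patient_col)
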