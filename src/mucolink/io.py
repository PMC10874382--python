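"""TSV readers/writers for feature matrices and sample metadata.

Matrices are features x samples TSV with the feature ID in the first column;
metadata is one row per sample with the sample ID in the first column.
Loading validates uniqueness and numeric content; the sample universes of
the loaded tables are intersected with logged drop counts.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import OmicsMatrix, SampleMetadata

logger = logging.getLogger("mucolink.io")

__all__ = ["load_matrix", "load_metadata", "write_matrix", "write_metadata", "align_samples"]


def load_matrix(path: str | Path, kind: str, unit: str) -> OmicsMatrix:
    """Load a features x samples TSV matrix."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    seen: set = set()
    dup_cols = [c for c in header if c in seen or seen.add(c)]
    if dup_cols:
        # checked on the raw header: the parser would silently mangle them
        raise ValueError(f"{path}: duplicate sample columns {sorted(set(dup_cols))[:5]}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] == 0:
        raise ValueError(f"{path}: matrix has no sample columns")
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate feature IDs {dups[:5]}")
    bad = [c for c, dt in df.dtypes.items() if not np.issubdtype(dt, np.number)]
    if bad:
        raise ValueError(f"{path}: non-numeric cells in sample columns {bad[:5]}")
    return OmicsMatrix(data=df, kind=kind, unit=unit)


def load_metadata(path: str | Path, patient_col: str = "patient") -> SampleMetadata:
    """Load the per-sample metadata TSV (first column = sample ID)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate sample IDs {dups[:5]}")
    return SampleMetadata(data=df, patient_col=patient_col)


def write_matrix(m: OmicsMatrix, path: str | Path) -> Path:
    path = Path(path)
    m.data.to_csv(path, sep="\t")
    return path


def write_metadata(meta: SampleMetadata, path: str | Path) -> Path:
    path = Path(path)
    meta.data.to_csv(path, sep="\t")
    return path


def align_samples(*tables) -> list:
    """Intersect the sample universes of matrices/metadata, logging drops.

    Accepts OmicsMatrix and SampleMetadata objects; returns them subset to
    the shared samples, in the order of the first table's sample index.
    """
    universes = []
    for t in tables:
        universes.append(set(t.samples))
    shared = set.intersection(*universes)
    if not shared:
        raise ValueError("no samples shared across the input tables")
    first = tables[0].samples
    ordered = [s for s in first if s in shared]
    out = []
    for t in tables:
        dropped = len(t.samples) - len(ordered)
        if dropped:
            logger.info("dropping %d samples from %s during alignment", dropped, type(t).__name__)
        out.append(t.subset_samples(ordered) if isinstance(t, OmicsMatrix) else t.subset(ordered))
    return out
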