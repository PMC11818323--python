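"""Shared data model and file I/O.

The pipeline's universal currency is the per-cell table: one row per
segmented cell carrying its centroid (µm), nuclear area (µm²) and the
median intensity of each imaging channel.  Later stages append label
columns (cell type, isPLA call, tumour/stroma region, neighbourhood and
spatial-context assignments) onto the same table, mirroring the per-cell
export/import round trip of image-analysis platforms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

#: Imaging channels: five lineage markers, the proximity-ligation signal
#: and the nuclear counterstain.
CHANNELS = ["PanCK", "CD20", "CD3e", "CD8", "CD68", "isPLA", "DAPI"]

#: The six markers used for phenotyping (DAPI is QC-only).
MARKERS = ["PanCK", "CD20", "CD3e", "CD8", "CD68", "isPLA"]

#: The five annotated cell types.
CELL_TYPES = ["B cell", "CD3 T cell", "CD8 T cell", "Macrophage", "Tumour"]

#: RECIST 1.1 clinical response categories.
RESPONSE_GROUPS = ["CR", "PR", "SD", "PD"]

REQUIRED_COLUMNS = ["cell_id", "x", "y", "nuclear_area"] + CHANNELS

#: Columns written by downstream stages; absent until produced.
LABEL_COLUMNS = [
    "cell_type", "cluster", "ispla_positive", "region", "distance_um",
    "nearest_nest", "cn_label", "cn_label_pla", "sc_combination",
]


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class ValidationError(ValueError):
    """A table violates a per-cell invariant."""


@dataclass
class CellTable:
    """Per-cell spatial and intensity records for one tissue sample.

    Parameters
    ----------
    sample_id
        Identifier of the tissue section the cells came from.
    df
        One row per cell with at least :data:`REQUIRED_COLUMNS`.
        Label columns may be present after downstream stages have run.
    """

    sample_id: str
    df: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        for col in REQUIRED_COLUMNS:
            if col not in self.df.columns:
                raise SchemaError(f"missing required column: {col!r}")
        if self.df["cell_id"].duplicated().any():
            dup = self.df.loc[self.df["cell_id"].duplicated(), "cell_id"].iloc[0]
            raise ValidationError(f"duplicate cell_id within sample: {dup!r}")
        n = len(self.df)
        if n == 0:
            return
        xy = self.df[["x", "y"]].to_numpy(float)
        if not np.isfinite(xy).all():
            raise ValidationError("non-finite cell coordinates")
        area = self.df["nuclear_area"].to_numpy(float)
        if not (np.isfinite(area).all() and (area > 0).all()):
            raise ValidationError("nuclear_area must be finite and positive")
        inten = self.df[CHANNELS].to_numpy(float)
        if not (np.isfinite(inten).all() and (inten >= 0).all()):
            raise ValidationError("channel intensities must be finite and >= 0")
        # label columns, once present, must cover every retained cell
        for col in ("cell_type", "region", "cn_label", "cn_label_pla",
                    "sc_combination"):
            if col in self.df.columns and self.df[col].isna().any():
                raise ValidationError(f"label column {col!r} has missing values")

    # -- conveniences ----------------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    @property
    def xy(self) -> np.ndarray:
        """(n, 2) centroid array in µm."""
        return self.df[["x", "y"]].to_numpy(float)

    def with_column(self, name: str, values) -> "CellTable":
        """Return a copy with an added/replaced per-cell column."""
        df = self.df.copy()
        df[name] = np.asarray(values) if not np.isscalar(values) else values
        return CellTable(self.sample_id, df)

    def copy(self) -> "CellTable":
        return CellTable(self.sample_id, self.df.copy())


def _infer_format(path: Path, format: Optional[str]) -> str:
    if format is not None:
        return format
    return "parquet" if path.suffix in (".parquet", ".pq") else "csv"


def read_cell_table(path, sample_id: Optional[str] = None,
                    format: Optional[str] = None) -> CellTable:
    """Read a per-cell table from CSV or Parquet and validate it.

    Rows with missing x/y coordinates are rejected (dropped with a
    warning); every other invariant violation raises.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "parquet":
        df = pd.read_parquet(path)
    elif fmt == "csv":
        df = pd.read_csv(path, float_precision="round_trip")
    else:
        raise ValueError(f"unknown format: {fmt!r}")
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"{path.name}: missing required column: {col!r}")
    bad = df["x"].isna() | df["y"].isna()
    if bad.any():
        warnings.warn(f"{path.name}: rejected {int(bad.sum())} row(s) with "
                      "missing coordinates")
        df = df.loc[~bad].reset_index(drop=True)
    if "cell_id" in df.columns:
        df["cell_id"] = df["cell_id"].astype(str)
    sid = sample_id if sample_id is not None else path.stem
    return CellTable(sid, df)


def write_cell_table(table: CellTable, path, format: Optional[str] = None) -> Path:
    """Write a cell table to CSV or Parquet.

    Round-trips losslessly with :func:`read_cell_table` (CSV floats are
    written with ``repr`` precision, preserving values to < 1e-15 relative).
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "parquet":
        table.df.to_parquet(path, index=False)
    elif fmt == "csv":
        # %.17g guarantees bit-exact float64 round trips
        table.df.to_csv(path, index=False, float_format="%.17g")
    else:
        raise ValueError(f"unknown format: {fmt!r}")
    return path


@dataclass
class SampleMetadata:
    """Sample-level clinical metadata: one row per tissue sample."""

    df: pd.DataFrame  # columns: sample_id, patient_id, response_group

    def __post_init__(self) -> None:
        for col in ("sample_id", "patient_id", "response_group"):
            if col not in self.df.columns:
                raise SchemaError(f"metadata missing column: {col!r}")
        bad = set(self.df["response_group"]) - set(RESPONSE_GROUPS)
        if bad:
            raise ValidationError(
                f"response_group values outside RECIST categories: {sorted(bad)}")
        if self.df["sample_id"].duplicated().any():
            raise ValidationError("duplicate sample_id in metadata")

    def group_of(self, sample_id: str) -> str:
        row = self.df.loc[self.df["sample_id"] == sample_id]
        if row.empty:
            raise KeyError(sample_id)
        return str(row["response_group"].iloc[0])


def read_sample_metadata(path) -> SampleMetadata:
    return SampleMetadata(pd.read_csv(path, dtype=str))


def write_sample_metadata(meta: SampleMetadata, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta.df.to_csv(path, index=False)
    return path
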