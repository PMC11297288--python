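"""Data model and I/O for well-level morphological profile tables.

A *profile table* is the universal currency of the benchmark: a wells x
features matrix of numeric morphological measurements together with one
metadata record per well describing where the well sits in the experimental
hierarchy (source laboratory -> experimental batch -> plate -> well) and what
it was treated with.

Tables are stored on disk either as UTF-8 comma-delimited text (metadata
columns first, then feature columns) or as Parquet for lossless round trips.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "METADATA_COLUMNS",
    "REQUIRED_METADATA_COLUMNS",
    "CONTROL_TYPES",
    "ProfileTable",
    "WellAddress",
    "SchemaError",
    "IntegrityError",
    "read_profiles",
    "write_profiles",
    "aggregate_cells_to_wells",
    "subset",
]

#: Canonical metadata columns, in on-disk order.  ``microscope_type`` is
#: optional; all others are mandatory.
METADATA_COLUMNS = (
    "source_id",
    "batch_id",
    "plate_id",
    "well_position",
    "compound_id",
    "control_type",
    "microscope_type",
)
REQUIRED_METADATA_COLUMNS = METADATA_COLUMNS[:-1]
CONTROL_TYPES = ("negative", "positive", "treatment")


class SchemaError(ValueError):
    """A table is missing mandatory columns or has malformed values."""


class IntegrityError(ValueError):
    """A table violates a structural invariant (e.g. duplicate wells)."""


@dataclass(frozen=True)
class WellAddress:
    """Unique coordinates of one well in the experimental hierarchy."""

    source_id: str
    batch_id: str
    plate_id: str
    well_position: str


@dataclass
class ProfileTable:
    """Wells x features numeric matrix plus per-well metadata.

    Parameters
    ----------
    features
        DataFrame of shape (n_wells, n_features); all values finite floats.
    meta
        DataFrame with one row per well holding the metadata columns.
    """

    features: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.features = self.features.reset_index(drop=True)
        self.meta = self.meta.reset_index(drop=True)
        if "microscope_type" not in self.meta.columns:
            self.meta = self.meta.assign(microscope_type="unknown")
        self.validate()

    # -- structure ---------------------------------------------------------

    @property
    def n_wells(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    @property
    def feature_names(self) -> list[str]:
        return list(self.features.columns)

    def validate(self) -> None:
        missing = [c for c in REQUIRED_METADATA_COLUMNS if c not in self.meta.columns]
        if missing:
            raise SchemaError(f"missing mandatory metadata column(s): {missing}")
        if self.features.shape[0] != self.meta.shape[0]:
            raise IntegrityError(
                f"{self.features.shape[0]} feature rows vs {self.meta.shape[0]} metadata rows"
            )
        if self.features.shape[1] == 0:
            raise IntegrityError("empty table: no features")
        names = self.feature_names
        if len(set(names)) != len(names):
            raise SchemaError("duplicate feature names")
        bad = [c for c in self.features.columns
               if not np.issubdtype(self.features[c].dtype, np.number)]
        if bad:
            raise SchemaError(f"non-numeric feature column(s): {bad}")
        if self.n_wells and not np.isfinite(self.features.to_numpy()).all():
            raise SchemaError("feature matrix contains NaN or infinite values")
        bad_ct = set(self.meta["control_type"]) - set(CONTROL_TYPES)
        if bad_ct:
            raise SchemaError(f"unknown control_type value(s): {sorted(bad_ct)}")
        addr = self.meta[list(REQUIRED_METADATA_COLUMNS[:4])]
        if addr.duplicated().any():
            dup = addr[addr.duplicated()].iloc[0].to_dict()
            raise IntegrityError(f"duplicate well address: {dup}")

    def well_addresses(self) -> list[WellAddress]:
        return [
            WellAddress(r.source_id, r.batch_id, r.plate_id, r.well_position)
            for r in self.meta.itertuples(index=False)
        ]

    def matrix(self) -> np.ndarray:
        """Feature matrix as a float ndarray (copy)."""
        return self.features.to_numpy(dtype=float, copy=True)

    def with_features(self, values: np.ndarray,
                      feature_names: Sequence[str] | None = None) -> "ProfileTable":
        """New table with the same metadata and a replaced feature matrix."""
        names = list(feature_names) if feature_names is not None else self.feature_names
        feats = pd.DataFrame(np.asarray(values, dtype=float), columns=names)
        return ProfileTable(feats, self.meta.copy())

    def equals(self, other: "ProfileTable") -> bool:
        return (
            self.feature_names == other.feature_names
            and self.meta.reset_index(drop=True).equals(other.meta.reset_index(drop=True))
            and np.array_equal(self.features.to_numpy(), other.features.to_numpy())
        )


# -- readers / writers -----------------------------------------------------


def _infer_format(path: str, format: str | None) -> str:
    if format is not None:
        return format
    p = str(path)
    if p.endswith((".parquet", ".pq")):
        return "columnar"
    return "delimited"


def _split_columns(df: pd.DataFrame,
                   column_map: Mapping[str, str] | None = None) -> ProfileTable:
    if column_map:
        df = df.rename(columns=dict(column_map))
    missing = [c for c in REQUIRED_METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory metadata column(s): {missing}")
    meta_cols = [c for c in METADATA_COLUMNS if c in df.columns]
    feat_cols = [c for c in df.columns if c not in METADATA_COLUMNS]
    if not feat_cols:
        raise SchemaError("no feature columns found")
    feats = df[feat_cols]
    for c in feat_cols:
        if not np.issubdtype(feats[c].dtype, np.number):
            raise SchemaError(f"non-numeric feature column: {c!r}")
    meta = df[meta_cols].astype(str)
    return ProfileTable(feats.astype(float), meta)


def read_profiles(path, format: str | None = None,
                  column_map: Mapping[str, str] | None = None) -> ProfileTable:
    """Read a profile table from delimited text or Parquet.

    Parameters
    ----------
    path
        File to read.
    format
        ``"delimited"`` (CSV) or ``"columnar"`` (Parquet); inferred from the
        file extension when omitted.
    column_map
        Optional mapping of external header names to the canonical
        snake_case metadata names, e.g. ``{"Metadata_Plate": "plate_id"}``.
    """
    fmt = _infer_format(path, format)
    if fmt == "delimited":
        df = pd.read_csv(path)
    elif fmt == "columnar":
        df = pd.read_parquet(path)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return _split_columns(df, column_map)


def write_profiles(table: ProfileTable, path, format: str | None = None) -> None:
    """Write a profile table; metadata columns first, then features."""
    table.validate()
    if table.n_wells == 0:
        raise IntegrityError("refusing to write an empty (0-well) table")
    fmt = _infer_format(path, format)
    meta_cols = [c for c in METADATA_COLUMNS if c in table.meta.columns]
    df = pd.concat([table.meta[meta_cols], table.features], axis=1)
    if fmt == "delimited":
        df.to_csv(path, index=False)
    elif fmt == "columnar":
        df.to_parquet(path, index=False)
    else:
        raise ValueError(f"unknown format {fmt!r}")


# -- aggregation and subsetting -------------------------------------------


def aggregate_cells_to_wells(cell_features: pd.DataFrame,
                             cell_meta: pd.DataFrame) -> ProfileTable:
    """Mean-average single-cell feature vectors into well-level profiles.

    Each well's profile is the arithmetic mean of the feature vectors of all
    cells assigned to that well ("pseudo-bulk" aggregation).

    Parameters
    ----------
    cell_features
        (n_cells, n_features) numeric frame.
    cell_meta
        One metadata record per cell (same columns as well metadata).
    """
    if cell_features.shape[0] != cell_meta.shape[0]:
        raise IntegrityError("cell features and metadata row counts differ")
    if cell_features.shape[0] == 0:
        raise IntegrityError("no cells to aggregate")
    missing = [c for c in REQUIRED_METADATA_COLUMNS if c not in cell_meta.columns]
    if missing:
        raise SchemaError(f"missing mandatory metadata column(s): {missing}")
    key_cols = list(REQUIRED_METADATA_COLUMNS[:4])
    joined = pd.concat(
        [cell_meta.reset_index(drop=True), cell_features.reset_index(drop=True)], axis=1
    )
    meta_cols = [c for c in METADATA_COLUMNS if c in cell_meta.columns]
    grouped = joined.groupby(key_cols, sort=False)
    feats = grouped[list(cell_features.columns)].mean().reset_index(drop=True)
    meta = grouped[meta_cols].first().reset_index(drop=True)
    return ProfileTable(feats, meta)


def subset(table: ProfileTable,
           predicate: Callable[[pd.DataFrame], Iterable[bool]] | pd.Series) -> ProfileTable:
    """Row-subset a table by a boolean predicate on its metadata.

    ``predicate`` is either a callable taking the metadata frame and
    returning a boolean mask, or a precomputed boolean Series/array.
    Feature values are untouched; an empty result is allowed but warned
    about, since no downstream stage can consume a zero-well table.
    """
    mask = predicate(table.meta) if callable(predicate) else predicate
    mask = np.asarray(mask, dtype=bool)
    if mask.shape[0] != table.n_wells:
        raise ValueError("predicate mask length does not match well count")
    if not mask.any():
        warnings.warn("subset selected no wells", stacklevel=2)
    return ProfileTable(
        table.features.loc[mask].reset_index(drop=True),
        table.meta.loc[mask].reset_index(drop=True),
    )
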