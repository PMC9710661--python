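"""Cell-level and subject-level data containers, validation, and I/O.

The package works on long-format cell tables: one row per segmented cell,
with a subject identifier, an optional cell-type label, and one or more
continuous marker-intensity columns.  Raw intensities are min-max scaled to
[0, 1] over the pooled cohort before any density work, so that every subject's
sample lives on a common support.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._errors import (
    DegenerateScaleError,
    EmptyInputError,
    SchemaError,
)

logger = logging.getLogger(__name__)

SUBJECT_COL = "subject_id"
CELL_TYPE_COL = "cell_type"
CELL_ID_COL = "cell_id"

#: subjects with fewer cells than this after filtering get a KDE-reliability warning
MIN_CELLS_WARN = 10


@dataclass
class CellTable:
    """Long-format table of cells: one row per cell, markers as columns.

    ``df`` always carries a string-typed ``subject_id`` column; ``markers``
    lists the intensity columns that passed validation.
    """

    df: pd.DataFrame
    markers: list[str]

    def __post_init__(self) -> None:
        if SUBJECT_COL not in self.df.columns:
            raise SchemaError(f"cell table lacks required column '{SUBJECT_COL}'")
        if not self.markers:
            raise SchemaError("cell table has no marker columns")
        missing = [m for m in self.markers if m not in self.df.columns]
        if missing:
            raise SchemaError(f"marker columns not in table: {missing}")

    @property
    def subject_ids(self) -> list[str]:
        return list(dict.fromkeys(self.df[SUBJECT_COL]))

    @property
    def n_subjects(self) -> int:
        return self.df[SUBJECT_COL].nunique()

    def cells_per_subject(self) -> pd.Series:
        return self.df.groupby(SUBJECT_COL, sort=False).size()

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class SubjectSamples:
    """Scaled intensities of one marker for one subject (values in [0, 1])."""

    subject_id: str
    marker: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size < 1:
            raise EmptyInputError(f"subject {self.subject_id}: no cells")
        if not np.all(np.isfinite(self.values)):
            raise SchemaError(f"subject {self.subject_id}: non-finite marker values")
        if self.values.min() < -1e-12 or self.values.max() > 1 + 1e-12:
            raise SchemaError(
                f"subject {self.subject_id}: scaled values outside [0, 1]"
            )

    @property
    def n_cells(self) -> int:
        return self.values.size


@dataclass
class OutcomeTable:
    """One row per subject: a continuous outcome, or (time, event), plus covariates."""

    df: pd.DataFrame
    kind: str  # "continuous" | "survival"
    outcome_col: str = "Y"
    time_col: str = "time"
    event_col: str = "event"
    covariate_cols: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if SUBJECT_COL not in self.df.columns:
            raise SchemaError(f"outcome table lacks '{SUBJECT_COL}'")
        if self.df[SUBJECT_COL].duplicated().any():
            raise SchemaError("outcome table must have one row per subject")
        if self.kind == "continuous":
            if self.outcome_col not in self.df.columns:
                raise SchemaError(f"missing outcome column '{self.outcome_col}'")
        elif self.kind == "survival":
            for c in (self.time_col, self.event_col):
                if c not in self.df.columns:
                    raise SchemaError(f"missing survival column '{c}'")
            if (self.df[self.time_col] < 0).any():
                raise SchemaError("negative survival times")
            if not self.df[self.event_col].isin([0, 1]).all():
                raise SchemaError("event indicator must be 0/1")
        else:
            raise SchemaError(f"unknown outcome kind '{self.kind}'")

    def aligned_to(self, subject_ids: list[str]) -> pd.DataFrame:
        """Return rows reordered to ``subject_ids``; error on unmatched ids."""
        idx = self.df.set_index(SUBJECT_COL)
        missing = [s for s in subject_ids if s not in idx.index]
        extra = [s for s in idx.index if s not in set(subject_ids)]
        if missing or extra:
            raise SchemaError(
                f"subject mismatch between outcomes and analysis set; "
                f"missing={missing[:5]}, unmatched={extra[:5]}"
            )
        return idx.loc[subject_ids].reset_index()


def read_cell_table(
    path: str | Path,
    subject_col: str = SUBJECT_COL,
    cell_type_col: str | None = None,
    cell_id_col: str | None = None,
    marker_cols: list[str] | None = None,
) -> CellTable:
    """Read a long-format cell CSV and validate it.

    Marker columns default to every numeric column that is not an identifier.
    Rows with a missing value in any marker column are dropped (count logged).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, float_precision="round_trip")
    if subject_col not in df.columns:
        raise SchemaError(
            f"'{subject_col}' column not found; available: {list(df.columns)}"
        )
    rename = {subject_col: SUBJECT_COL}
    if cell_type_col and cell_type_col != CELL_TYPE_COL:
        if cell_type_col not in df.columns:
            raise SchemaError(f"cell-type column '{cell_type_col}' not found")
        rename[cell_type_col] = CELL_TYPE_COL
    if cell_id_col and cell_id_col != CELL_ID_COL:
        if cell_id_col not in df.columns:
            raise SchemaError(f"cell-id column '{cell_id_col}' not found")
        rename[cell_id_col] = CELL_ID_COL
    df = df.rename(columns=rename)
    df[SUBJECT_COL] = df[SUBJECT_COL].astype(str)

    if marker_cols is None:
        reserved = {SUBJECT_COL, CELL_TYPE_COL, CELL_ID_COL}
        marker_cols = [
            c
            for c in df.columns
            if c not in reserved and pd.api.types.is_numeric_dtype(df[c])
        ]
    else:
        missing = [m for m in marker_cols if m not in df.columns]
        if missing:
            raise SchemaError(f"marker columns not found: {missing}")
    if not marker_cols:
        raise SchemaError("no numeric marker columns found")

    n0 = len(df)
    df = df.dropna(subset=marker_cols)
    dropped = n0 - len(df)
    if dropped:
        logger.info("dropped %d rows with missing marker values", dropped)
    if len(df) == 0:
        raise EmptyInputError("no usable cell rows after dropping missing values")
    bad = [m for m in marker_cols if not np.isfinite(df[m].to_numpy(float)).all()]
    if bad:
        raise SchemaError(f"non-finite intensities in markers: {bad}")
    return CellTable(df=df.reset_index(drop=True), markers=list(marker_cols))


def filter_cells(
    table: CellTable,
    cell_type: str | None = None,
    tissue_region: str | None = None,
    region_col: str = "tissue_region",
) -> CellTable:
    """Restrict to one cell-type compartment (and optionally a tissue region).

    Subjects left with zero cells are dropped with a warning; an unknown label
    raises listing the labels that do exist.
    """
    df = table.df
    for label, col in ((cell_type, CELL_TYPE_COL), (tissue_region, region_col)):
        if label is None:
            continue
        if col not in df.columns:
            raise SchemaError(f"filter on '{col}' requested but column absent")
        available = sorted(df[col].astype(str).unique())
        if label not in available:
            raise KeyError(f"label '{label}' not found in '{col}'; available: {available}")
        df = df[df[col].astype(str) == label]
    if len(df) == 0:
        raise EmptyInputError("no cells match the requested filter")
    lost = set(table.subject_ids) - set(df[SUBJECT_COL])
    if lost:
        warnings.warn(
            f"{len(lost)} subject(s) have no cells after filtering and were "
            f"dropped: {sorted(lost)[:5]}",
            stacklevel=2,
        )
    return CellTable(df=df.reset_index(drop=True), markers=table.markers)


def scale_marker(
    table: CellTable,
    marker: str,
    min_cells_warn: int = MIN_CELLS_WARN,
) -> dict[str, SubjectSamples]:
    """Min-max scale one marker over the POOLED cohort and split by subject.

    Scaling is x' = (x - min) / (max - min) with min/max taken over every cell
    of every subject, so between-subject differences in the intensity
    distribution are preserved.  A cohort-wide constant marker is an error.
    """
    if marker not in table.markers:
        raise SchemaError(f"marker '{marker}' not in table; available: {table.markers}")
    x = table.df[marker].to_numpy(dtype=float)
    lo, hi = x.min(), x.max()
    if hi - lo <= 0:
        raise DegenerateScaleError(f"marker '{marker}' is constant cohort-wide")
    scaled = (x - lo) / (hi - lo)
    out: dict[str, SubjectSamples] = {}
    groups = table.df.groupby(SUBJECT_COL, sort=False).indices
    for sid in table.subject_ids:
        vals = scaled[groups[sid]]
        if vals.size < min_cells_warn:
            warnings.warn(
                f"subject {sid}: only {vals.size} cells; KDE may be unreliable",
                stacklevel=2,
            )
        out[sid] = SubjectSamples(subject_id=sid, marker=marker, values=vals)
    return out


def read_outcome_table(
    path: str | Path,
    kind: str | None = None,
    subject_col: str = SUBJECT_COL,
    outcome_col: str = "Y",
    time_col: str = "time",
    event_col: str = "event",
    covariate_cols: list[str] | None = None,
) -> OutcomeTable:
    """Read a subject-level outcome CSV; ``kind`` is inferred from columns."""
    df = pd.read_csv(path)
    if subject_col not in df.columns:
        raise SchemaError(f"'{subject_col}' not found in outcome table")
    df = df.rename(columns={subject_col: SUBJECT_COL})
    df[SUBJECT_COL] = df[SUBJECT_COL].astype(str)
    if kind is None:
        if time_col in df.columns and event_col in df.columns:
            kind = "survival"
        elif outcome_col in df.columns:
            kind = "continuous"
        else:
            raise SchemaError(
                f"cannot infer outcome kind: need '{outcome_col}' or "
                f"('{time_col}', '{event_col}')"
            )
    if covariate_cols is None:
        used = {SUBJECT_COL, outcome_col, time_col, event_col}
        covariate_cols = [
            c for c in df.columns
            if c not in used and pd.api.types.is_numeric_dtype(df[c])
        ]
    return OutcomeTable(
        df=df,
        kind=kind,
        outcome_col=outcome_col,
        time_col=time_col,
        event_col=event_col,
        covariate_cols=covariate_cols,
    )


def write_cell_table(table: CellTable, path: str | Path) -> None:
    table.df.to_csv(path, index=False)


def write_square_matrix(
    values: np.ndarray, subject_ids: list[str], path: str | Path
) -> None:
    """Square CSV with subject ids as both header and index."""
    pd.DataFrame(values, index=subject_ids, columns=subject_ids).to_csv(path)


def read_square_matrix(path: str | Path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    ids = [str(c) for c in df.columns]
    if [str(i) for i in df.index] != ids:
        raise SchemaError("square matrix CSV must have identical header and index")
    return df.to_numpy(dtype=float), ids


def write_results_json(records: list[dict], path: str | Path) -> None:
    Path(path).write_text(json.dumps(records, indent=2, default=float) + "\n")
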