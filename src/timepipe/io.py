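"""Readers, writers, and validation for cell and patient tables.

A *cell table* is a pandas DataFrame with one row per segmented cell:

======================  =======================================================
column                  meaning
======================  =======================================================
cell_id                 unique string id
fov_id                  field-of-view id (spatial operations never cross FOVs)
x, y                    centroid in pixels, 0-based, FOV-local, >= 0
phenotype               one of ``scheme.ALL_CLASSES`` or ``Unassigned``
<marker>_mean           per-cell mean intensity, 16-bit scale [0, 65535]
<marker>_sd             per-cell intensity standard deviation, >= 0
<marker>_pos            optional boolean functional flag (e.g. PD1 gating)
patient_id/outcome/...  added by :func:`join_patient_metadata`
======================  =======================================================

A *patient table* has columns patient_id, specimen_id, outcome. Files are
comma-separated UTF-8 with '.' decimals.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from . import scheme
from .errors import ReferentialError, SchemaError, ValidationError

REQUIRED_CELL_COLUMNS = ("cell_id", "fov_id", "x", "y")
REQUIRED_PATIENT_COLUMNS = ("patient_id", "specimen_id", "outcome")

#: canonical leading column order on write
_LEAD_COLUMNS = (
    "cell_id",
    "fov_id",
    "patient_id",
    "specimen_id",
    "outcome",
    "x",
    "y",
    "phenotype",
)


def marker_names(cells: pd.DataFrame) -> list[str]:
    """Markers present in a cell table, from the ``<marker>_mean`` columns."""
    return [c[: -len("_mean")] for c in cells.columns if c.endswith("_mean")]


def gated_markers(cells: pd.DataFrame) -> list[str]:
    """Markers that carry a functional-positivity flag column."""
    return [c[: -len("_pos")] for c in cells.columns if c.endswith("_pos")]


def validate_cell_table(cells: pd.DataFrame, fov_size: float | None = None) -> None:
    """Check the cell-table contract; raise with row-indexed diagnostics.

    ``fov_size`` (pixels) additionally bounds coordinates from above.
    """
    missing = [c for c in REQUIRED_CELL_COLUMNS if c not in cells.columns]
    if missing:
        raise SchemaError(f"cell table missing required columns: {missing}")
    if cells.empty:
        return
    for col in ("x", "y"):
        vals = pd.to_numeric(cells[col], errors="coerce")
        bad = list(cells.index[vals.isna()])
        if bad:
            raise ValidationError(f"non-numeric {col!r} at rows {bad[:10]}", rows=bad)
    bad = list(cells.index[(cells["x"] < 0) | (cells["y"] < 0)])
    if bad:
        raise ValidationError(f"negative coordinates at rows {bad[:10]}", rows=bad)
    if fov_size is not None:
        bad = list(cells.index[(cells["x"] >= fov_size) | (cells["y"] >= fov_size)])
        if bad:
            raise ValidationError(
                f"coordinates outside {fov_size}px FOV at rows {bad[:10]}", rows=bad
            )
    if cells["cell_id"].duplicated().any():
        bad = list(cells.index[cells["cell_id"].duplicated(keep=False)])
        raise ValidationError(f"duplicate cell_id at rows {bad[:10]}", rows=bad)
    for m in marker_names(cells):
        mean = cells[f"{m}_mean"]
        bad = list(cells.index[(mean < 0) | (mean > 65535)])
        if bad:
            raise ValidationError(
                f"{m}_mean outside [0, 65535] at rows {bad[:10]}", rows=bad
            )
        sd_col = f"{m}_sd"
        if sd_col in cells.columns:
            bad = list(cells.index[cells[sd_col] < 0])
            if bad:
                raise ValidationError(f"{m}_sd negative at rows {bad[:10]}", rows=bad)


def read_cell_table(path: str | os.PathLike, fov_size: float | None = None) -> pd.DataFrame:
    """Read and validate a CSV cell table.

    Unknown phenotype strings are coerced to ``Unassigned``; a missing
    phenotype column is added as all-``Unassigned``.
    """
    cells = pd.read_csv(path, dtype={"cell_id": str, "fov_id": str})
    missing = [c for c in REQUIRED_CELL_COLUMNS if c not in cells.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    for col in ("x", "y"):
        vals = pd.to_numeric(cells[col], errors="coerce")
        bad = list(cells.index[vals.isna()])
        if bad:
            raise ValidationError(
                f"{path}: non-numeric {col!r} at rows {bad[:10]}", rows=bad
            )
        cells[col] = vals.astype(float)
    if "phenotype" in cells.columns:
        cells["phenotype"] = cells["phenotype"].astype(str).map(scheme.coerce_phenotype)
    else:
        cells["phenotype"] = scheme.UNASSIGNED
    for col in cells.columns:
        if col.endswith("_pos"):
            cells[col] = cells[col].astype(bool)
    validate_cell_table(cells, fov_size=fov_size)
    return cells


def _canonical_columns(cells: pd.DataFrame) -> list[str]:
    lead = [c for c in _LEAD_COLUMNS if c in cells.columns]
    rest = sorted(c for c in cells.columns if c not in lead)
    return lead + rest


def write_cell_table(cells: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a cell table as CSV with deterministic column order.

    Round-trips bit-for-bit for string/integer/boolean fields and to full
    repr precision for floats.
    """
    validate_cell_table(cells)
    cells.loc[:, _canonical_columns(cells)].to_csv(path, index=False)


def read_patient_table(path: str | os.PathLike) -> pd.DataFrame:
    patients = pd.read_csv(path, dtype=str)
    missing = [c for c in REQUIRED_PATIENT_COLUMNS if c not in patients.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    return patients


def write_patient_table(patients: pd.DataFrame, path: str | os.PathLike) -> None:
    cols = [c for c in REQUIRED_PATIENT_COLUMNS if c in patients.columns]
    cols += sorted(c for c in patients.columns if c not in cols)
    patients.loc[:, cols].to_csv(path, index=False)


def join_patient_metadata(cells: pd.DataFrame, patients: pd.DataFrame) -> pd.DataFrame:
    """Attach specimen and outcome labels to every cell.

    Cells must already carry ``patient_id`` (the generator emits it; external
    tables may map FOV to patient upstream). Row count is unchanged.
    """
    if "patient_id" not in cells.columns:
        raise SchemaError("cell table has no patient_id column to join on")
    missing = [c for c in REQUIRED_PATIENT_COLUMNS if c not in patients.columns]
    if missing:
        raise SchemaError(f"patient table missing columns {missing}")
    known = set(patients["patient_id"])
    orphans = sorted(set(cells["patient_id"]) - known)
    if orphans:
        raise ReferentialError(f"patient_id not in patient table: {orphans}")
    joined = cells.drop(columns=["specimen_id", "outcome"], errors="ignore").merge(
        patients[list(REQUIRED_PATIENT_COLUMNS)], on="patient_id", how="left"
    )
    joined.index = cells.index
    assert len(joined) == len(cells)
    return joined


def ensure_patient_context(cells: pd.DataFrame, patients: pd.DataFrame | None) -> pd.DataFrame:
    """Return cells with outcome labels, joining if not already present."""
    if "outcome" in cells.columns:
        return cells
    if patients is None:
        raise SchemaError("cells lack outcome labels and no patient table was given")
    return join_patient_metadata(cells, patients)


def arcsinh_means(cells: pd.DataFrame, markers: list[str]) -> np.ndarray:
    """arcsinh-transformed marker-mean feature matrix (cofactor 1)."""
    cols = [f"{m}_mean" for m in markers]
    missing = [c for c in cols if c not in cells.columns]
    if missing:
        raise SchemaError(f"cell table missing marker columns {missing}")
    return np.arcsinh(cells[cols].to_numpy(dtype=float))
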