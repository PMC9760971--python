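"""Index-cell-centric cellular neighborhoods at paracrine scale.

A neighborhood is the closed disc of a fixed diameter (default 57 px,
radius 28.5 px) around every index cell of a chosen class — tumor-centric
(TCCN) or cytotoxic-T-centric (CTCN). For each index cell the per-class
neighbor counts and per-gated-marker positive-neighbor counts are tallied;
the index cell itself is never counted. Neighborhoods never cross FOV
boundaries and are truncated (no edge correction) at FOV borders, which is
flagged per row.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from . import io, scheme
from .errors import ParameterError, SchemaError

_META_COLS = ("cell_id", "fov_id", "x", "y", "border")


def count_columns(classes: tuple[str, ...] = scheme.ALL_CLASSES) -> list[str]:
    return [f"n_{c}" for c in classes]


@dataclass
class NeighborhoodMatrix:
    """Per-index-cell neighbor counts within a fixed-diameter disc."""

    index_class: str
    diameter: float
    data: pd.DataFrame  # cell_id, fov_id, x, y, border, n_<class>..., pos_<marker>_<class>...

    @property
    def radius(self) -> float:
        return self.diameter / 2.0

    def immune_counts(self) -> pd.DataFrame:
        return self.data[[f"n_{c}" for c in scheme.IMMUNE_CLASSES]]

    def total_neighbors(self) -> pd.Series:
        cols = [c for c in self.data.columns if c.startswith("n_")]
        return self.data[cols].sum(axis=1)


def build_neighborhoods(
    cells: pd.DataFrame,
    index_class: str,
    diameter: float = scheme.DEFAULT_NEIGHBORHOOD_DIAMETER,
    fov_size: float = scheme.DEFAULT_FOV_SIZE,
) -> NeighborhoodMatrix:
    """Count neighbors of every class around each index cell.

    A cell is a neighbor iff its Euclidean distance from the index centroid
    is <= diameter/2 (inclusive boundary). Functional-positive neighbors are
    counted per gated marker and per immune class (columns
    ``pos_<marker>_<class>`` plus a ``pos_<marker>`` total).
    """
    if diameter <= 0:
        raise ParameterError("diameter must be positive")
    if index_class not in scheme.ALL_CLASSES:
        raise ParameterError(f"unknown index class {index_class!r}")
    radius = diameter / 2.0
    classes = list(scheme.ALL_CLASSES)
    if (cells["phenotype"] == scheme.UNASSIGNED).any():
        classes.append(scheme.UNASSIGNED)
    code_of = {c: i for i, c in enumerate(classes)}
    markers = io.gated_markers(cells)

    rows: list[pd.DataFrame] = []
    for fov_id, fov in cells.groupby("fov_id", sort=True):
        fov = fov.sort_values("cell_id", kind="mergesort")
        is_index = (fov["phenotype"] == index_class).to_numpy()
        if not is_index.any():
            continue
        xy = fov[["x", "y"]].to_numpy(dtype=float)
        codes = fov["phenotype"].map(code_of).to_numpy()
        tree = cKDTree(xy)
        idx_pos = np.flatnonzero(is_index)
        neigh_lists = tree.query_ball_point(xy[idx_pos], radius)
        n_idx = len(idx_pos)
        lengths = np.fromiter((len(l) for l in neigh_lists), int, count=n_idx)
        flat = np.fromiter(
            (j for l in neigh_lists for j in l), int, count=int(lengths.sum())
        )
        row_of = np.repeat(np.arange(n_idx), lengths)
        keep = flat != idx_pos[row_of]  # exclude the index cell itself
        flat, row_of = flat[keep], row_of[keep]

        counts = np.zeros((n_idx, len(classes)), dtype=np.int64)
        np.add.at(counts, (row_of, codes[flat]), 1)
        frame = pd.DataFrame(counts, columns=[f"n_{c}" for c in classes])
        frame.insert(0, "cell_id", fov["cell_id"].to_numpy()[idx_pos])
        frame.insert(1, "fov_id", fov_id)
        frame.insert(2, "x", xy[idx_pos, 0])
        frame.insert(3, "y", xy[idx_pos, 1])
        edge_dist = np.minimum.reduce(
            [xy[idx_pos, 0], xy[idx_pos, 1], fov_size - xy[idx_pos, 0], fov_size - xy[idx_pos, 1]]
        )
        frame.insert(4, "border", edge_dist < radius)
        for m in markers:
            pos = fov[f"{m}_pos"].to_numpy(dtype=bool)
            pflat = flat[pos[flat]]
            prow = row_of[pos[flat]]
            pc = np.zeros((n_idx, len(classes)), dtype=np.int64)
            np.add.at(pc, (prow, codes[pflat]), 1)
            frame[f"pos_{m}"] = pc.sum(axis=1)
            for c in scheme.IMMUNE_CLASSES:
                frame[f"pos_{m}_{c}"] = pc[:, code_of[c]]
        rows.append(frame)

    if rows:
        data = pd.concat(rows, ignore_index=True)
    else:
        data = pd.DataFrame(columns=[*_META_COLS, *(f"n_{c}" for c in classes)])
    return NeighborhoodMatrix(index_class=index_class, diameter=diameter, data=data)


def filter_populated(
    matrix: NeighborhoodMatrix, require_class_group: str
) -> NeighborhoodMatrix:
    """Keep neighborhoods containing >= 1 immune (TCCN) or tumor (CTCN) cell."""
    if require_class_group == scheme.IMMUNE:
        cols = [f"n_{c}" for c in scheme.IMMUNE_CLASSES]
    elif require_class_group == scheme.TUMOR:
        cols = [f"n_{scheme.TUMOR}"]
    else:
        raise ParameterError(
            f"require_class_group must be 'Immune' or 'Tumor', got {require_class_group!r}"
        )
    present = [c for c in cols if c in matrix.data.columns]
    if not present or matrix.data.empty:
        return NeighborhoodMatrix(matrix.index_class, matrix.diameter, matrix.data.iloc[0:0])
    keep = matrix.data[present].sum(axis=1) >= 1
    return NeighborhoodMatrix(
        matrix.index_class, matrix.diameter, matrix.data[keep].reset_index(drop=True)
    )


def _attach_patient(matrix: NeighborhoodMatrix, cells: pd.DataFrame) -> pd.DataFrame:
    cols = ["cell_id", "patient_id"] + (["outcome"] if "outcome" in cells.columns else [])
    if "patient_id" not in cells.columns:
        raise SchemaError("cells lack patient_id; join patient metadata first")
    return matrix.data.merge(cells[cols], on="cell_id", how="left")


def neighborhood_composition_by_patient(
    matrix: NeighborhoodMatrix, cells: pd.DataFrame
) -> pd.DataFrame:
    """Per patient: fraction of neighborhoods containing >= 1 cell of each immune class.

    The denominator is the patient's neighborhood count in (the possibly
    filtered) ``matrix``. Patients with zero neighborhoods are excluded with
    a warning.
    """
    data = _attach_patient(matrix, cells)
    if data.empty:
        return pd.DataFrame(columns=list(scheme.IMMUNE_CLASSES)).rename_axis("patient_id")
    dropped = set(cells["patient_id"].unique()) - set(data["patient_id"].unique())
    if dropped:
        warnings.warn(f"patients with zero neighborhoods excluded: {sorted(dropped)}")
    present = {
        c: (data[f"n_{c}"] >= 1).groupby(data["patient_id"]).mean()
        for c in scheme.IMMUNE_CLASSES
    }
    return pd.DataFrame(present).rename_axis("patient_id")


def tumor_count_distribution(
    matrix: NeighborhoodMatrix, cells: pd.DataFrame
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-group histogram and mean of tumor-neighbor counts per neighborhood.

    Returns (histogram table indexed by tumor count with one column per
    group, mean tumor count per group).
    """
    data = _attach_patient(matrix, cells)
    if "outcome" not in data.columns:
        raise SchemaError("cells lack outcome labels; join patient metadata first")
    counts = data[f"n_{scheme.TUMOR}"]
    hist = pd.crosstab(counts, data["outcome"])
    hist.index.name = "tumor_count"
    means = counts.groupby(data["outcome"]).mean()
    return hist, means
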