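"""Homotypic/heterotypic categorization and pairing of neighborhoods.

Every neighborhood is placed in exactly one category by the distinct immune
classes present among its neighbors (the index cell itself never counts):

* **TumorOnly** — zero immune neighbors (tumor/stroma neighbors only, or none);
* **Homotypic(class)** — exactly one distinct immune class present;
* **Heterotypic(classes)** — two or more distinct immune classes present.

Heterotypic neighborhoods are summarized by presence (>= 1 cell of a class),
not abundance; a neighborhood with m distinct immune classes contributes to
all C(m, 2) unordered pairs.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd

from . import scheme
from .errors import DependencyError, SchemaError
from .neighborhoods import NeighborhoodMatrix, _attach_patient

TUMOR_ONLY = "TumorOnly"
HOMOTYPIC = "Homotypic"
HETEROTYPIC = "Heterotypic"


def categorize_neighborhoods(matrix: NeighborhoodMatrix) -> pd.DataFrame:
    """Exhaustive, mutually exclusive categorization of each neighborhood.

    Returns a DataFrame with cell_id, fov_id, category, homotypic_class
    (NA unless homotypic), and immune_classes_present ('|'-joined, sorted).
    """
    data = matrix.data
    imm_cols = [f"n_{c}" for c in scheme.IMMUNE_CLASSES if f"n_{c}" in data.columns]
    present = data[imm_cols].to_numpy() >= 1 if len(data) else np.zeros((0, len(imm_cols)), bool)
    n_classes = present.sum(axis=1)
    cls_names = np.array([c[2:] for c in imm_cols])
    category = np.where(
        n_classes == 0, TUMOR_ONLY, np.where(n_classes == 1, HOMOTYPIC, HETEROTYPIC)
    )
    homotypic_class = [
        cls_names[row][0] if k == 1 else None for row, k in zip(present, n_classes)
    ]
    present_str = ["|".join(cls_names[row]) for row in present]
    return pd.DataFrame(
        {
            "cell_id": data["cell_id"] if len(data) else pd.Series(dtype=object),
            "fov_id": data["fov_id"] if len(data) else pd.Series(dtype=object),
            "category": category,
            "homotypic_class": homotypic_class,
            "immune_classes_present": present_str,
        }
    )


def _explode_features(categories: pd.DataFrame) -> pd.DataFrame:
    """One row per (neighborhood, feature): category features and pair features."""
    rows = []
    for _, r in categories.iterrows():
        if r["category"] == TUMOR_ONLY:
            rows.append((r["cell_id"], "tumor_only"))
        elif r["category"] == HOMOTYPIC:
            rows.append((r["cell_id"], f"homotypic:{r['homotypic_class']}"))
        else:
            classes = r["immune_classes_present"].split("|")
            rows.append((r["cell_id"], "heterotypic"))
            for a, b in combinations(sorted(classes), 2):
                rows.append((r["cell_id"], f"pair:{a}+{b}"))
    return pd.DataFrame(rows, columns=["cell_id", "feature"])


def pairing_frequencies(
    categories: pd.DataFrame, cells: pd.DataFrame, by: str = "outcome"
) -> pd.DataFrame:
    """Frequencies of tumor-only / homotypic / heterotypic-pair features.

    ``by`` is 'outcome' (per group) or 'patient_id' (per patient). Each
    frequency is normalized by the total number of neighborhoods of the
    index type in that group/patient, so a heterotypic neighborhood with m
    classes contributes to C(m, 2) pair features but counts once in each
    denominator.

    Returns a tidy table (group, feature, events, total, frequency).
    """
    if by not in ("outcome", "patient_id"):
        raise SchemaError("by must be 'outcome' or 'patient_id'")
    meta_cols = ["cell_id", "patient_id"] + (
        ["outcome"] if "outcome" in cells.columns else []
    )
    if by not in meta_cols and by != "patient_id":
        raise SchemaError("cells lack outcome labels; join patient metadata first")
    meta = cells[meta_cols]
    cats = categories.merge(meta, on="cell_id", how="left")
    totals = cats.groupby(by).size()
    feats = _explode_features(categories).merge(cats[["cell_id", by]], on="cell_id")
    counts = feats.groupby([by, "feature"]).size()
    # complete grid: every observed feature for every group/patient, zeros kept
    grid = pd.MultiIndex.from_product(
        [totals.index, sorted(feats["feature"].unique())], names=[by, "feature"]
    )
    events = counts.reindex(grid, fill_value=0).rename("events").reset_index()
    events["total"] = events[by].map(totals)
    events["frequency"] = events["events"] / events["total"]
    return events.rename(columns={by: "group"})


def pd1_neighbor_frequencies(
    matrix: NeighborhoodMatrix, cells: pd.DataFrame, marker: str = "PD1"
) -> pd.DataFrame:
    """Per patient: fraction of neighborhoods with >= 1 functional-positive
    neighbor of each TIL class, plus a per-neighborhood flag for map export.

    Returns a per-patient table (columns = TIL classes) with the flags
    available as attribute ``.attrs['flags']`` (cell_id, has_positive).
    """
    pos_cols = {c: f"pos_{marker}_{c}" for c in scheme.TIL_CLASSES}
    missing = [c for c in pos_cols.values() if c not in matrix.data.columns]
    if missing:
        raise DependencyError(
            f"{marker} has not been gated; run gate_functional_marker first "
            f"(missing columns {missing})"
        )
    data = _attach_patient(matrix, cells)
    fractions = pd.DataFrame(
        {
            c: (data[col] >= 1).groupby(data["patient_id"]).mean()
            for c, col in pos_cols.items()
        }
    ).rename_axis("patient_id")
    flags = pd.DataFrame(
        {
            "cell_id": data["cell_id"],
            "has_positive": data[list(pos_cols.values())].sum(axis=1) >= 1,
        }
    )
    fractions.attrs["flags"] = flags
    return fractions
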