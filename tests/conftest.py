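"""Shared fixtures and brute-force spatial oracles."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import cdist

from timepipe import scheme, synth


@pytest.fixture(scope="session")
def small_spec() -> synth.CohortSpec:
    """A compact two-group cohort: 3+3 patients, 2 FOVs each, ~750 cells/FOV."""
    return synth.CohortSpec(
        n_patients_per_group=(3, 3),
        fovs_per_patient=2,
        tumor_nest_process=synth.NestProcess(parents_per_fov=15, mean_offspring=30),
        seed=42,
    )


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    """(cells joined to patients, patients, ground truth) for the small spec."""
    from timepipe import generate_cohort, join_patient_metadata

    cells, patients, truth = generate_cohort(small_spec)
    return join_patient_metadata(cells, patients), patients, truth


def random_cells(
    rng: np.random.Generator,
    n: int,
    fov_size: float = scheme.DEFAULT_FOV_SIZE,
    classes: tuple[str, ...] = scheme.ALL_CLASSES,
    fov_id: str = "F1",
) -> pd.DataFrame:
    """Uniform random cells with random phenotypes in a single FOV."""
    xy = rng.uniform(0.0, fov_size, size=(n, 2))
    return pd.DataFrame(
        {
            "cell_id": [f"{fov_id}-C{i:05d}" for i in range(n)],
            "fov_id": fov_id,
            "x": xy[:, 0],
            "y": xy[:, 1],
            "phenotype": rng.choice(classes, size=n),
        }
    )


def brute_knn_composition(cells: pd.DataFrame, k: int) -> pd.DataFrame:
    """O(n^2) oracle for k-NN composition within each FOV.

    Full pairwise distance matrix; each row lexsorted on (distance, cell_id)
    so ties at the k-th distance break by lowest cell_id.
    """
    class_cols = list(scheme.ALL_CLASSES)
    if (cells["phenotype"] == scheme.UNASSIGNED).any():
        class_cols.append(scheme.UNASSIGNED)
    frames = []
    for _, fov in cells.groupby("fov_id", sort=True):
        if len(fov) <= k:
            continue
        fov = fov.sort_values("cell_id", kind="mergesort")
        n = len(fov)
        xy = fov[["x", "y"]].to_numpy(dtype=float)
        ids = fov["cell_id"].to_numpy()
        codes = fov["phenotype"].map({c: i for i, c in enumerate(class_cols)}).to_numpy()
        id_rank = np.arange(n)  # rows pre-sorted by cell_id
        d = cdist(xy, xy)
        counts = np.zeros((n, len(class_cols)), dtype=np.int64)
        for i in range(n):
            order = np.lexsort((id_rank, d[i]))
            order = order[order != i][:k]
            counts[i] = np.bincount(codes[order], minlength=len(class_cols))
        frames.append(
            pd.DataFrame(counts / k, columns=class_cols, index=pd.Index(ids, name="cell_id"))
        )
    return pd.concat(frames) if frames else pd.DataFrame(columns=class_cols)


def brute_neighborhood_counts(
    cells: pd.DataFrame, index_class: str, diameter: float
) -> pd.DataFrame:
    """O(n^2) oracle for per-class counts in a closed disc of radius diameter/2."""
    radius = diameter / 2.0
    class_cols = list(scheme.ALL_CLASSES)
    if (cells["phenotype"] == scheme.UNASSIGNED).any():
        class_cols.append(scheme.UNASSIGNED)
    frames = []
    for _, fov in cells.groupby("fov_id", sort=True):
        xy = fov[["x", "y"]].to_numpy(dtype=float)
        ids = fov["cell_id"].to_numpy()
        phen = fov["phenotype"].to_numpy()
        codes = fov["phenotype"].map({c: i for i, c in enumerate(class_cols)}).to_numpy()
        d = cdist(xy, xy)
        idx = np.flatnonzero(phen == index_class)
        counts = np.zeros((len(idx), len(class_cols)), dtype=np.int64)
        for r, i in enumerate(idx):
            inside = np.flatnonzero(d[i] <= radius)
            inside = inside[inside != i]
            counts[r] = np.bincount(codes[inside], minlength=len(class_cols))
        frames.append(
            pd.DataFrame(counts, columns=class_cols, index=pd.Index(ids[idx], name="cell_id"))
        )
    out = pd.concat(frames) if frames else pd.DataFrame(columns=class_cols)
    return out
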