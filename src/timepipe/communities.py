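"""Cellular communities: k-NN composition vectors clustered into regional niches.

Each cell is described by the phenotype composition of its k nearest
neighbors (within its own FOV, excluding itself). Composition vectors are
pooled across the whole cohort and clustered with mini-batch k-means into c
community clusters; each cluster is labelled by its enriched (>10%)
phenotype classes and summarized as per-patient frequencies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import entropy
from sklearn.cluster import MiniBatchKMeans

from . import scheme
from .errors import ParameterError

DEFAULT_LABEL_THRESHOLD = 0.10


def _composition_columns(cells: pd.DataFrame) -> list[str]:
    cols = list(scheme.ALL_CLASSES)
    if (cells["phenotype"] == scheme.UNASSIGNED).any():
        cols.append(scheme.UNASSIGNED)
    return cols


def knn_composition(cells: pd.DataFrame, k: int = scheme.DEFAULT_COMMUNITY_K) -> pd.DataFrame:
    """Per-cell k-nearest-neighbor phenotype composition.

    Returns a DataFrame indexed by cell_id with one fraction column per
    phenotype class (rows sum to 1) plus ``fov_id``. Neighbors are searched
    within the cell's FOV only; FOVs with <= k cells are skipped with a
    warning. Distance ties at the k-th neighbor are broken by lowest cell_id.
    """
    if k <= 0:
        raise ParameterError("k must be positive")
    class_cols = _composition_columns(cells)
    code_of = {c: i for i, c in enumerate(class_cols)}
    frames = []
    for fov_id, fov in cells.groupby("fov_id", sort=True):
        n = len(fov)
        if n <= k:
            warnings.warn(
                f"FOV {fov_id!r} has {n} <= k={k} cells; skipped", stacklevel=2
            )
            continue
        fov = fov.sort_values("cell_id", kind="mergesort")
        xy = fov[["x", "y"]].to_numpy(dtype=float)
        codes = fov["phenotype"].map(code_of).to_numpy()
        ids = fov["cell_id"].to_numpy()
        tree = cKDTree(xy)
        q = min(k + 2, n)
        dists, idxs = tree.query(xy, k=q)
        counts = np.zeros((n, len(class_cols)), dtype=np.int64)
        for i in range(n):
            cand = [
                (dists[i, j], ids[idxs[i, j]], idxs[i, j])
                for j in range(q)
                if idxs[i, j] != i
            ]
            cand.sort(key=lambda t: (t[0], t[1]))
            for _, _, j in cand[:k]:
                counts[i, codes[j]] += 1
        frac = counts / float(k)
        frame = pd.DataFrame(frac, columns=class_cols, index=pd.Index(ids, name="cell_id"))
        frame.insert(0, "fov_id", fov_id)
        frames.append(frame)
    if not frames:
        return pd.DataFrame(columns=["fov_id", *class_cols]).rename_axis("cell_id")
    return pd.concat(frames)


@dataclass
class CommunityModel:
    """Fitted community clustering over composition vectors."""

    c: int
    k: int
    centroids: np.ndarray
    assignments: pd.Series  # cell_id -> cluster index
    cluster_profiles: pd.DataFrame  # cluster x class mean composition
    cluster_labels: dict[int, list[str]] = field(default_factory=dict)
    seed: int = 0
    inertia: float = 0.0


def fit_communities(
    vectors: pd.DataFrame,
    c: int = scheme.DEFAULT_COMMUNITY_C,
    seed: int = 0,
    k: int | None = None,
    batch_size: int = 1024,
    max_iter: int = 100,
) -> CommunityModel:
    """Mini-batch k-means over composition vectors pooled across patients.

    Input rows are canonically sorted by cell_id before fitting, so the
    result is invariant to input order given the same seed.
    """
    class_cols = [col for col in vectors.columns if col != "fov_id"]
    vectors = vectors.sort_index(kind="mergesort")
    X = vectors[class_cols].to_numpy(dtype=float)
    if c > len(X):
        raise ParameterError(f"c={c} exceeds {len(X)} composition vectors")
    km = MiniBatchKMeans(
        n_clusters=c,
        random_state=seed,
        batch_size=batch_size,
        max_iter=max_iter,
        n_init=3,
    )
    labels = km.fit_predict(X)
    assignments = pd.Series(labels, index=vectors.index, name="cluster")
    profiles = (
        pd.DataFrame(X, columns=class_cols, index=vectors.index)
        .groupby(assignments)
        .mean()
        .reindex(range(c), fill_value=0.0)
    )
    # full-data inertia (MiniBatchKMeans.inertia_ reflects the last batch);
    # labels are argmin against the final centers, so this is the objective
    inertia = float(np.sum((X - km.cluster_centers_[labels]) ** 2))
    model = CommunityModel(
        c=c,
        k=k if k is not None else -1,
        centroids=km.cluster_centers_,
        assignments=assignments,
        cluster_profiles=profiles,
        seed=seed,
        inertia=inertia,
    )
    return label_communities(model)


def label_communities(
    model: CommunityModel, threshold: float = DEFAULT_LABEL_THRESHOLD
) -> CommunityModel:
    """Label each cluster by its enriched classes (profile fraction > threshold).

    Labels are ordered by descending fraction.
    """
    labels: dict[int, list[str]] = {}
    for cluster, row in model.cluster_profiles.iterrows():
        enriched = row[row > threshold].sort_values(ascending=False)
        labels[int(cluster)] = list(enriched.index)
    model.cluster_labels = labels
    return model


def community_frequencies(model: CommunityModel, cells: pd.DataFrame) -> pd.DataFrame:
    """Per-patient community-cluster frequency matrix (rows sum to 1).

    Patients with zero assigned cells are excluded with a warning.
    """
    joined = cells.set_index("cell_id").join(model.assignments, how="inner")
    if "patient_id" not in joined.columns:
        raise ParameterError("cells must carry patient_id; join patient metadata first")
    dropped = set(cells["patient_id"].unique()) - set(joined["patient_id"].unique())
    if dropped:
        warnings.warn(f"patients with no assigned cells excluded: {sorted(dropped)}")
    freq = pd.crosstab(joined["patient_id"], joined["cluster"], normalize="index")
    return freq.reindex(columns=range(model.c), fill_value=0.0)


def sweep_parameters(
    cells: pd.DataFrame, k_grid: list[int], c_grid: list[int], seed: int = 0
) -> pd.DataFrame:
    """Fit one model per (k, c) grid point with summary diagnostics.

    Returns a table of (k, c, inertia, cluster-size entropy) supporting the
    manual choice of community parameters.
    """
    if not k_grid or not c_grid:
        raise ParameterError("k_grid and c_grid must be nonempty")
    rows = []
    for k in k_grid:
        vectors = knn_composition(cells, k=k)
        for c in c_grid:
            model = fit_communities(vectors, c=c, seed=seed, k=k)
            sizes = model.assignments.value_counts().to_numpy(dtype=float)
            rows.append(
                {
                    "k": k,
                    "c": c,
                    "inertia": model.inertia,
                    "cluster_size_entropy": float(entropy(sizes / sizes.sum())),
                }
            )
    return pd.DataFrame(rows)
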