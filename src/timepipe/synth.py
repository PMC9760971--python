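"""Synthetic tumor-core tissue generator.

Emulates the statistical structure of pathologist-annotated tumor-core FOVs
from multiplexed immunofluorescence of metastatic lymph nodes:

* tumor cells laid down by a Thomas (parent-offspring) cluster process,
  producing the nested, tumor-dominant macro-architecture of a tumor core;
* stromal and immune cells placed by thinning a uniform proposal, with
  acceptance weight ``1 + sum (multiplier - 1)`` over nearby cells of
  attracting classes — planting cohort-specific paracrine enrichments that
  the neighborhood analysis should recover (multiplier 1 is neutral,
  >1 attractive, <1 repulsive);
* marker intensities drawn from two-component Gaussian mixtures on the
  arcsinh scale and mapped back to the 16-bit range via sinh, so that the
  gating transform exactly linearizes the planted mixture;
* a per-specimen location shift on gated markers, emulating batch effects
  that the per-specimen peak alignment must remove.

Ground truth (true class, true functional positivity, planted enrichments)
is returned alongside the tables so recovery can be scored.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from . import scheme
from .errors import DegenerateSpecError, ParameterError

# -- spec dataclasses ---------------------------------------------------------


@dataclass(frozen=True)
class NestProcess:
    """Thomas-process parameters for tumor nests (per FOV)."""

    parents_per_fov: float = 30.0
    mean_offspring: float = 70.0
    dispersion: float = 60.0  # offspring sd around parent, px


@dataclass(frozen=True)
class MarkerMixture:
    """Two-component marker model on the arcsinh scale (gated markers).

    The sd channel shares the component structure with means scaled by
    ``sd_channel_scale``, so positives stand out on both gating axes.
    ``positive_classes``/``positive_groups`` restrict which cells can be
    positive (None = no restriction).
    """

    negative_mean: float = 5.0
    negative_sd: float = 0.5
    positive_mean: float = 9.0
    positive_sd: float = 0.5
    positive_fraction: float = 0.15
    positive_classes: tuple[str, ...] | None = scheme.TIL_CLASSES
    positive_groups: tuple[str, ...] | None = None
    sd_channel_scale: float = 0.6


@dataclass(frozen=True)
class LineageMarker:
    """Unimodal lineage marker: high in ``high_classes``, low elsewhere."""

    high_classes: tuple[str, ...]
    high_mean: float = 8.5
    low_mean: float = 4.5
    sd: float = 0.6


#: Class mix of a tumor core: tumor-dominant with a minority immune infiltrate.
DEFAULT_CLASS_PROPORTIONS: dict[str, float] = {
    "Tumor": 0.60,
    "Stroma": 0.10,
    "Macrophage": 0.07,
    "CytotoxicT": 0.05,
    "HelperT": 0.05,
    "BCell": 0.04,
    "Dendritic": 0.03,
    "Treg": 0.02,
    "UnclassifiedImmune": 0.015,
    "Monocyte": 0.015,
    "Neutrophil": 0.01,
}


def default_lineage_panel(separation_sd: float = 6.7) -> dict[str, LineageMarker]:
    """A compact, realistic lineage panel separating the 11 classes.

    ``separation_sd`` sets (high_mean - low_mean) / sd.
    """
    sd = 0.6
    hi, lo = 4.5 + separation_sd * sd, 4.5
    mk = lambda *cl: LineageMarker(high_classes=cl, high_mean=hi, low_mean=lo, sd=sd)
    return {
        "S100": mk("Tumor"),
        "SMA": mk("Stroma"),
        "CD45": mk(*scheme.IMMUNE_CLASSES),
        "CD20": mk("BCell"),
        "CD8": mk("CytotoxicT"),
        "CD4": mk("HelperT", "Treg"),
        "FOXP3": mk("Treg"),
        "MPO": mk("Neutrophil"),
        "CD14": mk("Monocyte"),
        "CD68": mk("Macrophage"),
        "CD11C": mk("Dendritic"),
    }


@dataclass(frozen=True)
class CohortSpec:
    """Study-conditions description of a two-group synthetic cohort.

    Defaults mirror the study design: 9 recurrence vs 16 no-recurrence
    patients, ~16 tumor-core FOVs each, 2040 px square FOVs, ~3,500 cells
    per FOV of which ~60% are tumor.
    """

    n_patients_per_group: tuple[int, int] = (9, 16)
    group_names: tuple[str, str] = ("Recurrence", "NoRecurrence")
    fovs_per_patient: int = 16
    fov_size: float = scheme.DEFAULT_FOV_SIZE
    class_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_PROPORTIONS)
    )
    tumor_nest_process: NestProcess = field(default_factory=NestProcess)
    #: (group, index/attractor class, neighbor/attracted class) -> multiplier
    interaction_enrichments: dict[tuple[str, str, str], float] = field(
        default_factory=dict
    )
    enrichment_radius: float = 28.5  # px; matches the neighborhood radius
    lineage_markers: dict[str, LineageMarker] = field(
        default_factory=default_lineage_panel
    )
    marker_models: dict[str, MarkerMixture] = field(
        default_factory=lambda: {"PD1": MarkerMixture()}
    )
    specimen_shift_sd: float = 0.3  # arcsinh-scale batch shift on gated markers
    seed: int = 0

    # expected cells per FOV implied by the nest process and proportions
    def expected_fov_total(self) -> float:
        exp_tumor = (
            self.tumor_nest_process.parents_per_fov
            * self.tumor_nest_process.mean_offspring
        )
        p_t = self.class_proportions.get(scheme.TUMOR, 0.0)
        return exp_tumor / p_t if p_t > 0 else exp_tumor

    def validate(self) -> None:
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ParameterError(f"class proportions sum to {total}, not 1")
        if any(p < 0 for p in self.class_proportions.values()):
            raise ParameterError("class proportions must be nonnegative")
        unknown = set(self.class_proportions) - set(scheme.ALL_CLASSES)
        if unknown:
            raise ParameterError(f"unknown phenotype classes: {sorted(unknown)}")
        if any(m < 0 for m in self.interaction_enrichments.values()):
            raise ParameterError("attraction multipliers must be >= 0")
        for name, mm in self.marker_models.items():
            if not 0.0 <= mm.positive_fraction <= 1.0:
                raise ParameterError(f"{name}: positive fraction outside [0,1]")
        if self.expected_fov_total() < 10:
            raise DegenerateSpecError(
                f"expected {self.expected_fov_total():.1f} cells per FOV (< 10)"
            )


@dataclass
class GroundTruth:
    """Planted truth for a generated cohort."""

    table: pd.DataFrame  # cell_id, true_class, <marker>_true_pos ...
    enrichments: dict[tuple[str, str, str], float]


def replace(spec: CohortSpec, **changes) -> CohortSpec:
    """Functional update of a (frozen) CohortSpec."""
    return dataclasses.replace(spec, **changes)


# -- point placement ----------------------------------------------------------


def _tumor_nests(rng: np.random.Generator, nest: NestProcess, size: float) -> np.ndarray:
    n_parents = rng.poisson(nest.parents_per_fov)
    if n_parents == 0:
        return np.empty((0, 2))
    parents = rng.uniform(0.0, size, size=(n_parents, 2))
    n_off = rng.poisson(nest.mean_offspring, size=n_parents)
    pts = np.repeat(parents, n_off, axis=0)
    pts = pts + rng.normal(0.0, nest.dispersion, size=pts.shape)
    inside = ((pts >= 0.0) & (pts < size)).all(axis=1)
    return pts[inside]


def _place_enriched(
    rng: np.random.Generator,
    n: int,
    size: float,
    attractors: list[tuple[np.ndarray, float]],
    radius: float,
) -> np.ndarray:
    """Place n points by importance resampling of a uniform proposal.

    Each candidate's weight is ``max(0, 1 + sum (mult-1) * n_nearby)`` over
    the attractor point sets. With no attractors this reduces to a uniform
    (binomial) placement.
    """
    if n == 0:
        return np.empty((0, 2))
    if not attractors:
        return rng.uniform(0.0, size, size=(n, 2))
    m = max(10 * n, 200)
    cand = rng.uniform(0.0, size, size=(m, 2))
    w = np.ones(m)
    for pts, mult in attractors:
        if len(pts) == 0:
            continue
        tree = cKDTree(pts)
        counts = tree.query_ball_point(cand, radius, return_length=True)
        w += (mult - 1.0) * counts
    w = np.clip(w, 0.0, None)
    if not np.any(w > 0):
        return rng.uniform(0.0, size, size=(n, 2))
    if np.count_nonzero(w) < n:  # pathological repulsion: pad uniformly
        extra = n - np.count_nonzero(w)
        idx = np.flatnonzero(w > 0)
        return np.vstack(
            [cand[idx], rng.uniform(0.0, size, size=(extra, 2))]
        )
    idx = rng.choice(m, size=n, replace=False, p=w / w.sum())
    return cand[idx]


def _simulate_fov_points(
    rng: np.random.Generator, spec: CohortSpec, group: str
) -> tuple[np.ndarray, np.ndarray]:
    """Return (xy, class labels) for one FOV."""
    size = spec.fov_size
    exp_total = spec.expected_fov_total()
    placed_xy: list[np.ndarray] = []
    placed_cls: list[str] = []

    def _attractors_for(target: str) -> list[tuple[np.ndarray, float]]:
        out = []
        for xy, cls in zip(placed_xy, placed_cls):
            mult = spec.interaction_enrichments.get((group, cls, target), 1.0)
            if mult != 1.0 and len(xy):
                out.append((xy, mult))
        return out

    p_tumor = spec.class_proportions.get(scheme.TUMOR, 0.0)
    if p_tumor > 0:
        xy = _tumor_nests(rng, spec.tumor_nest_process, size)
        placed_xy.append(xy)
        placed_cls.append(scheme.TUMOR)
    # place remaining classes in scheme order so attraction acts from
    # already-placed classes (tumor first, then stroma, then immune)
    for cls in scheme.ALL_CLASSES:
        if cls == scheme.TUMOR:
            continue
        p = spec.class_proportions.get(cls, 0.0)
        if p <= 0:
            continue
        n = rng.poisson(exp_total * p)
        xy = _place_enriched(rng, n, size, _attractors_for(cls), spec.enrichment_radius)
        placed_xy.append(xy)
        placed_cls.append(cls)

    xy = np.vstack(placed_xy) if placed_xy else np.empty((0, 2))
    labels = np.concatenate(
        [np.full(len(p), c) for p, c in zip(placed_xy, placed_cls)]
    ) if placed_xy else np.empty(0, dtype=object)
    return xy, labels


# -- marker synthesis ---------------------------------------------------------


def _raw16(arcsinh_values: np.ndarray) -> np.ndarray:
    return np.clip(np.sinh(arcsinh_values), 0.0, 65535.0)


def _fov_markers(
    rng: np.random.Generator,
    spec: CohortSpec,
    labels: np.ndarray,
    group: str,
    specimen_shift: dict[str, float],
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Draw marker columns and truth flags for one FOV's cells."""
    n = len(labels)
    cols: dict[str, np.ndarray] = {}
    flags: dict[str, np.ndarray] = {}
    for name, lm in spec.lineage_markers.items():
        mu = np.where(np.isin(labels, lm.high_classes), lm.high_mean, lm.low_mean)
        mean_a = rng.normal(mu, lm.sd)
        sd_a = rng.normal(0.5 * mu, lm.sd)
        cols[f"{name}_mean"] = _raw16(mean_a)
        cols[f"{name}_sd"] = _raw16(sd_a)
    for name, mm in spec.marker_models.items():
        eligible = np.ones(n, dtype=bool)
        if mm.positive_classes is not None:
            eligible &= np.isin(labels, mm.positive_classes)
        if mm.positive_groups is not None and group not in mm.positive_groups:
            eligible[:] = False
        pos = eligible & (rng.random(n) < mm.positive_fraction)
        mu = np.where(pos, mm.positive_mean, mm.negative_mean)
        sd = np.where(pos, mm.positive_sd, mm.negative_sd)
        shift = specimen_shift[name]
        mean_a = rng.normal(mu + shift, sd)
        sd_a = rng.normal(mu * mm.sd_channel_scale + shift, sd)
        cols[f"{name}_mean"] = _raw16(mean_a)
        cols[f"{name}_sd"] = _raw16(sd_a)
        flags[name] = pos
    return cols, flags


# -- public API ---------------------------------------------------------------


def generate_cohort(
    spec: CohortSpec,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate a two-group cohort of tumor-core FOVs.

    Returns (cells, patients, ground truth); fully reproducible from
    ``spec.seed``. Cell phenotypes are pre-filled with the true class so the
    spatial stages can run with or without the classification stage.
    """
    spec.validate()
    root = np.random.SeedSequence(spec.seed)
    cell_frames: list[pd.DataFrame] = []
    truth_frames: list[pd.DataFrame] = []
    patient_rows: list[dict] = []

    for gi, (group, n_pat) in enumerate(
        zip(spec.group_names, spec.n_patients_per_group)
    ):
        for pi in range(n_pat):
            patient_id = f"{group}-{pi + 1:02d}"
            specimen_id = f"S-{patient_id}"
            patient_rows.append(
                {"patient_id": patient_id, "specimen_id": specimen_id, "outcome": group}
            )
            pat_seq = root.spawn(1)[0]
            pat_rng = np.random.Generator(np.random.PCG64(pat_seq))
            shift = {
                name: pat_rng.normal(0.0, spec.specimen_shift_sd)
                for name in spec.marker_models
            }
            for fi in range(spec.fovs_per_patient):
                fov_id = f"{patient_id}-F{fi + 1:02d}"
                rng = np.random.Generator(np.random.PCG64(pat_seq.spawn(1)[0]))
                xy, labels = _simulate_fov_points(rng, spec, group)
                cols, flags = _fov_markers(rng, spec, labels, group, shift)
                n = len(labels)
                ids = [f"{fov_id}-C{k:05d}" for k in range(n)]
                frame = pd.DataFrame(
                    {
                        "cell_id": ids,
                        "fov_id": fov_id,
                        "patient_id": patient_id,
                        "x": xy[:, 0] if n else np.empty(0),
                        "y": xy[:, 1] if n else np.empty(0),
                        "phenotype": labels,
                        **cols,
                    }
                )
                cell_frames.append(frame)
                tf = pd.DataFrame({"cell_id": ids, "true_class": labels})
                for name, f in flags.items():
                    tf[f"{name}_true_pos"] = f
                truth_frames.append(tf)

    cells = pd.concat(cell_frames, ignore_index=True)
    truth = pd.concat(truth_frames, ignore_index=True)
    patients = pd.DataFrame(patient_rows)
    return cells, patients, GroundTruth(truth, dict(spec.interaction_enrichments))


def generate_annotation_subset(
    cells: pd.DataFrame, truth: GroundTruth, n: int, seed: int
) -> pd.DataFrame:
    """Uniform random sample of cells carrying their true labels.

    Stands in for the expert annotation set used to train classifiers and
    calibrate gates.
    """
    total = len(cells)
    if n > total:
        raise ParameterError(f"requested {n} annotations from {total} cells")
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(total, size=n, replace=False))
    sample = cells.iloc[idx].merge(truth.table, on="cell_id", how="left")
    sample = sample.rename(columns={"true_class": "label"})
    return sample.reset_index(drop=True)


def generate_niche_fovs(
    niche_compositions: dict[str, dict[str, float]],
    fovs_per_niche: int,
    cells_per_fov: int,
    seed: int,
    fov_size: float = scheme.DEFAULT_FOV_SIZE,
) -> tuple[pd.DataFrame, pd.Series]:
    """Planted-niche benchmark: uniform FOVs whose composition depends on niche.

    Each FOV belongs to one niche; cells are placed uniformly with classes
    drawn from the niche's composition. Returns (cells, true niche per cell).
    Used to test whether community clustering recovers regional composition
    differences.
    """
    rng = np.random.default_rng(seed)
    frames, niches = [], []
    for niche, comp in niche_compositions.items():
        classes = sorted(comp)
        probs = np.array([comp[c] for c in classes], dtype=float)
        if abs(probs.sum() - 1.0) > 1e-9:
            raise ParameterError(f"niche {niche!r} composition sums to {probs.sum()}")
        for fi in range(fovs_per_niche):
            fov_id = f"{niche}-F{fi + 1:02d}"
            xy = rng.uniform(0.0, fov_size, size=(cells_per_fov, 2))
            labels = rng.choice(classes, size=cells_per_fov, p=probs)
            frames.append(
                pd.DataFrame(
                    {
                        "cell_id": [f"{fov_id}-C{k:05d}" for k in range(cells_per_fov)],
                        "fov_id": fov_id,
                        "x": xy[:, 0],
                        "y": xy[:, 1],
                        "phenotype": labels,
                    }
                )
            )
            niches.extend([niche] * cells_per_fov)
    cells = pd.concat(frames, ignore_index=True)
    return cells, pd.Series(niches, index=cells.index, name="niche")
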