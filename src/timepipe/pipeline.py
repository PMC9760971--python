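"""End-to-end orchestration: simulate/load -> phenotype -> gate -> communities
-> neighborhoods -> interactions -> cohort comparison.

Every stage writes its outputs as CSV under the configured output directory;
``run_metadata.json`` records the seed, parameters and package version. The
whole run is deterministic given (config, seed): two runs produce
byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__, communities, gating, interactions, io, neighborhoods
from . import phenotyping, scheme, stats, synth
from .errors import TimepipeError

log = logging.getLogger("timepipe")


@dataclass
class PipelineConfig:
    """Declarative pipeline configuration (keys mirror CLI flags)."""

    out_dir: str = "timepipe_out"
    seed: int = 0
    # input: either paths to existing tables or a synthetic cohort
    cells_path: str | None = None
    patients_path: str | None = None
    synthetic: dict | None = None  # CohortSpec field overrides; None + no paths -> default spec
    # stage toggles
    run_phenotyping: bool = False  # synthetic truth phenotypes are pre-filled
    run_gating: bool = True
    run_communities: bool = True
    run_neighborhoods: bool = True
    run_interactions: bool = True
    run_compare: bool = True
    # parameters
    community_k: int = scheme.DEFAULT_COMMUNITY_K
    community_c: int = scheme.DEFAULT_COMMUNITY_C
    label_threshold: float = communities.DEFAULT_LABEL_THRESHOLD
    diameter: float = scheme.DEFAULT_NEIGHBORHOOD_DIAMETER
    fov_size: float = scheme.DEFAULT_FOV_SIZE
    marker: str = "PD1"
    target_fpr: float = 0.01
    n_annotations: int = 2000

    @classmethod
    def from_json(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            payload = json.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise TimepipeError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)


@dataclass
class ReportBundle:
    """Paths and key tables produced by a pipeline run."""

    out_dir: Path
    outputs: dict[str, Path] = field(default_factory=dict)
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)


def _write(bundle: ReportBundle, name: str, frame: pd.DataFrame, index: bool = False) -> None:
    path = bundle.out_dir / f"{name}.csv"
    frame.to_csv(path, index=index)
    bundle.outputs[name] = path
    bundle.tables[name] = frame


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                log.info("stage %s", name)
                return fn(*args, **kwargs)
            except TimepipeError:
                raise
            except Exception as exc:  # annotate with the failing stage
                raise TimepipeError(f"stage {name!r} failed: {exc}") from exc

        return wrapper

    return deco


@_stage("input")
def _load_or_simulate(config: PipelineConfig, bundle: ReportBundle):
    if config.cells_path is not None:
        cells = io.read_cell_table(config.cells_path)
        patients = (
            io.read_patient_table(config.patients_path)
            if config.patients_path
            else None
        )
        truth = None
    else:
        spec = synth.CohortSpec(seed=config.seed)
        if config.synthetic:
            overrides = dict(config.synthetic)
            overrides.setdefault("seed", config.seed)
            spec = synth.replace(spec, **overrides)
        cells, patients, gt = synth.generate_cohort(spec)
        truth = gt
        _write(bundle, "truth", gt.table)
    if patients is not None:
        cells = io.join_patient_metadata(cells, patients)
        io.write_patient_table(patients, bundle.out_dir / "patients.csv")
        bundle.outputs["patients"] = bundle.out_dir / "patients.csv"
    return cells, patients, truth


@_stage("phenotyping")
def _phenotype(config, bundle, cells, truth):
    ann = synth.generate_annotation_subset(
        cells, truth, min(config.n_annotations, len(cells)), seed=config.seed
    )
    model, report = phenotyping.fit_hierarchical_classifier(ann, seed=config.seed)
    cells = phenotyping.classify_cells(model, cells)
    _write(bundle, "classifier_report", pd.DataFrame([report.as_dict()]))
    return cells


@_stage("gating")
def _gate(config, bundle, cells, truth):
    ann = synth.generate_annotation_subset(
        cells, truth, min(config.n_annotations, len(cells)), seed=config.seed + 1
    )
    model, cells = gating.gate_functional_marker(
        cells, config.marker, ann, target_fpr=config.target_fpr
    )
    path = bundle.out_dir / "gate_model.json"
    path.write_text(json.dumps(model.to_dict(), indent=2, sort_keys=True))
    bundle.outputs["gate_model"] = path
    return cells


@_stage("communities")
def _communities(config, bundle, cells):
    vectors = communities.knn_composition(cells, k=config.community_k)
    model = communities.fit_communities(
        vectors, c=config.community_c, seed=config.seed, k=config.community_k
    )
    communities.label_communities(model, threshold=config.label_threshold)
    _write(bundle, "community_assignments", model.assignments.reset_index())
    _write(bundle, "community_profiles", model.cluster_profiles, index=True)
    labels = pd.DataFrame(
        {
            "cluster": list(model.cluster_labels),
            "enriched_classes": ["|".join(v) for v in model.cluster_labels.values()],
        }
    )
    _write(bundle, "community_labels", labels)
    freq = communities.community_frequencies(model, cells)
    _write(bundle, "community_frequencies", freq, index=True)
    return model


@_stage("neighborhoods")
def _neighborhoods(config, bundle, cells):
    out = {}
    for name, index_class, require in (
        ("tccn", scheme.TUMOR, scheme.IMMUNE),
        ("ctcn", "CytotoxicT", scheme.TUMOR),
    ):
        matrix = neighborhoods.build_neighborhoods(
            cells, index_class, diameter=config.diameter, fov_size=config.fov_size
        )
        populated = neighborhoods.filter_populated(matrix, require)
        _write(bundle, name, matrix.data)
        _write(bundle, f"{name}_populated", populated.data)
        comp = neighborhoods.neighborhood_composition_by_patient(populated, cells)
        _write(bundle, f"{name}_composition", comp, index=True)
        out[name] = (matrix, populated)
    hist, means = neighborhoods.tumor_count_distribution(out["tccn"][1], cells)
    _write(bundle, "tccn_tumor_count_hist", hist, index=True)
    _write(bundle, "tccn_tumor_count_means", means.to_frame("mean_tumor_count"), index=True)
    return out


@_stage("interactions")
def _interactions(config, bundle, cells, nbhd):
    cats = {}
    for name, (matrix, _) in nbhd.items():
        c = interactions.categorize_neighborhoods(matrix)
        _write(bundle, f"{name}_categories", c)
        pair = interactions.pairing_frequencies(c, cells, by="outcome")
        _write(bundle, f"{name}_pairings", pair)
        cats[name] = c
    gated = io.gated_markers(cells)
    if config.marker in gated:
        pd1 = interactions.pd1_neighbor_frequencies(
            nbhd["tccn"][0], cells, marker=config.marker
        )
        _write(bundle, "pd1_tccn", pd1, index=True)
        _write(bundle, "pd1_tccn_flags", pd1.attrs["flags"])
    return cats


def patient_feature_counts(
    matrix: neighborhoods.NeighborhoodMatrix,
    cells: pd.DataFrame,
    kind: str,
    marker: str = "PD1",
) -> pd.DataFrame:
    """Tidy per-patient (feature, events, total) counts for a neighborhood family.

    ``kind`` is 'composition' (>= 1 neighbor of each immune class), 'category'
    (tumor-only / homotypic / heterotypic-pair features), or 'pd1' (>= 1
    positive neighbor per TIL class).
    """
    data = neighborhoods._attach_patient(matrix, cells)
    totals = data.groupby("patient_id").size()
    if kind == "composition":
        rows = []
        for c in scheme.IMMUNE_CLASSES:
            ev = (data[f"n_{c}"] >= 1).groupby(data["patient_id"]).sum()
            rows.append(
                pd.DataFrame(
                    {
                        "patient_id": ev.index,
                        "feature": f"contains:{c}",
                        "events": ev.to_numpy(),
                        "total": totals.reindex(ev.index).to_numpy(),
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)
    if kind == "category":
        categorized = interactions.categorize_neighborhoods(matrix)
        tidy = interactions.pairing_frequencies(categorized, cells, by="patient_id")
        return tidy.rename(columns={"group": "patient_id"})[
            ["patient_id", "feature", "events", "total"]
        ]
    if kind == "pd1":
        rows = []
        for c in scheme.TIL_CLASSES:
            col = f"pos_{marker}_{c}"
            if col not in data.columns:
                continue
            ev = (data[col] >= 1).groupby(data["patient_id"]).sum()
            rows.append(
                pd.DataFrame(
                    {
                        "patient_id": ev.index,
                        "feature": f"pd1:{c}",
                        "events": ev.to_numpy(),
                        "total": totals.reindex(ev.index).to_numpy(),
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)
    raise TimepipeError(f"unknown feature kind {kind!r}")


@_stage("compare")
def _compare(config, bundle, cells, patients, community_model, nbhd):
    families = []
    if community_model is not None:
        joined = cells.set_index("cell_id").join(community_model.assignments, how="inner")
        totals = joined.groupby("patient_id").size()
        rows = []
        for cluster in range(community_model.c):
            ev = (joined["cluster"] == cluster).groupby(joined["patient_id"]).sum()
            rows.append(
                pd.DataFrame(
                    {
                        "patient_id": ev.index,
                        "feature": f"community:{cluster}",
                        "events": ev.to_numpy(),
                        "total": totals.reindex(ev.index).to_numpy(),
                    }
                )
            )
        fam = stats.compare_groups(pd.concat(rows, ignore_index=True), patients)
        fam.insert(0, "family", "community")
        families.append(fam)
    if nbhd is not None:
        for name, (matrix, populated) in nbhd.items():
            for kind, mat in (("composition", populated), ("category", matrix)):
                counts = patient_feature_counts(mat, cells, kind, marker=config.marker)
                fam = stats.compare_groups(counts, patients)
                fam.insert(0, "family", f"{name}_{kind}")
                families.append(fam)
        if f"pos_{config.marker}" in nbhd["tccn"][0].data.columns:
            counts = patient_feature_counts(
                nbhd["tccn"][0], cells, "pd1", marker=config.marker
            )
            fam = stats.compare_groups(counts, patients)
            fam.insert(0, "family", "pd1_tccn")
            families.append(fam)
    comparisons = pd.concat(families, ignore_index=True) if families else pd.DataFrame()
    _write(bundle, "comparisons", comparisons)
    return comparisons


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Execute all enabled stages and write the report bundle."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bundle = ReportBundle(out_dir=out_dir)

    cells, patients, truth = _load_or_simulate(config, bundle)
    if config.run_phenotyping:
        if truth is None:
            raise TimepipeError("phenotyping stage needs ground-truth annotations")
        cells = _phenotype(config, bundle, cells, truth)
    if config.run_gating:
        if truth is None:
            raise TimepipeError("gating stage needs ground-truth annotations")
        cells = _gate(config, bundle, cells, truth)
    _write(bundle, "cells", cells)

    community_model = _communities(config, bundle, cells) if config.run_communities else None
    nbhd = _neighborhoods(config, bundle, cells) if config.run_neighborhoods else None
    if config.run_interactions and nbhd is not None:
        _interactions(config, bundle, cells, nbhd)
    if config.run_compare and patients is not None:
        _compare(config, bundle, cells, patients, community_model, nbhd)

    meta = {
        "version": __version__,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
    }
    meta_path = out_dir / "run_metadata.json"
    meta_path.write_text(json.dumps(meta, indent=2, sort_keys=True))
    bundle.outputs["run_metadata"] = meta_path
    return bundle
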