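"""Planted-truth validation experiments.

Because the imaging cohort behind this kind of analysis is never public,
the pipeline is validated on synthetic tissue with known ground truth.
This module bundles the standard experiments: planted-enrichment power and
null calibration for the neighborhood/interaction statistics, two-niche
community recovery, gating calibration, and classifier benchmarks. Each
function runs the full relevant slice of the pipeline from freshly
generated data and returns the measured quantities.

Problem sizes default to compact cohorts (20 patients/group, one ~750-cell
FOV each for the enrichment studies) chosen so that hundreds of replicates
run on a single CPU while per-group neighborhood counts stay in the
thousands.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from . import gating, neighborhoods, phenotyping, scheme, stats, synth
from .io import join_patient_metadata
from .pipeline import patient_feature_counts

DENDRITIC_FEATURE = "contains:Dendritic"
PAIRING_FEATURE = "pair:CytotoxicT+Dendritic"


def enrichment_spec(seed: int, multiplier: float, n_patients: int = 20) -> synth.CohortSpec:
    """Two-group cohort with Dendritic and CytotoxicT co-attraction to tumor
    planted in GroupA at the given multiplier (1 = null)."""
    enrichments = {}
    if multiplier != 1.0:
        enrichments = {
            ("GroupA", scheme.TUMOR, "Dendritic"): multiplier,
            ("GroupA", scheme.TUMOR, "CytotoxicT"): multiplier,
        }
    return synth.CohortSpec(
        n_patients_per_group=(n_patients, n_patients),
        group_names=("GroupA", "GroupB"),
        fovs_per_patient=1,
        tumor_nest_process=synth.NestProcess(parents_per_fov=15, mean_offspring=30),
        interaction_enrichments=enrichments,
        lineage_markers={},
        marker_models={},
        seed=seed,
    )


def enrichment_replicate(seed: int, multiplier: float, n_patients: int = 20) -> pd.DataFrame:
    """One cohort: generate, build TCCN, compare composition + category
    features between groups. Returns the comparison table."""
    cells, patients, _ = synth.generate_cohort(
        enrichment_spec(seed, multiplier, n_patients)
    )
    cells = join_patient_metadata(cells, patients)
    tccn = neighborhoods.build_neighborhoods(cells, scheme.TUMOR)
    populated = neighborhoods.filter_populated(tccn, scheme.IMMUNE)
    counts = pd.concat(
        [
            patient_feature_counts(populated, cells, "composition"),
            patient_feature_counts(tccn, cells, "category"),
        ],
        ignore_index=True,
    )
    return stats.compare_groups(counts, patients)


def enrichment_power_study(
    n_replicates: int = 100, multiplier: float = 3.0, seed: int = 0
) -> dict[str, float]:
    """Fraction of replicates where the planted dendritic-fraction and
    dendritic-CTL pairing signals are detected (p_adj < 0.05, GroupA higher)."""
    hits_d = hits_p = 0
    for i in range(n_replicates):
        res = enrichment_replicate(seed * 1000 + i, multiplier).set_index("feature")
        row = res.loc[DENDRITIC_FEATURE]
        hits_d += bool(row["significant"] and row["direction"] == "GroupA")
        if PAIRING_FEATURE in res.index:
            row = res.loc[PAIRING_FEATURE]
            hits_p += bool(row["significant"] and row["direction"] == "GroupA")
    return {
        "power_dendritic_fraction": hits_d / n_replicates,
        "power_dendritic_ctl_pairing": hits_p / n_replicates,
        "n_replicates": n_replicates,
    }


def null_false_flag_study(n_replicates: int = 200, seed: int = 0) -> dict[str, float]:
    """Fraction of features flagged significant on null cohorts (multiplier 1)."""
    flagged = total = 0
    for i in range(n_replicates):
        res = enrichment_replicate(seed * 1000 + 500_000 + i, 1.0)
        flagged += int(res["significant"].sum())
        total += len(res)
    return {
        "false_flag_rate": flagged / total,
        "n_feature_tests": total,
        "n_replicates": n_replicates,
    }


def two_niche_recovery(
    seed: int, k: int = 75, fovs_per_niche: int = 2, cells_per_fov: int = 400
) -> float:
    """ARI between planted niches (TV distance 0.8) and k-NN community
    clustering with c=2."""
    from . import communities

    tumor_niche = {"Tumor": 0.8, "Stroma": 0.1, "Macrophage": 0.1}
    immune_niche = {"Tumor": 0.2, "BCell": 0.4, "CytotoxicT": 0.4}
    cells, niche = synth.generate_niche_fovs(
        {"nicheA": tumor_niche, "nicheB": immune_niche},
        fovs_per_niche=fovs_per_niche,
        cells_per_fov=cells_per_fov,
        seed=seed,
    )
    vectors = communities.knn_composition(cells, k=k)
    model = communities.fit_communities(vectors, c=2, seed=seed)
    truth = niche.set_axis(cells["cell_id"]).loc[model.assignments.index]
    return float(adjusted_rand_score(truth, model.assignments))


def gating_calibration_experiment(
    seed: int, target_fpr: float = 0.01, positive_fraction: float = 0.15
) -> dict[str, float]:
    """Gate a ~20k-cell cohort with a planted PD1 mixture; measure held-out
    FPR and the estimated positive fraction among eligible TIL cells."""
    spec = synth.CohortSpec(
        n_patients_per_group=(3, 3),
        fovs_per_patient=2,
        tumor_nest_process=synth.NestProcess(parents_per_fov=25, mean_offspring=70),
        lineage_markers={},
        marker_models={"PD1": synth.MarkerMixture(positive_fraction=positive_fraction)},
        seed=seed,
    )
    cells, patients, truth = synth.generate_cohort(spec)
    cells = join_patient_metadata(cells, patients)
    ann = synth.generate_annotation_subset(cells, truth, 5000, seed=seed + 1)
    _, gated = gating.gate_functional_marker(cells, "PD1", ann, target_fpr=target_fpr)
    merged = gated.merge(
        truth.table[["cell_id", "true_class", "PD1_true_pos"]], on="cell_id"
    )
    held = ~merged["cell_id"].isin(set(ann["cell_id"]))
    negatives = merged[held & ~merged["PD1_true_pos"]]
    eligible = merged[merged["true_class"].isin(scheme.TIL_CLASSES)]
    return {
        "n_cells": len(cells),
        "held_out_fpr": float(negatives["PD1_pos"].mean()),
        "estimated_positive_fraction": float(eligible["PD1_pos"].mean()),
        "planted_positive_fraction": positive_fraction,
    }


def classifier_benchmark(seed: int, n_annotations: int = 4000) -> dict[str, float]:
    """Fit the two-tier classifier on well-separated synthetic annotations;
    report tier accuracies, whole-cohort planted-label recovery, hierarchical
    consistency, and the permuted-label null accuracy."""
    spec = synth.CohortSpec(
        n_patients_per_group=(2, 2),
        fovs_per_patient=2,
        tumor_nest_process=synth.NestProcess(parents_per_fov=15, mean_offspring=40),
        seed=seed,
    )
    cells, _, truth = synth.generate_cohort(spec)
    ann = synth.generate_annotation_subset(cells, truth, n_annotations, seed=seed + 1)
    model, report = phenotyping.fit_hierarchical_classifier(ann, seed=seed)
    out = phenotyping.classify_cells(model, cells)
    acc = float(
        out.set_index("cell_id")["phenotype"]
        .eq(truth.table.set_index("cell_id")["true_class"])
        .mean()
    )
    X = np.arcsinh(out[[f"{m}_mean" for m in model.feature_list]].to_numpy())
    broad1 = model.tier1.predict(X)
    fine_is_immune = out["phenotype"].isin(scheme.IMMUNE_CLASSES).to_numpy()
    consistency = float((fine_is_immune == (broad1 == scheme.IMMUNE)).mean())

    rng = np.random.default_rng(seed)
    shuffled = ann.copy()
    shuffled["label"] = rng.permutation(shuffled["label"].to_numpy())
    _, null_report = phenotyping.fit_hierarchical_classifier(shuffled, seed=seed)
    majority = (
        shuffled["label"].map(scheme.broad_class).value_counts(normalize=True).max()
    )
    return {
        "tier1_test_accuracy": report.tier1_test,
        "tier2_test_accuracy": report.tier2_test,
        "overall_accuracy_vs_truth": acc,
        "hierarchical_consistency": consistency,
        "permuted_tier1_test_accuracy": null_report.tier1_test,
        "broad_majority_rate": float(majority),
        "n_test": report.n_test,
    }
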