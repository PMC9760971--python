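"""Neighborhood categorization and pairing frequencies."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from timepipe import interactions, neighborhoods, scheme
from timepipe.errors import DependencyError
from tests.conftest import random_cells


def _cluster(cid_prefix, center, members):
    """Cells packed within a few px of `center` (one tight neighborhood)."""
    rows = []
    for i, phenotype in enumerate(members):
        rows.append(
            {
                "cell_id": f"{cid_prefix}{i}",
                "fov_id": "F",
                "x": center[0] + i * 2.0,
                "y": center[1],
                "phenotype": phenotype,
            }
        )
    return rows


def test_forced_categorizations():
    """Homotypic = one distinct immune class; heterotypic = >= 2; tumor-only
    = zero immune neighbors even when stroma is present."""
    rows = (
        _cluster("h", (100, 100), ["Tumor", "Macrophage", "Macrophage"])
        + _cluster("x", (600, 100), ["Tumor", "Dendritic", "CytotoxicT", "Tumor", "Tumor", "Tumor"])
        + _cluster("t", (1100, 100), ["Tumor", "Tumor", "Tumor", "Tumor", "Tumor", "Stroma"])
    )
    cells = pd.DataFrame(rows)
    matrix = neighborhoods.build_neighborhoods(cells, "Tumor")
    cats = interactions.categorize_neighborhoods(matrix).set_index("cell_id")
    assert cats.loc["h0", "category"] == "Homotypic"
    assert cats.loc["h0", "homotypic_class"] == "Macrophage"
    assert cats.loc["x0", "category"] == "Heterotypic"
    assert cats.loc["x0", "immune_classes_present"] == "CytotoxicT|Dendritic"
    assert cats.loc["t0", "category"] == "TumorOnly"


def test_categories_are_exhaustive_and_exclusive():
    rng = np.random.default_rng(7)
    cells = random_cells(rng, 800, fov_size=400.0)
    matrix = neighborhoods.build_neighborhoods(cells, "Tumor", fov_size=400.0)
    cats = interactions.categorize_neighborhoods(matrix)
    assert len(cats) == len(matrix.data)
    assert cats["category"].isin(["TumorOnly", "Homotypic", "Heterotypic"]).all()


def test_categorization_agrees_with_brute_force():
    """Re-derive each neighborhood's category from the raw cell list."""
    from scipy.spatial.distance import cdist

    rng = np.random.default_rng(8)
    cells = random_cells(rng, 600, fov_size=400.0)
    matrix = neighborhoods.build_neighborhoods(cells, "Tumor", fov_size=400.0)
    cats = interactions.categorize_neighborhoods(matrix).set_index("cell_id")
    xy = cells[["x", "y"]].to_numpy()
    d = cdist(xy, xy)
    phen = cells["phenotype"].to_numpy()
    ids = cells["cell_id"].to_numpy()
    for i in np.flatnonzero(phen == "Tumor"):
        classes = {
            phen[j]
            for j in range(len(cells))
            if j != i and d[i, j] <= 28.5 and phen[j] in scheme.IMMUNE_CLASSES
        }
        expected = (
            "TumorOnly" if not classes else "Homotypic" if len(classes) == 1 else "Heterotypic"
        )
        assert cats.loc[ids[i], "category"] == expected


def test_category_frequencies_sum_to_one_per_group(small_cohort):
    cells, _, _ = small_cohort
    matrix = neighborhoods.build_neighborhoods(cells, "Tumor")
    cats = interactions.categorize_neighborhoods(matrix)
    tidy = interactions.pairing_frequencies(cats, cells, by="outcome")
    base = tidy[~tidy["feature"].str.startswith("pair:")]
    sums = base.groupby("group")["frequency"].sum()
    assert np.allclose(sums, 1.0, atol=1e-9)


def test_heterotypic_neighborhood_contributes_all_pairs():
    """m distinct immune classes -> C(m,2) unordered pair contributions."""
    members = ["Tumor", "Dendritic", "CytotoxicT", "Macrophage"]
    cells = pd.DataFrame(_cluster("n", (200, 200), members))
    cells["patient_id"] = "P1"
    cells["outcome"] = "G"
    matrix = neighborhoods.build_neighborhoods(cells, "Tumor")
    cats = interactions.categorize_neighborhoods(matrix)
    tidy = interactions.pairing_frequencies(cats, cells, by="outcome")
    pairs = tidy[tidy["feature"].str.startswith("pair:")]
    assert len(pairs) == 3
    expected = {
        f"pair:{a}+{b}"
        for a, b in combinations(sorted(["Dendritic", "CytotoxicT", "Macrophage"]), 2)
    }
    assert set(pairs["feature"]) == expected


def test_total_pair_incidences_match_combinatorics(small_cohort):
    cells, _, _ = small_cohort
    matrix = neighborhoods.build_neighborhoods(cells, "Tumor")
    cats = interactions.categorize_neighborhoods(matrix)
    tidy = interactions.pairing_frequencies(cats, cells, by="outcome")
    total_pairs = tidy.loc[tidy["feature"].str.startswith("pair:"), "events"].sum()
    het = cats[cats["category"] == "Heterotypic"]
    expected = sum(
        len(list(combinations(s.split("|"), 2))) for s in het["immune_classes_present"]
    )
    assert total_pairs == expected


def test_group_with_only_homotypic_has_no_pair_events():
    cells = pd.DataFrame(_cluster("n", (200, 200), ["Tumor", "Macrophage", "Macrophage"]))
    cells["patient_id"] = "P1"
    cells["outcome"] = "G"
    matrix = neighborhoods.build_neighborhoods(cells, "Tumor")
    cats = interactions.categorize_neighborhoods(matrix)
    tidy = interactions.pairing_frequencies(cats, cells, by="outcome")
    assert not tidy["feature"].str.startswith("pair:").any()


class TestPD1Frequencies:
    def _cells(self, positive: bool):
        cells = pd.DataFrame(
            _cluster("n", (200, 200), ["Tumor", "CytotoxicT", "HelperT"])
            + _cluster("m", (600, 200), ["Tumor", "CytotoxicT"])
        )
        cells["patient_id"] = "P1"
        cells["PD1_pos"] = positive & (cells["phenotype"] == "CytotoxicT")
        return cells

    def test_no_positive_cells_gives_zero_fractions(self):
        cells = self._cells(False)
        matrix = neighborhoods.build_neighborhoods(cells, "Tumor")
        freq = interactions.pd1_neighbor_frequencies(matrix, cells)
        assert (freq.loc["P1"] == 0.0).all()

    def test_ubiquitous_positive_class_gives_fraction_one(self):
        cells = self._cells(True)
        matrix = neighborhoods.build_neighborhoods(cells, "Tumor")
        freq = interactions.pd1_neighbor_frequencies(matrix, cells)
        assert freq.loc["P1", "CytotoxicT"] == 1.0
        assert freq.loc["P1", "HelperT"] == 0.0
        flags = freq.attrs["flags"]
        assert flags["has_positive"].all()

    def test_ungated_marker_raises_dependency_error(self):
        cells = self._cells(True).drop(columns=["PD1_pos"])
        matrix = neighborhoods.build_neighborhoods(cells, "Tumor")
        with pytest.raises(DependencyError, match="gate"):
            interactions.pd1_neighbor_frequencies(matrix, cells)


def test_planted_group_restricted_positives_recovered():
    """PD1 positives planted only in GroupA helper T cells: GroupA's HelperT
    PD1+ neighbor fraction must exceed GroupB's."""
    from timepipe import generate_cohort, join_patient_metadata, synth
    from timepipe import gating
    from timepipe.synth import MarkerMixture, NestProcess

    spec = synth.CohortSpec(
        n_patients_per_group=(3, 3),
        group_names=("GroupA", "GroupB"),
        fovs_per_patient=2,
        tumor_nest_process=NestProcess(parents_per_fov=15, mean_offspring=30),
        lineage_markers={},
        marker_models={
            "PD1": MarkerMixture(
                positive_fraction=0.4,
                positive_classes=("HelperT",),
                positive_groups=("GroupA",),
            )
        },
        seed=23,
    )
    cells, patients, truth = generate_cohort(spec)
    cells = join_patient_metadata(cells, patients)
    ann = synth.generate_annotation_subset(cells, truth, 3000, seed=1)
    _, gated = gating.gate_functional_marker(cells, "PD1", ann, target_fpr=0.01)
    matrix = neighborhoods.build_neighborhoods(gated, "Tumor")
    freq = interactions.pd1_neighbor_frequencies(matrix, gated)
    by_group = freq.join(patients.set_index("patient_id")["outcome"]).groupby("outcome")[
        "HelperT"
    ].mean()
    assert by_group["GroupA"] > by_group["GroupB"]
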