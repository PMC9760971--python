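"""Cellular communities: composition oracles, clustering, labels, sweeps."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from timepipe import communities, scheme, synth
from timepipe.errors import ParameterError
from tests.conftest import brute_knn_composition, random_cells


def test_toy_composition_matches_hand_derivation():
    """Four collinear cells, k=2: the query cell's two nearest neighbors are
    one Tumor and one BCell."""
    cells = pd.DataFrame(
        {
            "cell_id": ["q", "b1", "t2", "b2"],
            "fov_id": "F",
            "x": [0.0, 1.0, 2.0, 10.0],
            "y": 0.0,
            "phenotype": ["Tumor", "BCell", "Tumor", "BCell"],
        }
    )
    vec = communities.knn_composition(cells, k=2)
    assert vec.loc["q", "Tumor"] == 0.5
    assert vec.loc["q", "BCell"] == 0.5


def test_single_class_fov_gives_one_hot_vectors():
    rng = np.random.default_rng(1)
    cells = random_cells(rng, 60, classes=("Macrophage",))
    vec = communities.knn_composition(cells, k=10)
    assert (vec["Macrophage"] == 1.0).all()
    assert (vec[[c for c in scheme.ALL_CLASSES if c != "Macrophage"]] == 0.0).all().all()


def test_knn_composition_matches_brute_force_oracle():
    rng = np.random.default_rng(2)
    cells = random_cells(rng, 500)
    vec = communities.knn_composition(cells, k=75)
    oracle = brute_knn_composition(cells, k=75)
    pd.testing.assert_frame_equal(
        vec.drop(columns="fov_id").sort_index(), oracle.sort_index()
    )


def test_fractions_sum_to_one(small_cohort):
    cells, _, _ = small_cohort
    vec = communities.knn_composition(cells, k=30)
    sums = vec.drop(columns="fov_id").sum(axis=1)
    assert np.allclose(sums, 1.0, atol=1e-9)


def test_small_fov_skipped_with_warning():
    rng = np.random.default_rng(3)
    big = random_cells(rng, 50, fov_id="big")
    tiny = random_cells(rng, 5, fov_id="tiny")
    cells = pd.concat([big, tiny], ignore_index=True)
    with pytest.warns(UserWarning, match="tiny"):
        vec = communities.knn_composition(cells, k=10)
    assert set(vec["fov_id"]) == {"big"}


def test_nonpositive_k_rejected():
    with pytest.raises(ParameterError):
        communities.knn_composition(pd.DataFrame(), k=0)


class TestFitCommunities:
    def _blocks(self):
        cols = list(scheme.ALL_CLASSES)
        a = pd.DataFrame(0.0, index=[f"a{i}" for i in range(50)], columns=cols)
        a["Tumor"] = 1.0
        b = pd.DataFrame(0.0, index=[f"b{i}" for i in range(50)], columns=cols)
        b["BCell"] = 1.0
        return pd.concat([a, b]).rename_axis("cell_id")

    def test_planted_blocks_recovered_exactly(self):
        vectors = self._blocks()
        model = communities.fit_communities(vectors, c=2, seed=0)
        truth = [0] * 50 + [1] * 50
        assert adjusted_rand_score(truth, model.assignments.loc[vectors.index]) == 1.0

    def test_same_seed_identical_assignments(self):
        vectors = self._blocks()
        m1 = communities.fit_communities(vectors, c=2, seed=7)
        m2 = communities.fit_communities(vectors, c=2, seed=7)
        pd.testing.assert_series_equal(m1.assignments, m2.assignments)

    def test_input_order_does_not_matter(self):
        vectors = self._blocks()
        shuffled = vectors.sample(frac=1.0, random_state=1)
        m1 = communities.fit_communities(vectors, c=2, seed=7)
        m2 = communities.fit_communities(shuffled, c=2, seed=7)
        pd.testing.assert_series_equal(m1.assignments, m2.assignments)

    def test_single_cluster_profile_is_global_mean(self):
        vectors = self._blocks()
        model = communities.fit_communities(vectors, c=1, seed=0)
        assert model.assignments.nunique() == 1
        expected = vectors.mean()
        pd.testing.assert_series_equal(
            model.cluster_profiles.iloc[0], expected, check_names=False
        )

    def test_too_many_clusters_rejected(self):
        with pytest.raises(ParameterError):
            communities.fit_communities(self._blocks(), c=500, seed=0)

    def test_profiles_rows_sum_to_one(self, small_cohort):
        cells, _, _ = small_cohort
        vectors = communities.knn_composition(cells, k=30)
        model = communities.fit_communities(vectors, c=5, seed=0)
        assert np.allclose(model.cluster_profiles.sum(axis=1), 1.0, atol=1e-6)


def test_two_niche_cohort_recovered_with_high_ari():
    """FOVs drawn from two compositions at total-variation distance >= 0.5
    are recovered by k=75 community clustering with ARI >= 0.9."""
    tumor_niche = {"Tumor": 0.8, "Stroma": 0.1, "Macrophage": 0.1}
    immune_niche = {"Tumor": 0.2, "BCell": 0.4, "CytotoxicT": 0.4}
    # TV distance = 0.5*(0.6+0.1+0.1+0.4+0.4) = 0.8
    cells, niche = synth.generate_niche_fovs(
        {"nicheA": tumor_niche, "nicheB": immune_niche},
        fovs_per_niche=2,
        cells_per_fov=400,
        seed=0,
    )
    vectors = communities.knn_composition(cells, k=75)
    model = communities.fit_communities(vectors, c=2, seed=0)
    truth = niche.set_axis(cells["cell_id"]).loc[model.assignments.index]
    assert adjusted_rand_score(truth, model.assignments) >= 0.9


class TestLabels:
    def _model_with_profile(self, profile: dict) -> communities.CommunityModel:
        row = pd.Series(0.0, index=list(scheme.ALL_CLASSES))
        for k, v in profile.items():
            row[k] = v
        profiles = pd.DataFrame([row])
        return communities.CommunityModel(
            c=1,
            k=75,
            centroids=profiles.to_numpy(),
            assignments=pd.Series(dtype=int),
            cluster_profiles=profiles,
        )

    def test_tumor_dendritic_cluster_labelled_by_enriched_classes(self):
        """A cluster of 59% tumor and 26% dendritic cells is labelled
        {Tumor, Dendritic}, in descending order of contribution."""
        rest = (1 - 0.59 - 0.26) / 8
        prof = {c: rest for c in scheme.IMMUNE_CLASSES if c != "Dendritic"}
        prof.update({"Tumor": 0.59, "Dendritic": 0.26})
        model = self._model_with_profile(prof)
        communities.label_communities(model)
        assert model.cluster_labels[0] == ["Tumor", "Dendritic"]

    def test_dominant_tumor_cluster_labelled_tumor_only(self):
        rest = 0.05 / 10
        prof = {c: rest for c in scheme.ALL_CLASSES if c != "Tumor"}
        prof["Tumor"] = 0.95
        model = self._model_with_profile(prof)
        communities.label_communities(model)
        assert model.cluster_labels[0] == ["Tumor"]

    def test_uniform_profile_has_empty_label_at_strict_threshold(self):
        prof = {c: 0.10 for c in scheme.ALL_CLASSES[:10]}
        model = self._model_with_profile(prof)
        communities.label_communities(model, threshold=0.10)
        assert model.cluster_labels[0] == []


class TestFrequencies:
    def test_rows_sum_to_one_and_identical_patients_match(self, small_cohort):
        cells, _, _ = small_cohort
        vectors = communities.knn_composition(cells, k=30)
        model = communities.fit_communities(vectors, c=4, seed=0)
        freq = communities.community_frequencies(model, cells)
        assert np.allclose(freq.sum(axis=1), 1.0, atol=1e-9)

    def test_single_cluster_gives_unit_row(self, small_cohort):
        cells, _, _ = small_cohort
        vectors = communities.knn_composition(cells, k=30)
        model = communities.fit_communities(vectors, c=1, seed=0)
        freq = communities.community_frequencies(model, cells)
        assert (freq[0] == 1.0).all()


class TestSweep:
    def test_grid_size(self, small_cohort):
        cells, _, _ = small_cohort
        table = communities.sweep_parameters(cells, [5, 30], [2, 6], seed=0)
        assert len(table) == 4
        assert set(zip(table["k"], table["c"])) == {(5, 2), (5, 6), (30, 2), (30, 6)}

    def test_inertia_non_increasing_in_c(self, small_cohort):
        cells, _, _ = small_cohort
        table = communities.sweep_parameters(cells, [30], [2, 4, 8], seed=0)
        inertia = table.sort_values("c")["inertia"].to_numpy()
        # allow 1% mini-batch noise
        assert (np.diff(inertia) <= 0.01 * inertia[:-1]).all()

    def test_empty_grid_rejected(self, small_cohort):
        cells, _, _ = small_cohort
        with pytest.raises(ParameterError):
            communities.sweep_parameters(cells, [], [2], seed=0)
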