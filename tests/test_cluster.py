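import numpy as np
import pandas as pd
import pytest

from lofclust._exceptions import ConfigurationError, ValidationError
from lofclust.cluster import (
    PositionClusterer,
    assign,
    fit_clusterer,
    label_roles,
    role_composition,
)
from lofclust.profiles import profile_matrix


class TestLabelRoles:
    @pytest.mark.parametrize(
        "centroid,expected",
        [
            ([0, 0, 0, 0, 0], "empty"),
            ([0.2, 0.2, 0.2, 0.2, 0.2], "uniform"),
            ([0.01, 0.04, 0.25, 0.3, 0.4], "non_uniform"),
            ([0.05, 0.2, 0.25, 0.25, 0.25], "uniform"),  # exactly at threshold
        ],
    )
    def test_rule(self, centroid, expected):
        assert label_roles(np.array([centroid]))[0] == expected


class TestFit:
    def test_identical_profiles_raise_configuration_error(self):
        X = np.tile([0.2, 0.2, 0.2, 0.2, 0.2], (50, 1))
        with pytest.raises(ConfigurationError, match="n_clusters"):
            PositionClusterer(n_clusters=7).fit(X)

    def test_refit_same_seed_gives_identical_parameters(self, small_profiles):
        pop = small_profiles[small_profiles["dataset"] == "population"]
        m1 = fit_clusterer(pop, random_state=11)
        m2 = fit_clusterer(pop, random_state=11)
        np.testing.assert_array_equal(m1.gmm_.means_, m2.gmm_.means_)
        np.testing.assert_array_equal(m1.gmm_.weights_, m2.gmm_.weights_)
        assert m1.roles_ == m2.roles_

    def test_roles_cover_all_three_patterns(self, fitted_model):
        assert {"empty", "uniform", "non_uniform"} <= set(fitted_model.roles_)

    def test_projection_consistency_on_training_data(self, small_profiles, fitted_model):
        pop = small_profiles[small_profiles["dataset"] == "population"]
        X = profile_matrix(pop)
        np.testing.assert_array_equal(fitted_model.predict(X), fitted_model.labels_)


class TestAssign:
    def test_zero_profile_goes_to_empty_cluster_with_high_posterior(self, fitted_model):
        proba = fitted_model.predict_proba(np.zeros((1, 5)))
        cluster = int(np.argmax(proba))
        assert fitted_model.roles_[cluster] == "empty"
        assert proba[0, cluster] > 0.99

    def test_exact_uniform_profile_is_uniform_role(self, fitted_model):
        assert fitted_model.predict_roles(np.array([[0.2] * 5]))[0] == "uniform"

    def test_start_depleted_profile_is_non_uniform_role(self, fitted_model):
        X = np.array([[0.0, 0.0, 0.3, 0.3, 0.4]])
        assert fitted_model.predict_roles(X)[0] == "non_uniform"

    def test_negative_entries_rejected(self, fitted_model):
        with pytest.raises(ValidationError):
            fitted_model.predict(np.array([[-0.1, 0.3, 0.3, 0.3, 0.2]]))

    def test_assign_posteriors_sum_to_one_and_argmax_matches(self, small_profiles, fitted_model):
        out = assign(small_profiles, fitted_model)
        post = out[[c for c in out.columns if c.startswith("posterior_")]].to_numpy()
        np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-9)
        np.testing.assert_array_equal(np.argmax(post, axis=1), out["cluster_id"])


class TestRecovery:
    def test_regime_roles_recovered(self, small_cohort, small_profiles, fitted_model):
        pop = small_profiles[small_profiles["dataset"] == "population"]
        out = assign(pop, fitted_model)
        plof = out[out["class"] == "plof_all"].merge(small_cohort.truth, on="gene_id")
        for expected, floor in (("uniform", 0.9), ("non_uniform", 0.9), ("empty", 1.0)):
            sub = plof[plof["expected_role"] == expected]
            assert (sub["role"] == expected).mean() >= floor

    def test_role_composition_invariant_to_refit_seed(self):
        # well-separated profiles: high-count multinomials leave no boundary
        # genes, so roles agree across restarts up to label permutation
        rng = np.random.default_rng(0)
        X = np.vstack(
            [
                rng.multinomial(400, [0.2] * 5, size=100) / 400,
                rng.multinomial(400, [0, 0, 1 / 3, 1 / 3, 1 / 3], size=40) / 400,
                np.zeros((20, 5)),
            ]
        )
        frame = pd.DataFrame(
            {
                "gene_id": [f"G{i}" for i in range(len(X))],
                "class": "plof_all",
                "dataset": "population",
                "n": 400,
            }
        )
        for i in range(5):
            frame[f"p{i + 1}"] = X[:, i]
        roles = []
        for seed in (3, 19):
            model = fit_clusterer(frame, random_state=seed)
            roles.append(assign(frame, model)["role"].to_numpy())
        np.testing.assert_array_equal(roles[0], roles[1])


class TestRoleComposition:
    @staticmethod
    def stub(roles, cls="plof_all"):
        return pd.DataFrame(
            {
                "gene_id": [f"G{i}" for i in range(len(roles))],
                "class": cls,
                "dataset": "population",
                "role": roles,
            }
        )

    def test_fractions_exclude_empty_from_denominator(self):
        table = role_composition(
            self.stub(["uniform"] * 90 + ["non_uniform"] * 10 + ["empty"] * 20)
        )
        uni = table[table["role"] == "uniform"].iloc[0]
        assert uni["fraction"] == pytest.approx(0.90)
        assert uni["n_nonempty"] == 100

    def test_all_empty_is_flagged_undefined(self):
        table = role_composition(self.stub(["empty"] * 5))
        assert not table["defined"].any()
        assert table["fraction"].isna().all()

    def test_gene_set_restriction(self):
        table = role_composition(
            self.stub(["non_uniform"] * 4 + ["uniform"] * 6),
            gene_set=[f"G{i}" for i in range(10)],
        )
        nonuni = table[table["role"] == "non_uniform"].iloc[0]
        assert nonuni["fraction"] == pytest.approx(0.4)


class TestSerialization:
    def test_json_round_trip_preserves_predictions(self, fitted_model, tmp_path):
        path = tmp_path / "model.json"
        fitted_model.save(path)
        back = PositionClusterer.load(path)
        X = np.array(
            [[0.2] * 5, [0, 0, 0.3, 0.3, 0.4], [0.0] * 5, [0.5, 0.5, 0, 0, 0]]
        )
        np.testing.assert_allclose(
            fitted_model.predict_proba(X), back.predict_proba(X), atol=1e-12
        )
        assert list(back.roles_) == list(fitted_model.roles_)
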