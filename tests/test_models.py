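"""Model fitting: pseudo-absences, GLM, maxent-like, projection, importance."""

import numpy as np
import pytest

from stacksdm.grid import GridSpec
from stacksdm.models import (FittedModel, fit_glm, fit_maxent_like,
                             fitted_optimum, important_variables,
                             permutation_importance, predict_suitability,
                             predict_vectors, sample_pseudo_absences)
from stacksdm.prep import build_samples, presence_cells
from stacksdm.synthetic import (apply_scenario_shift, sample_occurrences)
from stacksdm.evaluation import evaluate_replicate, tss_curve


# a larger world than the session fixture: 500 presences need ten times
# as many background cells to be available outside presence cells
@pytest.fixture(scope="module")
def grid():
    from stacksdm.grid import GridSpec
    return GridSpec(n_rows=90, n_cols=90, cell_size_km=10.0)


@pytest.fixture(scope="module")
def stack(grid):
    from stacksdm.synthetic import generate_climate_stack
    return generate_climate_stack(grid, n_vars=3, seed=11)


@pytest.fixture(scope="module")
def truth(stack):
    from stacksdm.synthetic import ResponseParam, VirtualSpeciesTruth
    v1 = stack["bio1"]
    return VirtualSpeciesTruth(
        species_id="sp001", guild="FR", habitat="FT",
        response_params={"bio1": ResponseParam(
            optimum=float(np.quantile(v1, 0.2)), breadth=1.0, weight=12.0)},
        prevalence_target=0.2)


@pytest.fixture(scope="module")
def true_prob(stack, truth):
    from stacksdm.synthetic import generate_virtual_species
    return generate_virtual_species(stack, truth)


@pytest.fixture(scope="module")
def presence_points(true_prob, grid):
    occ = sample_occurrences(true_prob, grid, 500, seed=21)
    return occ.for_species("sp")


@pytest.fixture(scope="module")
def training_data(presence_points, stack, grid):
    pa_sets = sample_pseudo_absences(presence_points, grid, seed=22)
    xp = build_samples(presence_points, stack)
    xa = build_samples(pa_sets[0].points, stack)
    return xp, xa


class TestPseudoAbsences:
    def test_ten_times_presences_in_three_sets(self, presence_points, grid):
        sets = sample_pseudo_absences(presence_points, grid, seed=1)
        assert len(sets) == 3
        for s in sets:
            assert len(s.points) == 10 * len(presence_points)

    def test_sets_differ(self, presence_points, grid):
        a, b, _ = sample_pseudo_absences(presence_points, grid, seed=1)
        assert set(map(tuple, a.points)) != set(map(tuple, b.points))

    def test_no_point_in_a_presence_cell(self, presence_points, grid):
        occupied = presence_cells(presence_points, grid)
        for s in sample_pseudo_absences(presence_points, grid, seed=2):
            for x, y in s.points:
                r, c = grid.cell_of(x, y)
                assert not occupied[r, c]

    def test_insufficient_candidate_cells_rejected(self):
        tiny = GridSpec(3, 3)
        pts = np.array([[5.0, 5.0], [15.0, 5.0]])
        with pytest.raises(ValueError, match="non-presence cells"):
            sample_pseudo_absences(pts, tiny, multiplier=10, seed=0)


class TestGlm:
    def test_separable_data_orders_probabilities(self):
        xp = np.array([[2.0 + 0.1 * i] for i in range(20)])
        xa = np.array([[-2.0 - 0.1 * i] for i in range(20)])
        m = fit_glm(xp, xa, ["v"])
        assert m.converged
        assert predict_vectors(m, [[2.5]]) > predict_vectors(m, [[-2.5]])

    def test_null_data_gives_near_zero_slopes(self):
        rng = np.random.default_rng(0)
        xp = rng.normal(size=(300, 2))
        xa = rng.normal(size=(300, 2))
        m = fit_glm(xp, xa, ["a", "b"])
        # labels carry no signal: every slope should sit within ~3 SE of 0
        # (SE >= 1/sqrt(n) on standardized features at this sample size)
        assert np.all(np.abs(m.coef) < 3.0 / np.sqrt(600) * 5)

    def test_recovers_niche_optimum_from_virtual_truth(self, training_data,
                                                       truth):
        xp, xa = training_data
        m = fit_glm(xp, xa, ["bio1", "bio2", "bio3"])
        rp = truth.response_params["bio1"]
        assert abs(fitted_optimum(m, "bio1") - rp.optimum) < rp.breadth / 2

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            fit_glm(np.ones((1, 1)), np.zeros((5, 1)), ["v"])
        with pytest.raises(ValueError):
            fit_glm(np.ones((5, 1)), np.ones((5, 1)), ["v"])  # constant


class TestMaxentLike:
    def test_suitability_rank_correlates_with_truth(self, training_data,
                                                    stack, true_prob):
        from scipy.stats import spearmanr
        xp, xa = training_data
        m = fit_maxent_like(xp, xa, ["bio1", "bio2", "bio3"], seed=1)
        pred = predict_suitability(m, stack)
        rho, _ = spearmanr(pred.ravel(), true_prob.ravel())
        assert rho > 0.9

    def test_permuted_labels_have_no_skill(self, training_data):
        rng = np.random.default_rng(5)
        xp, xa = training_data
        x = np.vstack([xp, xa])
        y = np.concatenate([np.ones(len(xp)), np.zeros(len(xa))])
        y = rng.permutation(y)
        m = fit_maxent_like(x[y == 1], x[y == 0],
                            ["bio1", "bio2", "bio3"], seed=2)
        # held-out half
        half = len(y) // 2
        scores = predict_vectors(m, x[:half])
        rec = evaluate_replicate("maxent_like", 1, 1, scores, y[:half])
        assert rec.tss < 0.2

    def test_identical_backgrounds_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            fit_maxent_like(np.random.default_rng(0).normal(size=(10, 1)),
                            np.ones((10, 1)), ["v"])


class TestPrediction:
    def test_intercept_only_model_is_constant_logistic(self, stack):
        from scipy.special import expit
        m = FittedModel(algorithm="glm", pa_set_id=1, repeat_id=1,
                        layer_names=["bio1"], coef=np.zeros(2),
                        intercept=0.7, feature_means=np.zeros(1),
                        feature_sds=np.ones(1))
        pred = predict_suitability(m, stack)
        assert np.allclose(pred, expit(0.7))

    def test_bounds_and_consistency_with_training_vectors(self,
                                                          training_data,
                                                          stack, grid):
        xp, xa = training_data
        m = fit_glm(xp, xa, ["bio1", "bio2", "bio3"])
        pred_map = predict_suitability(m, stack)
        assert np.all((pred_map >= 0) & (pred_map <= 1))
        # projecting onto the stack reproduces per-cell vector predictions
        for r, c in [(0, 0), (3, 7), (12, 40), (49, 49), (25, 25)]:
            cellvec = [[stack[n][r, c] for n in ["bio1", "bio2", "bio3"]]]
            assert pred_map[r, c] == pytest.approx(
                float(predict_vectors(m, cellvec)[0]))

    def test_projection_onto_shifted_stack_matches_shifted_vectors(
            self, training_data, stack, grid):
        xp, xa = training_data
        m = fit_glm(xp, xa, ["bio1", "bio2", "bio3"])
        shifted = apply_scenario_shift(stack, {"bio1": 1.5}, "warm")
        pred_map = predict_suitability(m, shifted)
        mat = stack.as_matrix(["bio1", "bio2", "bio3"]).copy()
        mat[:, 0] += 1.5
        np.testing.assert_allclose(pred_map.ravel(),
                                   predict_vectors(m, mat), atol=1e-12)

    def test_missing_layer_rejected(self, training_data, grid):
        from stacksdm.grid import ClimateStack
        xp, xa = training_data
        m = fit_glm(xp, xa, ["bio1", "bio2", "bio3"])
        partial = ClimateStack(grid=grid, scenario_id="x",
                               layers={"bio1": np.zeros(grid.shape)})
        with pytest.raises(KeyError):
            predict_suitability(m, partial)


class TestPermutationImportance:
    def test_unused_variable_has_zero_importance(self, training_data):
        rng = np.random.default_rng(1)
        xp, xa = training_data
        # append a pure-noise column the truth never used
        xp2 = np.hstack([xp, rng.normal(size=(len(xp), 1))])
        xa2 = np.hstack([xa, rng.normal(size=(len(xa), 1))])
        m = fit_maxent_like(xp2, xa2, ["bio1", "bio2", "bio3", "noise"],
                            seed=3)
        imp = permutation_importance(m, np.vstack([xp2, xa2]), seed=4)
        assert imp["bio1"] > imp["noise"]
        assert imp["noise"] < 0.05

    def test_driver_variable_dominates(self, training_data):
        xp, xa = training_data
        m = fit_glm(xp, xa, ["bio1", "bio2", "bio3"])
        imp = permutation_importance(m, np.vstack([xp, xa]), seed=2)
        assert imp["bio1"] == max(imp.values())

    def test_importance_threshold_flags(self):
        imp = {"a": 0.45, "b": 0.30, "c": 0.1}
        assert important_variables(imp) == ["a"]  # strict > 30%

    def test_constant_predictions_warn_and_zero(self, training_data):
        xp, xa = training_data
        m = FittedModel(algorithm="glm", pa_set_id=1, repeat_id=1,
                        layer_names=["bio1", "bio2", "bio3"],
                        coef=np.zeros(6), intercept=0.0,
                        feature_means=np.zeros(3), feature_sds=np.ones(3))
        with pytest.warns(UserWarning):
            imp = permutation_importance(m, xp, seed=0)
        assert set(imp.values()) == {0.0}
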