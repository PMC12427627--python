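"""Additive behavioral model: additivity, pruning, screening, explainability."""

import numpy as np
import pytest

import neurofuse as nf
from neurofuse.gami import GAMIModel


def _random_model(seed=0, pairs=((0, 1), (2, 3))):
    return GAMIModel.random(6, pairs=pairs, seed=seed)


def _interaction_cohort(seed, n=300, p=5):
    """Binary outcome driven purely by the (1, 2) feature interaction."""
    rng = np.random.default_rng(seed)
    X = rng.random((n, p))
    z = 16.0 * (X[:, 1] - 0.5) * (X[:, 2] - 0.5)
    y = (z + 0.5 * rng.standard_normal(n) > 0).astype(int)
    return X, y


class TestAdditivity:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_predict_is_sigmoid_of_effect_sum(self, seed, rng):
        """Exact decomposition: prob == sigmoid(row-sum of effects + bias)."""
        model = _random_model(seed)
        X = rng.random((40, 6))
        prob = nf.gami_predict(model, X).prob
        effects = nf.gami_effects(model, X)
        recon = 1.0 / (1.0 + np.exp(-(effects.sum(axis=1).to_numpy() + model.bias)))
        assert np.abs(prob - recon).max() < 1e-6
        assert prob.min() >= 0 and prob.max() <= 1

    def test_pruned_effects_contribute_exactly_zero(self, rng):
        model = _random_model(3)
        model.main_active[2] = False
        model.inter_active[1] = False
        X = rng.random((25, 6))
        before = nf.gami_predict(model, X).prob
        # perturbing a pruned subnetwork must not move any prediction
        model.main["W0"][2] += 100.0
        model.inter["W2"][1] -= 50.0
        after = nf.gami_predict(model, X).prob
        assert np.array_equal(before, after)
        names = nf.gami_effects(model, X).columns
        assert "x2" not in names and "x2*x3" not in names

    def test_all_effects_zeroed_gives_half(self):
        model = _random_model(4)
        model.main_active[:] = False
        model.inter_active[:] = False
        model.bias = 0.0
        prob = nf.gami_predict(model, np.random.default_rng(0).random((5, 6))).prob
        assert np.allclose(prob, 0.5)
        model.bias = 10.0
        prob = nf.gami_predict(model, np.random.default_rng(0).random((5, 6))).prob
        assert np.all(prob > 0.999)

    def test_feature_count_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            nf.gami_predict(_random_model(), rng.random((4, 9)))


class TestInteractionScreening:
    def test_recovers_planted_pair_across_seeds(self):
        hits = 0
        for seed in range(5):
            X, y = _interaction_cohort(seed)
            cfg = nf.GAMIConfig(epochs=15, max_interactions=10, seed=seed)
            main_model = nf.fit_gami(X, y, cfg)
            pairs = nf.select_interactions(X, y, main_model, k=1)
            hits += pairs == [(1, 2)]
        assert hits >= 4

    def test_zero_budget_returns_empty(self):
        X, y = _interaction_cohort(0)
        model = nf.fit_gami(X, y, nf.GAMIConfig(epochs=3, max_interactions=0))
        assert nf.select_interactions(X, y, model, k=0) == []

    def test_bounded_by_candidate_count(self, rng):
        X = rng.random((60, 2))
        y = (X[:, 0] > 0.5).astype(int)
        model = nf.fit_gami(X, y, nf.GAMIConfig(epochs=3, max_interactions=0))
        assert len(nf.select_interactions(X, y, model, k=5)) <= 1


class TestFit:
    def test_informative_feature_ranks_first(self):
        """A single strongly shifted feature tops the importance ranking."""
        hits = 0
        for seed in range(5):
            c = nf.generate_cohort(n=400, n_features=10, behavioral_effect=2.0,
                                   n_informative_features=1, shape=(4, 4, 4),
                                   n_rois=8, seed=seed)
            X = nf.apply_preprocessor(
                nf.fit_preprocessor(c.behavioral), c.behavioral
            )
            model = nf.fit_gami(X, c.labels,
                                nf.GAMIConfig(max_interactions=2, seed=seed))
            top = nf.gami_importance(model, X)[0][0]
            hits += top == c.truth["informative_feature_names"][0]
        assert hits >= 4

    def test_training_loss_decreases(self):
        c = nf.generate_cohort(n=200, n_features=6, behavioral_effect=1.5,
                               n_informative_features=2, shape=(4, 4, 4),
                               n_rois=8, seed=5)
        X = nf.apply_preprocessor(nf.fit_preprocessor(c.behavioral), c.behavioral)
        model = nf.fit_gami(X, c.labels, nf.GAMIConfig(seed=5))
        assert model.history["stage1_bce"][-1] < model.history["stage1_bce"][0]

    def test_null_labels_leave_no_dominant_effect(self):
        """With y independent of X, no effect should dominate the ranking."""
        rng = np.random.default_rng(8)
        X = rng.random((300, 8))
        y = rng.integers(0, 2, 300)
        model = nf.fit_gami(X, y, nf.GAMIConfig(max_interactions=0, seed=8))
        ranking = nf.gami_importance(model, X)
        if ranking:
            scores = [s for _, s in ranking]
            assert max(scores) < 2 * min(scores) or max(scores) < 0.5
        # else: everything pruned, which is also acceptable null behavior

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            nf.fit_gami(rng.random((20, 3)), np.ones(20, dtype=int))

    def test_unscaled_features_rejected(self, rng):
        with pytest.raises(ValueError):
            nf.fit_gami(rng.normal(size=(20, 3)) * 10,
                        rng.integers(0, 2, 20))


class TestImportance:
    def test_single_active_effect_scores_one(self, rng):
        model = _random_model(6)
        model.main_active[:] = False
        model.main_active[1] = True
        model.inter_active[:] = False
        ranking = nf.gami_importance(model, rng.random((30, 6)))
        assert len(ranking) == 1
        assert ranking[0] == ("x1", 1.0)

    def test_scores_sum_to_one(self, rng):
        ranking = nf.gami_importance(_random_model(7), rng.random((50, 6)))
        assert abs(sum(s for _, s in ranking) - 1.0) < 1e-9

    def test_no_active_effects_empty(self, rng):
        model = _random_model(8)
        model.main_active[:] = False
        model.inter_active[:] = False
        assert nf.gami_importance(model, rng.random((10, 6))) == []


class TestPartialDependence:
    def test_pruned_feature_is_named_error(self):
        model = _random_model(9)
        model.main_active[4] = False
        with pytest.raises(ValueError, match="x4"):
            nf.gami_partial_dependence(model, 4, np.linspace(0, 1, 5))

    def test_grid_length_preserved(self):
        grid, curve = nf.gami_partial_dependence(
            _random_model(10), 0, np.linspace(0, 1, 50)
        )
        assert len(grid) == len(curve) == 50

    def test_zeroed_subnetwork_gives_flat_zero(self):
        model = _random_model(11)
        model.main["gamma"][3] = 0.0
        model.main_centers[3] = 0.0
        _, curve = nf.gami_partial_dependence(model, 3, np.linspace(0, 1, 9))
        assert np.allclose(curve, 0.0)

    def test_curve_consistent_with_effects_column(self, rng):
        """PDP values equal the contribution column where X hits grid points."""
        model = _random_model(12)
        grid = np.linspace(0, 1, 8)
        X = rng.random((8, 6))
        X[:, 2] = grid
        effects = nf.gami_effects(model, X)
        _, curve = nf.gami_partial_dependence(model, 2, grid)
        assert np.abs(effects["x2"].to_numpy() - curve).max() < 1e-6


def test_model_archive_roundtrip(tmp_path, rng):
    model = _random_model(13)
    path = tmp_path / "gami.npz"
    model.save(path)
    back = GAMIModel.load(path)
    X = rng.random((20, 6))
    assert np.array_equal(nf.gami_predict(model, X).prob,
                          nf.gami_predict(back, X).prob)
    assert back.pairs == model.pairs
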