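import numpy as np
import pytest

from fvtlda.config import AnnConfig
from fvtlda.models import (
    AnnModel,
    MlrModel,
    _mse,
    fit_ann,
    fit_mlr,
    hidden_activation,
    predict_ann,
    predict_mlr,
)


class TestMlr:
    def test_exactly_determined_system_interpolates(self):
        model = fit_mlr(np.array([[0.0], [1.0]]), np.array([1.0, 3.0]))
        assert np.allclose(model.weights, [1.0, 2.0])
        assert predict_mlr(model, np.array([0.0])) == pytest.approx(1.0)

    def test_normal_equation_hand_solve(self):
        # x = 1,2,3; y = 1,2,2 -> intercept 2/3, slope 1/2
        model = fit_mlr(np.array([[1.0], [2.0], [3.0]]), np.array([1.0, 2.0, 2.0]))
        assert np.allclose(model.weights, [2 / 3, 0.5])

    def test_duplicated_column_keeps_predictions_finite_and_unchanged(self, rng):
        x = rng.random((20, 3))
        y = rng.random(20)
        base = predict_mlr(fit_mlr(x, y), x)
        dup = fit_mlr(np.hstack([x, x[:, :1]]), y)
        assert np.isfinite(dup.weights).all()
        assert np.allclose(predict_mlr(dup, np.hstack([x, x[:, :1]])), base, atol=1e-8)

    def test_zero_weights_predict_zero(self):
        model = MlrModel(np.zeros(4))
        assert predict_mlr(model, np.ones(3)) == 0.0

    def test_hand_scoring(self):
        assert predict_mlr(MlrModel(np.array([1.0, 2.0])), np.array([3.0])) == 7.0

    def test_dimension_mismatch_errors(self):
        with pytest.raises(ValueError):
            predict_mlr(MlrModel(np.array([1.0, 2.0])), np.ones(5))

    def test_no_samples_errors(self):
        with pytest.raises(ValueError):
            fit_mlr(np.empty((0, 3)), np.empty(0))

    def test_residuals_orthogonal_to_design(self, rng):
        x = rng.random((50, 4))
        y = rng.random(50)
        model = fit_mlr(x, y)
        residuals = y - predict_mlr(model, x)
        design = np.hstack([np.ones((50, 1)), x])
        assert np.abs(design.T @ residuals).max() < 1e-8

    def test_parameter_recovery_improves_with_sample_size(self, rng):
        beta = rng.normal(size=6)
        intercept = 0.7
        rmses = []
        for n in (50, 500, 5000):
            x = rng.normal(size=(n, 6))
            y = intercept + x @ beta + rng.normal(scale=0.5, size=n)
            w = fit_mlr(x, y).weights
            rmses.append(np.sqrt(np.mean((w[1:] - beta) ** 2)))
        assert rmses[0] > rmses[1] > rmses[2]

    def test_save_load_round_trip(self, tmp_path):
        model = fit_mlr(np.array([[0.0], [1.0]]), np.array([1.0, 3.0]))
        model.save(tmp_path / "m.json")
        assert np.allclose(MlrModel.load(tmp_path / "m.json").weights, model.weights)


class TestHiddenActivation:
    def test_zero_maps_to_zero(self):
        assert hidden_activation(0.0) == 0.0

    def test_hand_value_at_one(self):
        assert hidden_activation(1.0) == pytest.approx(0.76159, abs=1e-5)

    def test_odd_function(self, rng):
        x = rng.normal(size=20)
        assert np.allclose(hidden_activation(-x), -hidden_activation(x))


class TestAnn:
    def make_data(self, rng, n=60, d=3):
        x = rng.normal(size=(n, d))
        y = 0.4 * np.tanh(x[:, 0]) + 0.1 * x[:, 1] + 0.5
        return x, y

    def test_mse_formula(self):
        assert _mse(np.array([1.0, 0.0]), np.array([0.0, 0.0])) == 0.5

    def test_constant_targets_learned(self, rng):
        x = rng.normal(size=(40, 2))
        model = fit_ann(x, np.full(40, 0.5), seed=0)
        assert np.allclose(predict_ann(model, x), 0.5, atol=0.05)

    def test_seeded_training_is_bit_reproducible(self, rng):
        x, y = self.make_data(rng)
        a = fit_ann(x, y, seed=7)
        b = fit_ann(x, y, seed=7)
        assert (a.weights_in == b.weights_in).all()
        assert (a.weights_out == b.weights_out).all()
        assert a.bias_out == b.bias_out

    def test_different_seeds_differ(self, rng):
        x, y = self.make_data(rng)
        a = fit_ann(x, y, seed=1)
        b = fit_ann(x, y, seed=2)
        assert not np.allclose(a.weights_in, b.weights_in)

    def test_learns_smooth_function(self, rng):
        x, y = self.make_data(rng, n=200)
        model = fit_ann(x, y, seed=0)
        preds = predict_ann(model, x)
        assert _mse(preds, y) < 0.25 * y.var()

    def test_validation_spread_across_seeds(self, rng):
        # mirrors the repeated-training protocol: different splits/inits give
        # a nonzero spread of validation MSE
        x, y = self.make_data(rng, n=80)
        vals = [fit_ann(x, y, seed=s).history["best_val_mse"] for s in range(5)]
        assert np.std(vals) > 0

    def test_too_few_samples_error(self):
        with pytest.raises(ValueError, match="at least 5"):
            fit_ann(np.ones((3, 2)), np.ones(3))

    def test_zero_network_outputs_zero(self):
        model = AnnModel(np.zeros((4, 2)), np.zeros(2), np.zeros(2), 0.0)
        assert predict_ann(model, np.ones(4)) == 0.0

    def test_dead_hidden_layer_passes_output_bias(self):
        model = AnnModel(np.zeros((3, 1)), np.zeros(1), np.ones(1), 0.3)
        assert predict_ann(model, np.array([5.0, -2.0, 1.0])) == pytest.approx(0.3)

    def test_output_finite_for_any_finite_input(self, rng):
        model = AnnModel(
            rng.normal(size=(3, 4)), rng.normal(size=4), rng.normal(size=4), 0.1
        )
        assert np.isfinite(predict_ann(model, np.array([1e6, -1e6, 0.0])))

    def test_dimension_mismatch_errors(self):
        model = AnnModel(np.zeros((3, 2)), np.zeros(2), np.zeros(2), 0.0)
        with pytest.raises(ValueError):
            predict_ann(model, np.ones(5))

    def test_split_sizes_respect_ratio(self, rng):
        x, y = self.make_data(rng, n=100)
        model = fit_ann(x, y, cfg=AnnConfig(), seed=0)
        tr, va, te = model.history["split_sizes"]
        assert tr + va + te == 100
        assert tr == 60 and va == 20 and te == 20

    def test_save_load_round_trip(self, tmp_path, rng):
        x, y = self.make_data(rng)
        model = fit_ann(x, y, seed=3)
        model.save(tmp_path / "ann.json")
        loaded = AnnModel.load(tmp_path / "ann.json")
        assert np.allclose(predict_ann(loaded, x), predict_ann(model, x))
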