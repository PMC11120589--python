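"""MLP response models: normalization, forward pass, training against closed forms."""

import warnings

import numpy as np
import pytest

from osmodry.ann import (
    MLPModel,
    TrainConfig,
    minmax_denormalize,
    minmax_normalize,
    split_sizes,
    topology_search,
    train_response,
)
from osmodry.ann import _sos_loss_grad
from osmodry.synthetic_bbd import SurfaceSpec, bbd_design, simulate_responses


def identity_model(**overrides):
    fields = dict(
        W1=np.array([[1.0, 0.0, 0.0]]), b1=np.array([0.0]),
        w2=np.array([2.0]), b2=1.0,
        f_hidden="identity", f_output="identity",
        x_bounds=(np.zeros(3), np.ones(3)), y_bounds=(0.0, 1.0),
    )
    fields.update(overrides)
    return MLPModel(**fields)


class TestMinMaxNormalization:
    def test_maps_training_levels_to_unit_interval(self):
        bounds = (np.array([20.0]), np.array([60.0]))
        out = minmax_normalize(np.array([[20.0], [40.0], [60.0]]), bounds,
                               warn_outside=False)
        assert out.ravel() == pytest.approx([0.0, 0.5, 1.0])

    def test_round_trip_is_identity(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(-5, 5, size=(10, 3))
        bounds = (x.min(axis=0), x.max(axis=0))
        back = minmax_denormalize(minmax_normalize(x, bounds), bounds)
        np.testing.assert_allclose(back, x, atol=1e-12)

    def test_values_outside_bounds_warn_and_map_outside(self):
        bounds = (np.array([0.0]), np.array([1.0]))
        with pytest.warns(UserWarning, match="outside"):
            out = minmax_normalize(np.array([[2.0]]), bounds)
        assert out.ravel()[0] == pytest.approx(2.0)

    def test_degenerate_bounds_rejected(self):
        with pytest.raises(ValueError, match="max <= min"):
            minmax_normalize(np.array([[1.0]]), (np.array([3.0]), np.array([3.0])))


class TestForwardPass:
    def test_identity_network_hand_example(self):
        model = identity_model()
        out = model.forward_normalized(np.array([[0.5, 0.0, 0.0]]))
        assert out[0] == pytest.approx(2.0)  # 2 * 0.5 + 1

    def test_zero_network_logistic_output(self):
        model = identity_model(W1=np.zeros((1, 3)), w2=np.zeros(1), b2=0.0,
                               f_output="logistic")
        out = model.forward_normalized(np.zeros((1, 3)))
        assert out[0] == pytest.approx(0.5)

    def test_tanh_hidden_zero_input_passes_output_bias(self):
        model = identity_model(f_hidden="tanh", b2=0.7)
        out = model.forward_normalized(np.zeros((1, 3)))
        assert out[0] == pytest.approx(0.7)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="inputs"):
            identity_model().forward_normalized(np.zeros((1, 2)))

    def test_json_round_trip(self):
        model = identity_model(f_hidden="tanh", response="DMC")
        clone = MLPModel.from_dict(model.to_dict())
        x = np.array([[0.2, 0.4, 0.9]])
        np.testing.assert_allclose(clone.forward_normalized(x),
                                   model.forward_normalized(x))

    def test_analytic_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(7)
        Xn = rng.uniform(0, 1, size=(6, 3))
        yn = rng.uniform(0, 1, size=6)
        theta = rng.normal(0, 0.5, size=3 * 3 + 2 * 3 + 1)
        _, grad = _sos_loss_grad(theta, Xn, yn, 3, "tanh", "logistic")
        eps = 1e-6
        for k in range(len(theta)):
            step = np.zeros_like(theta)
            step[k] = eps
            up, _ = _sos_loss_grad(theta + step, Xn, yn, 3, "tanh", "logistic")
            down, _ = _sos_loss_grad(theta - step, Xn, yn, 3, "tanh", "logistic")
            assert grad[k] == pytest.approx((up - down) / (2 * eps), abs=1e-5, rel=1e-4)


class TestSplitting:
    @pytest.mark.parametrize(
        "n, fractions, expected",
        [
            (15, (0.6, 0.2, 0.2), (9, 3, 3)),
            (15, (0.8, 0.1, 0.1), (12, 2, 1)),
            (10, (0.6, 0.2, 0.2), (6, 2, 2)),
        ],
    )
    def test_split_sizes(self, n, fractions, expected):
        assert split_sizes(n, fractions) == expected

    def test_config_validation(self):
        with pytest.raises(ValueError, match="sum to 1"):
            TrainConfig(split=(0.5, 0.2, 0.2))
        with pytest.raises(ValueError, match="restarts"):
            TrainConfig(restarts=0)
        with pytest.raises(ValueError, match="activation"):
            TrainConfig(f_hidden="relu")


def linear_table(seed=0, noise=0.0):
    design = bbd_design()
    spec = SurfaceSpec("y", 50.0, (8.0, 3.0, 12.0), noise_sd=noise)
    return simulate_responses(design, [spec], seed=seed)


class TestTraining:
    def test_identity_h1_matches_least_squares(self, table1):
        """A linear network's SOS optimum is the OLS fit on the same split."""
        cfg = TrainConfig(hidden_range=(1,), restarts=10, max_iter=500, seed=3,
                          f_hidden="identity", f_output="identity")
        result = train_response(table1, "DMC", cfg)
        X = table1.factors().to_numpy()
        y = table1.responses()["DMC"].to_numpy()
        rows = [table1.run_ids.index(r) for r in result.split_indices["train"]]
        beta, *_ = np.linalg.lstsq(np.c_[np.ones(len(rows)), X[rows]], y[rows], rcond=None)
        ols = np.c_[np.ones(len(X)), X] @ beta
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # rows beyond the training bounds
            predictions = result.model.predict(X)
        np.testing.assert_allclose(predictions, ols, atol=1e-6)

    def test_noise_free_linear_surface_fits_exactly(self):
        table = linear_table()
        cfg = TrainConfig(hidden_range=(1,), restarts=5, max_iter=500, seed=1,
                          f_hidden="identity", f_output="identity")
        result = train_response(table, "y", cfg)
        assert result.r2["train"] >= 0.999

    def test_quadratic_surface_needs_more_than_one_hidden_unit(self):
        """A pure parabola in one factor is monotone-inapproximable with H=1 tanh."""
        design = bbd_design()
        spec = SurfaceSpec("y", 10.0, (0.0, 0.0, 0.0), quadratic=(8.0, 0.0, 0.0))
        table = simulate_responses(design, [spec], seed=0)
        cfg = TrainConfig(hidden_range=(1, 2, 3), restarts=20, max_iter=300, seed=2)
        result = train_response(table, "y", cfg)
        assert result.hidden_units >= 2
        assert result.r2["train"] >= 0.99

    def test_affine_input_rescaling_leaves_predictions_unchanged(self):
        """Min-max normalization absorbs affine maps of the factors."""
        table = linear_table(noise=1.0)
        rescaled_frame = table.data
        rescaled_frame["T"] = 2.0 * rescaled_frame["T"] + 10.0
        from osmodry.dataset import DesignTable

        rescaled = DesignTable(rescaled_frame)
        cfg = TrainConfig(hidden_range=(3,), restarts=3, max_iter=200, seed=4)
        first = train_response(table, "y", cfg)
        second = train_response(rescaled, "y", cfg)
        X = table.factors().to_numpy()
        X2 = rescaled.factors().to_numpy()
        np.testing.assert_allclose(second.model.predict(X2), first.model.predict(X),
                                   atol=1e-8)

    def test_recovers_generating_surface_as_noise_vanishes(self):
        design = bbd_design()
        spec = SurfaceSpec("y", 30.0, (5.0, 2.0, 8.0), quadratic=(-1.0, 0.5, 1.5),
                           interaction=(0.5, 1.0, 0.0))
        table = simulate_responses(design, [spec], seed=6)
        cfg = TrainConfig(hidden_range=(3, 4, 5), restarts=20, max_iter=300, seed=6)
        result = train_response(table, "y", cfg)
        truth = table.responses()["y"].to_numpy()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rmse = np.sqrt(np.mean((result.model.predict(table.factors().to_numpy())
                                    - truth) ** 2))
        span = truth.max() - truth.min()
        assert rmse < 0.05 * span

    def test_unknown_response_rejected(self, table1):
        with pytest.raises(KeyError, match="nope"):
            train_response(table1, "nope", TrainConfig())


class TestTopologySearch:
    def test_empty_response_list_gives_empty_result(self, table1):
        assert topology_search(table1, [], TrainConfig()) == []

    def test_one_result_per_response_with_searched_width(self, table1):
        cfg = TrainConfig(hidden_range=(2, 3), restarts=2, max_iter=100, seed=0)
        results = topology_search(table1, ["DMC", "WL"], cfg)
        assert [r.response for r in results] == ["DMC", "WL"]
        for result in results:
            assert result.hidden_units in (2, 3)
            assert result.name == f"MLP 3-{result.hidden_units}-1"
            assert all(v <= 1.0 + 1e-12 for v in result.r2.values() if not np.isnan(v))
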