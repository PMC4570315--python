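"""ANN engine: activations, gradients, trainers, scaling."""

import numpy as np
import pytest

from vinotaste.neuralnet import (
    ACTIVATION_KINDS,
    ALGORITHMS,
    AnnConfig,
    AnnModel,
    RPROP_DELTA_MAX,
    RPROP_DELTA_MIN,
    TrainingDivergedError,
    activation,
    activation_derivative,
    fit_regressor,
    forward,
    gradients,
    init_model,
    predict,
    train,
    scale_targets,
    unscale_outputs,
)

XOR_X = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=float)
XOR_Y = np.array([0, 1, 1, 0], dtype=float)


def total_loss(model, X, t):
    from vinotaste.neuralnet import _forward_pass

    _, acts = _forward_pass(model, np.atleast_2d(X))
    return 0.5 * np.sum((acts[-1][:, 0] - np.asarray(t)) ** 2)


def finite_diff_check(model, X, t, n_checks=40, seed=0, eps=1e-6):
    """Max |analytic - central-difference| over a random parameter subset."""
    dW, db = gradients(model, X, t)
    rng = np.random.default_rng(seed)
    worst = 0.0
    for arr, g in zip(model.weights + model.biases, dW + db):
        flat_idx = rng.choice(arr.size, size=min(n_checks, arr.size), replace=False)
        for fi in flat_idx:
            ix = np.unravel_index(fi, arr.shape)
            old = arr[ix]
            arr[ix] = old + eps
            lp = total_loss(model, X, t)
            arr[ix] = old - eps
            lm = total_loss(model, X, t)
            arr[ix] = old
            worst = max(worst, abs((lp - lm) / (2 * eps) - g[ix]))
    return worst


class TestActivations:
    def test_reference_values(self):
        assert activation("sigmoid", 0.0) == pytest.approx(0.5)
        assert activation("gaussian", 0.0) == pytest.approx(1.0)
        assert activation("linear", 2.5) == pytest.approx(2.5)
        assert activation("sin", np.pi / 2) == pytest.approx(1.0)
        assert activation("cos", 0.0) == pytest.approx(1.0)

    @pytest.mark.parametrize("kind", ACTIVATION_KINDS)
    def test_derivative_matches_finite_difference(self, kind):
        rng = np.random.default_rng(1)
        for x in rng.uniform(-3, 3, 20):
            num = (activation(kind, x + 1e-6) - activation(kind, x - 1e-6)) / 2e-6
            assert activation_derivative(kind, x) == pytest.approx(num, abs=1e-6)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            activation("relu", 0.0)


class TestForward:
    def test_zero_weights_linear_output(self):
        cfg = AnnConfig(output_activation="linear", hidden1_activation="linear")
        m = init_model(cfg, n_inputs=4)
        for w in m.weights:
            w[:] = 0.0
        for b in m.biases:
            b[:] = 0.0
        m.y_min, m.y_max = 10.0, 30.0
        raw = forward(m, np.zeros(4))
        assert raw == 0.0
        assert predict(m, np.zeros(4)) == pytest.approx(
            float(unscale_outputs(m, np.array([0.0]))[0])
        )

    def test_single_linear_layer_is_matrix_product(self):
        rng = np.random.default_rng(3)
        W = rng.normal(size=(1, 5))
        b = rng.normal(size=1)
        m = AnnModel(
            sizes=[5, 1], weights=[W], biases=[b], activations=["linear"]
        )
        x = rng.normal(size=5)
        assert forward(m, x) == pytest.approx(float((W @ x + b)[0]), abs=1e-12)

    def test_sigmoid_outputs_bounded(self):
        cfg = AnnConfig(output_activation="sigmoid", seed=2)
        m = init_model(cfg, n_inputs=24)
        X = np.random.default_rng(0).normal(scale=10, size=(100_000, 24))
        raw = forward(m, X)
        assert np.all((raw > 0) & (raw < 1))

    def test_non_finite_input_rejected(self):
        m = init_model(AnnConfig(), n_inputs=3)
        with pytest.raises(ValueError):
            forward(m, np.array([1.0, np.nan, 0.0]))


class TestGradients:
    @pytest.mark.parametrize("h1_act", ACTIVATION_KINDS)
    @pytest.mark.parametrize("h2_act", ACTIVATION_KINDS)
    @pytest.mark.parametrize("out_act", ACTIVATION_KINDS)
    def test_gradient_all_activation_combinations(self, h1_act, h2_act, out_act):
        cfg = AnnConfig(
            hidden1_size=9,
            hidden1_activation=h1_act,
            hidden2_size=11,
            hidden2_activation=h2_act,
            output_activation=out_act,
            seed=7,
        )
        m = init_model(cfg, n_inputs=24)
        rng = np.random.default_rng(4)
        X = rng.normal(size=(3, 24))
        t = rng.uniform(-0.5, 0.5, 3)
        assert finite_diff_check(m, X, t, n_checks=8) < 1e-5

    @pytest.mark.parametrize("h1", (9, 11, 13))
    @pytest.mark.parametrize("h2", (0, 9, 11, 13))
    def test_gradient_all_architectures(self, h1, h2):
        cfg = AnnConfig(
            hidden1_size=h1, hidden2_size=h2, output_activation="sin", seed=5
        )
        m = init_model(cfg, n_inputs=24)
        rng = np.random.default_rng(8)
        X = rng.normal(size=(4, 24))
        t = rng.uniform(-0.5, 0.5, 4)
        assert finite_diff_check(m, X, t, n_checks=10) < 1e-5

    def test_batch_gradient_equals_sum_of_per_sample(self):
        cfg = AnnConfig(hidden2_size=11, seed=1)
        m = init_model(cfg, n_inputs=24)
        rng = np.random.default_rng(2)
        X = rng.normal(size=(4, 24))
        t = rng.uniform(0.1, 0.9, 4)
        dW_batch, db_batch = gradients(m, X, t)
        dW_sum = [np.zeros_like(w) for w in m.weights]
        db_sum = [np.zeros_like(b) for b in m.biases]
        for i in range(4):
            dW_i, db_i = gradients(m, X[i : i + 1], t[i : i + 1])
            for acc, g in zip(dW_sum + db_sum, dW_i + db_i):
                acc += g
        for a, b in zip(dW_batch + db_batch, dW_sum + db_sum):
            np.testing.assert_allclose(a, b, atol=1e-10)


class TestTrainers:
    @pytest.mark.parametrize("algorithm", ALGORITHMS)
    def test_xor_converges_for_most_seeds(self, algorithm):
        wins = 0
        for seed in range(10):
            cfg = AnnConfig(
                algorithm=algorithm,
                learning_rate=0.9,
                hidden1_size=4,
                output_activation="sigmoid",
                max_epochs=5000,
                seed=seed,
            )
            model, _ = fit_regressor(XOR_X, XOR_Y, cfg)
            mse = float(np.mean((predict(model, XOR_X) - XOR_Y) ** 2))
            wins += mse < 0.01
        assert wins >= 8

    def test_rprop_steps_bounded_and_weights_finite(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, 6))
        y = rng.uniform(0.1, 0.9, 20)
        cfg = AnnConfig(algorithm="rprop", hidden1_size=5, max_epochs=200, seed=3)
        m = init_model(cfg, n_inputs=6)
        m, trace = train(m, X, y, cfg)
        assert all(np.all(np.isfinite(w)) for w in m.weights + m.biases)
        assert RPROP_DELTA_MIN <= RPROP_DELTA_MAX  # engine constants sane
        assert len(trace["train_mse"]) == 200

    def test_linear_map_recovered_by_linear_net(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(60, 24))
        beta = rng.normal(size=24)
        y = X @ beta + 1.5
        cfg = AnnConfig(
            algorithm="rprop",
            hidden1_size=9,
            hidden1_activation="linear",
            output_activation="linear",
            max_epochs=1500,
            seed=0,
        )
        model, _ = fit_regressor(X, y, cfg)
        pred = predict(model, X)
        ss_res = np.sum((y - pred) ** 2)
        ss_tot = np.sum((y - y.mean()) ** 2)
        assert 1 - ss_res / ss_tot > 0.999

    def test_divergence_aborts_with_diagnostic(self):
        rng = np.random.default_rng(0)
        X = rng.normal(scale=100, size=(10, 4))
        y = rng.uniform(-0.9, 0.9, 10)
        cfg = AnnConfig(
            algorithm="batch",
            learning_rate=0.9,  # summed-gradient updates on wild inputs blow up
            hidden1_size=4,
            hidden1_activation="linear",
            output_activation="linear",
            max_epochs=500,
            seed=1,
        )
        m = init_model(cfg, n_inputs=4)
        with pytest.raises(TrainingDivergedError):
            train(m, X, y, cfg)

    def test_training_is_deterministic_given_seed(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(12, 5))
        y = rng.uniform(0, 1, 12)
        cfg = AnnConfig(algorithm="incremental", hidden1_size=4, max_epochs=50, seed=9)
        m1, t1 = fit_regressor(X, y, cfg)
        m2, t2 = fit_regressor(X, y, cfg)
        assert t1["train_mse"] == t2["train_mse"]
        for a, b in zip(m1.weights, m2.weights):
            np.testing.assert_array_equal(a, b)

    def test_early_stopping_restores_best_weights(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(30, 6))
        y = rng.uniform(0.1, 0.9, 30)
        Xv = rng.normal(size=(10, 6))
        yv = rng.uniform(0.1, 0.9, 10)
        cfg = AnnConfig(
            algorithm="incremental", hidden1_size=8, max_epochs=400,
            patience=20, seed=2,
        )
        m = init_model(cfg, n_inputs=6)
        m, trace = train(m, X, y, cfg, validation=(Xv, yv))
        assert len(trace["val_mse"]) < 400  # patience fired
        from vinotaste.neuralnet import _mse

        assert _mse(m, Xv, yv) == pytest.approx(min(trace["val_mse"]), abs=1e-12)


class TestScaling:
    def test_target_scaling_round_trip(self):
        m = init_model(AnnConfig(output_activation="sin"), n_inputs=2)
        m.y_min, m.y_max = 36.0, 478.0
        y = np.array([36.0, 100.0, 478.0])
        back = unscale_outputs(m, scale_targets(m, y))
        np.testing.assert_allclose(back, y, atol=1e-10)

    def test_scaled_targets_inside_guard_band(self):
        m = init_model(AnnConfig(output_activation="sigmoid"), n_inputs=2)
        m.y_min, m.y_max = 0.0, 10.0
        ys = scale_targets(m, np.array([0.0, 10.0]))
        assert ys.min() == pytest.approx(0.1)
        assert ys.max() == pytest.approx(0.9)

    def test_model_dict_round_trip(self):
        cfg = AnnConfig(hidden2_size=9, output_activation="cos", seed=4)
        rng = np.random.default_rng(1)
        X = rng.normal(size=(10, 6))
        y = rng.uniform(0, 5, 10)
        m, _ = fit_regressor(X, y, AnnConfig(
            algorithm="rprop", hidden1_size=4, max_epochs=30, seed=4
        ))
        back = AnnModel.from_dict(m.to_dict())
        np.testing.assert_allclose(predict(back, X), predict(m, X), atol=1e-12)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            AnnConfig(algorithm="adam")
        with pytest.raises(ValueError):
            AnnConfig(learning_rate=0.0)
        with pytest.raises(ValueError):
            AnnConfig(hidden1_activation="tanh")
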