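"""MLP surrogate: normalization, forward pass, gradients, the momentum +
adaptive-rate trainer, model selection and evaluation metrics."""

import numpy as np
import pytest

from gbopt.surrogate import (
    MLPModel,
    NormalizationParams,
    TrainConfig,
    _mse_and_grads,
    evaluate,
    init_weights,
    minmax_fit,
    mlp_forward,
    select_hidden_size,
    train_gdx,
    train_test_split,
)


class TestMinMax:
    def test_endpoints_and_midpoint(self):
        col = np.array([40.0, 55.0, 70.0, 85.0, 100.0])[:, None]
        norm = minmax_fit(col)
        scaled = norm.apply(col)[:, 0]
        assert scaled[0] == -1.0 and scaled[-1] == 1.0
        assert abs(norm.apply(np.array([[70.0]]))[0, 0]) < 1e-12  # midpoint -> 0

    def test_roundtrip_identity(self, ref_data):
        design, _ = ref_data
        X = design.values
        norm = minmax_fit(X)
        assert np.abs(norm.invert(norm.apply(X)) - X).max() < 1e-12

    def test_constant_column_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            minmax_fit(np.array([[1.0, 2.0], [1.0, 3.0]]))


class TestForwardPass:
    def test_zero_weights_return_output_bias(self):
        W1 = np.zeros((3, 4))
        out = mlp_forward(W1, np.zeros(3), np.zeros(3), 0.3, np.ones((5, 4)))
        assert np.allclose(out, 0.3)

    def test_single_unit_closed_form(self):
        W1 = np.array([[1.0, 0.0, 0.0, 0.0]])
        out = mlp_forward(W1, np.zeros(1), np.array([2.0]), 0.0, np.array([[1, 0, 0, 0.0]]))
        assert abs(out[0] - 2 * np.tanh(1.0)) < 1e-12  # = 1.52318...

    def test_zero_input_ignores_w1(self, rng):
        W1 = rng.normal(size=(4, 4))
        out = mlp_forward(W1, np.zeros(4), rng.normal(size=4), 1.7, np.zeros((1, 4)))
        assert abs(out[0] - 1.7) < 1e-12

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            mlp_forward(np.zeros((2, 3)), np.zeros(2), np.zeros(2), 0.0, np.ones((1, 4)))


class TestGradients:
    def test_backprop_matches_central_differences(self, rng):
        """Analytic gradients vs finite differences, rel. error < 1e-6."""
        for _ in range(5):
            n, h, d = 7, 3, 4
            Xn = rng.uniform(-1, 1, size=(n, d))
            yn = rng.uniform(-1, 1, size=n)
            W1, b1, W2, b2 = init_weights(h, d, rng)
            _, (gW1, gb1, gW2, gb2) = _mse_and_grads(W1, b1, W2, b2, Xn, yn)
            eps = 1e-6

            def mse(W1=W1, b1=b1, W2=W2, b2=b2):
                return _mse_and_grads(W1, b1, W2, b2, Xn, yn)[0]

            for arr, grad in ((W1, gW1), (b1, gb1), (W2, gW2)):
                it = np.nditer(arr, flags=["multi_index"])
                for _v in it:
                    i = it.multi_index
                    orig = arr[i]
                    arr[i] = orig + eps
                    up = mse()
                    arr[i] = orig - eps
                    dn = mse()
                    arr[i] = orig
                    fd = (up - dn) / (2 * eps)
                    assert abs(grad[i] - fd) < 1e-6 * max(1.0, abs(fd))
            fd = (mse(b2=b2 + eps) - mse(b2=b2 - eps)) / (2 * eps)
            assert abs(gb2 - fd) < 1e-6 * max(1.0, abs(fd))


class TestTrainer:
    def _linear_data(self, n=20, seed=3):
        rng = np.random.default_rng(seed)
        X = rng.uniform(-2, 2, size=(n, 4))
        return X, X[:, 0].copy()

    def test_reaches_goal_on_noiseless_linear_target(self):
        X, y = self._linear_data()
        model, report = train_gdx(X, y, 4, TrainConfig(seed=1))
        assert report.train_mse <= 1e-4
        assert report.epochs_run <= 2000

    def test_seeded_determinism_bit_identical(self, ref_data):
        design, y = ref_data
        cfg = TrainConfig(max_epochs=200, seed=99)
        m1, r1 = train_gdx(design.values, y, 5, cfg)
        m2, r2 = train_gdx(design.values, y, 5, cfg)
        assert np.array_equal(m1.W1, m2.W1) and np.array_equal(m1.W2, m2.W2)
        assert r1.mse_history == r2.mse_history

    def test_accepted_mse_never_exceeds_rejection_threshold(self, ref_data):
        design, y = ref_data
        cfg = TrainConfig(max_epochs=500, seed=7)
        _, report = train_gdx(design.values, y, 8, cfg)
        h = report.mse_history
        assert all(h[i + 1] <= cfg.max_perf_inc * h[i] + 1e-15 for i in range(len(h) - 1))
        assert h[-1] <= h[0]

    def test_normalization_invariance_of_trajectory(self):
        """Affinely rescaling raw inputs leaves the normalized training
        trajectory identical for the same seed."""
        X, y = self._linear_data()
        cfg = TrainConfig(max_epochs=300, seed=11)
        _, r1 = train_gdx(X, y, 3, cfg)
        _, r2 = train_gdx(X * 37.0 + 5.0, y, 3, cfg)
        np.testing.assert_allclose(r1.mse_history, r2.mse_history, rtol=1e-9)

    def test_uniform_init_scheme_available(self):
        X, y = self._linear_data()
        cfg = TrainConfig(max_epochs=50, seed=1, init="uniform")
        model, report = train_gdx(X, y, 3, cfg)
        assert np.all(np.isfinite(model.W1)) and report.train_mse < report.mse_history[0]
        with pytest.raises(ValueError):
            TrainConfig(init="xavier")

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            train_gdx(np.ones((1, 4)), np.ones(1), 4)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            TrainConfig(rate_down=1.5)
        with pytest.raises(ValueError):
            TrainConfig(momentum=1.0)
        with pytest.raises(ValueError):
            TrainConfig(max_perf_inc=0.9)

    def test_model_json_roundtrip(self, tmp_path, ref_data):
        design, y = ref_data
        model, _ = train_gdx(design.values, y, 4, TrainConfig(max_epochs=50, seed=2))
        path = tmp_path / "model.json"
        model.save(path)
        loaded = MLPModel.load(path)
        x = design.values[:5]
        np.testing.assert_allclose(loaded.predict(x), model.predict(x), atol=1e-12)


class TestEvaluate:
    def _identity_norm(self, width):
        return NormalizationParams(lo=np.full(width, -1.0), hi=np.full(width, 1.0))

    def _constant_model(self, c, n_in=4):
        # zero weights -> predicts b2 on the normalized scale; identity norms
        return MLPModel(
            W1=np.zeros((1, n_in)),
            b1=np.zeros(1),
            W2=np.zeros(1),
            b2=float(c),
            norm_x=self._identity_norm(n_in),
            norm_y=self._identity_norm(1),
        )

    def test_mean_prediction_gives_r2_zero(self, rng):
        y = rng.normal(size=10)
        model = self._constant_model(y.mean())
        report = evaluate(model, rng.normal(size=(10, 4)), y)
        assert abs(report.r2) < 1e-12

    def test_perfect_prediction_gives_r2_one(self):
        # constant models cannot predict varying truth exactly, so check the
        # R²→1 limit on a representable target fitted to convergence
        rng = np.random.default_rng(5)
        X = rng.uniform(-1, 1, size=(30, 4))
        y = X[:, 0].copy()
        model, _ = train_gdx(X, y, 4, TrainConfig(seed=4, goal_mse=1e-9, max_epochs=5000))
        report = evaluate(model, X, y)
        assert report.r2 > 0.999
        assert report.r2_pearson >= report.r2 - 1e-9

    def test_zero_variance_truth_rejected(self):
        model = self._constant_model(0.0)
        with pytest.raises(ValueError, match="zero-variance"):
            evaluate(model, np.zeros((4, 4)), np.ones(4))


class TestSplitAndSelection:
    def test_split_is_partition(self):
        tr, te = train_test_split(49, 6, seed=1)
        assert len(tr) == 43 and len(te) == 6
        assert sorted(np.concatenate([tr, te]).tolist()) == list(range(49))

    def test_single_candidate_returned(self, ref_data):
        design, y = ref_data
        cfg = TrainConfig(max_epochs=30)
        h, curve = select_hidden_size(design.values, y, candidates=(8,), seed=0, config=cfg)
        assert h == 8 and set(curve) == {8}

    def test_tie_tolerance_prefers_smaller_network(self):
        """Noiseless linear target: both H=1 and H=20 reach the goal, so the
        5% tie rule must pick the one-unit network."""
        rng = np.random.default_rng(8)
        X = rng.uniform(-1, 1, size=(40, 4))
        y = 0.5 * X[:, 0]
        h, curve = select_hidden_size(
            X, y, candidates=(1, 20), k_folds=4, seed=2, config=TrainConfig(seed=0)
        )
        assert h == 1

    def test_invalid_candidates_rejected(self, ref_data):
        design, y = ref_data
        with pytest.raises(ValueError):
            select_hidden_size(design.values, y, candidates=())
        with pytest.raises(ValueError):
            select_hidden_size(design.values, y, candidates=(0, 3))
        with pytest.raises(ValueError):
            select_hidden_size(design.values, y, candidates=(3,), k_folds=1)
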