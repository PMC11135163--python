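"""Forward math, Bayesian-regularized training and serialization."""

import io
import warnings

import numpy as np
import pytest

import desvisc as dv
from desvisc.errors import ConvergenceWarning, ExtrapolationWarning, SchemaError
from desvisc.network import (
    _forward_scaled,
    _init_parameters,
    _jacobian,
    _pack,
    default_layer_grid,
    random_model,
)


def composed_forward_oracle(model, X):
    """Independent matrix-expression evaluation of the same network."""
    U = 2.0 * (X - model.input_min) / (model.input_max - model.input_min) - 1.0
    a = U
    for W, b in zip(model.weights[:-1], model.biases[:-1]):
        a = np.tanh(a @ W.T + b)
    y = a @ model.weights[-1].T + model.biases[-1]
    return (y[:, 0] + 1.0) / 2.0 * (
        model.output_max - model.output_min
    ) + model.output_min


class TestForward:
    def test_zero_network_predicts_output_midpoint(self):
        m = random_model((9, 4, 1), seed=0, output_range=(1.0, 3.0))
        m.weights = [np.zeros_like(W) for W in m.weights]
        m.biases = [np.zeros_like(b) for b in m.biases]
        x = np.zeros((5, 9))
        np.testing.assert_allclose(m.forward(x, warn_extrapolation=False), 2.0)

    def test_hand_built_tanh_network(self):
        # 2-1-1 net, identity scalers: y = tanh(u1 + u2)
        m = dv.AnnModel(
            layer_sizes=(2, 1, 1),
            weights=[np.array([[1.0, 1.0]]), np.array([[1.0]])],
            biases=[np.zeros(1), np.zeros(1)],
            input_min=np.array([-1.0, -1.0]),
            input_max=np.array([1.0, 1.0]),
            output_min=-1.0,
            output_max=1.0,
        )
        u = np.array([[0.3, -0.8], [0.5, 0.5], [0.0, 0.0]])
        np.testing.assert_allclose(
            m.forward(u, warn_extrapolation=False),
            np.tanh(u.sum(axis=1)),
            rtol=1e-15,
        )

    @pytest.mark.parametrize("seed", range(4))
    def test_forward_matches_composed_matrix_oracle(self, seed, rng):
        sizes = [(5, 3, 1), (9, 7, 4, 1), (2, 10, 1)][seed % 3]
        m = random_model(sizes, seed=seed, output_range=(-2.0, 5.0))
        X = rng.uniform(-1, 1, size=(40, sizes[0]))
        got = m.forward(X, warn_extrapolation=False)
        want = composed_forward_oracle(m, X)
        np.testing.assert_allclose(got, want, rtol=1e-12)

    def test_hidden_activations_bounded(self, rng):
        m = random_model((9, 6, 5, 1), seed=3, weight_scale=1.0)
        X = rng.uniform(-2, 2, size=(100, 9))  # beyond the scaler range
        for layer in m.hidden_activations(X):
            assert np.all(np.abs(layer) < 1.0)

    def test_scaling_roundtrip_identity(self, rng):
        m = random_model(
            (9, 3, 1), seed=1,
            input_min=rng.uniform(-5, 0, 9), input_max=rng.uniform(1, 5, 9),
        )
        X = rng.uniform(-4, 4, size=(20, 9))
        U = m.scale_inputs(X, warn=False)
        back = (U + 1.0) / 2.0 * (m.input_max - m.input_min) + m.input_min
        np.testing.assert_allclose(back, X, rtol=1e-12)

    def test_out_of_range_query_warns_not_raises(self):
        m = random_model((2, 3, 1), seed=0)
        with pytest.warns(ExtrapolationWarning):
            m.forward(np.array([[5.0, 0.0]]))

    def test_jacobian_matches_finite_differences(self, rng):
        sizes = (4, 5, 3, 1)
        weights, biases = _init_parameters(sizes, seed=8)
        w0 = _pack(weights, biases)
        U = rng.uniform(-1, 1, size=(7, 4))
        J, y = _jacobian(weights, biases, U)
        eps = 1e-6
        from desvisc.network import _unpack

        for j in rng.choice(w0.size, size=12, replace=False):
            wp, wm = w0.copy(), w0.copy()
            wp[j] += eps
            wm[j] -= eps
            yp = _forward_scaled(*_unpack(wp, sizes), U)
            ym = _forward_scaled(*_unpack(wm, sizes), U)
            fd = (yp - ym) / (2 * eps)
            np.testing.assert_allclose(J[:, j], fd, rtol=1e-5, atol=1e-8)


class TestTraining:
    def test_linear_target_fits_below_rmse_001(self, rng):
        X = rng.uniform(0, 1, size=(500, 9))
        coef = rng.uniform(-1, 1, 9)
        y = X @ coef + 0.3
        m = dv.train((X, y), (9, 5, 1), dv.TrainingConfig(seed=0, max_iterations=200))
        pred = m.forward(X, warn_extrapolation=False)
        assert np.sqrt(np.mean((pred - y) ** 2)) < 0.01

    def test_same_seed_gives_bit_identical_model(self, rng):
        X = rng.uniform(0, 1, size=(80, 3))
        y = np.sin(X.sum(axis=1))
        cfg = dv.TrainingConfig(seed=5, max_iterations=40)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            m1 = dv.train((X, y), (3, 4, 1), cfg)
            m2 = dv.train((X, y), (3, 4, 1), cfg)
        for W1, W2 in zip(m1.weights, m2.weights):
            np.testing.assert_array_equal(W1, W2)
        for b1, b2 in zip(m1.biases, m2.biases):
            np.testing.assert_array_equal(b1, b2)

    def test_training_reduces_rmse_from_initialization(self, rng):
        X = rng.uniform(0, 2, size=(200, 4))
        y = np.cos(X[:, 0]) + 0.5 * X[:, 1]
        sizes = (4, 6, 1)
        cfg = dv.TrainingConfig(seed=2, max_iterations=60)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            m = dv.train((X, y), sizes, cfg)
        # rebuild the untrained network with the same seed and scalers
        w0, b0 = _init_parameters(sizes, seed=2)
        init = dv.AnnModel(
            layer_sizes=sizes, weights=w0, biases=b0,
            input_min=m.input_min, input_max=m.input_max,
            output_min=m.output_min, output_max=m.output_max,
        )
        rmse = lambda mod: np.sqrt(
            np.mean((mod.forward(X, warn_extrapolation=False) - y) ** 2)
        )
        assert rmse(m) <= rmse(init)

    def test_fixed_l2_path_approaches_least_squares(self, rng):
        # linear network (no hidden layer): with alpha -> 0 the penalized
        # optimum must converge to the ordinary least-squares fit
        X = rng.uniform(-1, 1, size=(60, 3))
        y = X @ np.array([0.5, -1.0, 2.0]) + 0.1 * rng.normal(size=60)
        # closed-form OLS in the scaled space, mapped back to predictions
        dists = []
        for alpha in (1.0, 1e-3, 1e-8):
            cfg = dv.TrainingConfig(
                algorithm="l2", alpha=alpha, seed=0, max_iterations=100
            )
            m = dv.train((X, y), (3, 1), cfg)
            U = m.scale_inputs(X, warn=False)
            A = np.hstack([U, np.ones((len(U), 1))])
            t = m.scale_output(y)
            wls = np.linalg.lstsq(A, t, rcond=None)[0]
            ols_pred = m.unscale_output(A @ wls)
            pred = m.forward(X, warn_extrapolation=False)
            dists.append(np.max(np.abs(pred - ols_pred)))
        assert dists[2] < 1e-6
        assert dists[2] <= dists[1] <= dists[0] + 1e-12

    def test_teacher_network_recovered_within_noise_floor(self, rng):
        sigma = 0.01
        teacher = random_model(
            (9, 3, 1), seed=4,
            input_min=np.zeros(9), input_max=np.ones(9),
            output_range=(0.0, 3.0), weight_scale=2.0,
        )
        X = rng.uniform(0, 1, size=(700, 9))
        y = teacher.forward(X, warn_extrapolation=False) + rng.normal(
            0, sigma, 700
        )
        m = dv.train(
            (X[:500], y[:500]), (9, 3, 1),
            dv.TrainingConfig(seed=0, max_iterations=300),
        )
        pred = m.forward(X[500:], warn_extrapolation=False)
        rmse = np.sqrt(np.mean((pred - y[500:]) ** 2))
        assert rmse < 3 * sigma

    def test_nonfinite_inputs_rejected(self):
        X = np.ones((10, 2))
        X[0, 0] = np.nan
        with pytest.raises(dv.ValidationError, match="finite"):
            dv.train((X, np.ones(10)), (2, 2, 1))


class TestGridSearch:
    def test_singleton_grid_returns_that_architecture(self, small_dataset):
        dataset, _ = small_dataset
        res = dv.grid_search(
            dataset, layer_grid=[(9, 4, 1)],
            config=dv.TrainingConfig(seed=0, max_iterations=40),
        )
        assert res.selected == (9, 4, 1)
        assert len(res.table) == 1

    def test_default_grid_has_25_plus_625_candidates(self):
        grid = default_layer_grid()
        assert len(grid) == 650
        assert sum(1 for g in grid if len(g) == 4) == 625

    def test_capacity_ordering_on_teacher_data(self, rng):
        teacher = random_model(
            (9, 3, 1), seed=11,
            input_min=np.zeros(9), input_max=np.ones(9),
            output_range=(0.0, 2.0), weight_scale=2.0,
        )
        X = rng.uniform(0, 1, size=(300, 9))
        y = teacher.forward(X, warn_extrapolation=False)
        records = [
            dv.ViscosityRecord("S", dv.ratio_to_fractions(1, 2, 0), 300.0,
                               float(10.0**v))
            for v in y
        ]
        dataset = dv.Dataset(records=records, features=X)
        res = dv.grid_search(
            dataset, layer_grid=[(9, 1, 1), (9, 3, 1), (9, 5, 1)],
            config=dv.TrainingConfig(seed=0, max_iterations=120),
        )
        tab = res.table
        rmse_of = lambda arch: tab[tab["architecture"] == arch]["rmse"].iloc[0]
        assert rmse_of(res.selected) <= rmse_of((9, 1, 1))

    def test_empty_grid_rejected(self, small_dataset):
        dataset, _ = small_dataset
        with pytest.raises(dv.ValidationError, match="empty"):
            dv.grid_search(dataset, layer_grid=[])


class TestSerialization:
    def test_json_roundtrip_is_bit_exact(self, small_model, rng):
        buf = io.StringIO()
        dv.save_model(small_model, buf)
        buf.seek(0)
        back = dv.load_model(buf)
        X = rng.uniform(
            small_model.input_min, small_model.input_max, size=(100, 9)
        )
        np.testing.assert_array_equal(
            back.forward(X, warn_extrapolation=False),
            small_model.forward(X, warn_extrapolation=False),
        )

    def test_truncated_file_is_schema_error(self, small_model, tmp_path):
        path = tmp_path / "model.json"
        dv.save_model(small_model, str(path))
        text = path.read_text()[: len(path.read_text()) // 2]
        path.write_text(text)
        with pytest.raises(SchemaError):
            dv.load_model(str(path))

    def test_wrong_schema_version_rejected(self, tmp_path):
        path = tmp_path / "model.json"
        path.write_text('{"schema_version": 99}')
        with pytest.raises(SchemaError, match="version"):
            dv.load_model(str(path))

    def test_weight_table_roundtrip_identical_predictions(
        self, small_model, tmp_path, rng
    ):
        path = tmp_path / "weights.csv"
        dv.export_weight_table(small_model, str(path))
        back = dv.import_weight_table(str(path))
        assert back.layer_sizes == small_model.layer_sizes
        X = rng.uniform(
            small_model.input_min, small_model.input_max, size=(50, 9)
        )
        np.testing.assert_array_equal(
            back.forward(X, warn_extrapolation=False),
            small_model.forward(X, warn_extrapolation=False),
        )
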