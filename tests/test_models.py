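import json

import numpy as np
import pytest

from barospiro.models import (
    MlpModel,
    PolyModel,
    RootModel,
    fit_by_name,
    fit_mlp,
    fit_poly,
    fit_root,
    gof_rmse,
    is_monotone,
    model_from_dict,
    model_to_dict,
    predict,
)

# published-layout coefficient sets used as generating truths
ROOT2ONLY = {"c_pos": 0.1744, "c_neg": -0.1373}
ROOT2_POS = (0.0049, -0.3337, 0.1466)  # (a, b, c)
ROOT2_NEG = (-0.0043, 0.1956, -0.1150)
POLY2 = (0.7420, 1.5460, -0.0768)  # constant-first convention


def _root2only_data(n=400, xmax=2000.0, rng=None):
    rng = rng or np.random.default_rng(1)
    x = np.concatenate([rng.uniform(0, xmax, n // 2), -rng.uniform(0, 0.75 * xmax, n // 2)])
    y = np.where(x >= 0, ROOT2ONLY["c_pos"] * np.sqrt(np.abs(x)),
                 ROOT2ONLY["c_neg"] * np.sqrt(np.abs(x)))
    return x, y


from _oracles import normal_equations_oracle


class TestRootFit:
    def test_recovers_root2only_truth_exactly(self):
        x, y = _root2only_data()
        model, rep = fit_root((x, y), variant="root2only")
        assert model.pos_coeffs[2] == pytest.approx(ROOT2ONLY["c_pos"], abs=1e-8)
        assert model.neg_coeffs[2] == pytest.approx(ROOT2ONLY["c_neg"], abs=1e-8)
        assert rep.rmse_gof < 1e-10

    def test_recovers_root2_truth_and_matches_oracle(self, rng):
        x = np.concatenate([rng.uniform(0, 2000, 200), -rng.uniform(0, 2000, 200)])
        a, b, c = ROOT2_POS
        an, bn, cn = ROOT2_NEG
        z = np.abs(x)
        y = np.where(x >= 0, a * z + b + c * np.sqrt(z), an * z + bn + cn * np.sqrt(z))
        model, _ = fit_root((x, y), variant="root2")
        for got, want in zip(model.pos_coeffs[[0, 1, 2]], ROOT2_POS):
            assert got == pytest.approx(want, abs=1e-6)
        for got, want in zip(model.neg_coeffs[[0, 1, 2]], ROOT2_NEG):
            assert got == pytest.approx(want, abs=1e-6)
        # independent oracle on the positive branch
        pos = x >= 0
        A = np.column_stack([z[pos], np.ones(pos.sum()), np.sqrt(z[pos])])
        oracle = normal_equations_oracle(A, y[pos])
        assert np.allclose(model.pos_coeffs[[0, 1, 2]], oracle, rtol=1e-8, atol=1e-10)

    def test_zero_targets_give_zero_coefficients(self, rng):
        x = np.concatenate([rng.uniform(0, 100, 50), -rng.uniform(0, 100, 50)])
        model, _ = fit_root((x, np.zeros_like(x)), variant="root4")
        assert np.allclose(model.pos_coeffs, 0.0, atol=1e-12)
        assert np.allclose(model.neg_coeffs, 0.0, atol=1e-12)

    def test_rank_deficient_rejected(self):
        x = np.concatenate([np.full(20, 5.0), np.full(20, -5.0)])
        with pytest.raises(ValueError, match="rank-deficient"):
            fit_root((x, x * 0.1), variant="root2")

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="samples"):
            fit_root((np.array([1.0, -1.0]), np.array([0.1, -0.1])), variant="root4")

    def test_robust_fit_resists_outliers(self, rng):
        """Gross outliers move the LAR fit far less than the plain LLS fit."""
        x, y = _root2only_data(n=600, rng=rng)
        y_dirty = y.copy()
        k = int(0.05 * y.size)
        idx = rng.choice(y.size, k, replace=False)
        y_dirty[idx] *= 10.0
        truth = np.array([ROOT2ONLY["c_pos"], ROOT2ONLY["c_neg"]])

        def shift(robust):
            m, _ = fit_root((x, y_dirty), variant="root2only", robust=robust)
            return np.abs(np.array([m.pos_coeffs[2], m.neg_coeffs[2]]) - truth).max()

        assert shift(True) < shift(False) / 3.0


class TestPolyFit:
    def test_recovers_poly2_truth(self, rng):
        x = rng.uniform(-1500, 2000, 300)
        p1, p2, p3 = POLY2
        y = p1 + p2 * x + p3 * x**2
        model, rep = fit_poly((x, y), degree=2)
        assert np.allclose(model.coeffs, POLY2, atol=1e-8)
        assert rep.rmse_gof < 1e-8

    def test_constant_targets(self, rng):
        x = rng.uniform(-10, 10, 100)
        model, _ = fit_poly((x, np.full_like(x, 5.0)), degree=3)
        assert model.coeffs[0] == pytest.approx(5.0, abs=1e-10)
        assert np.allclose(model.coeffs[1:], 0.0, atol=1e-10)

    def test_nested_degrees_agree_on_quadratic_truth(self, rng):
        x = rng.uniform(-50, 50, 400)
        y = 0.742 + 1.546 * x - 0.0768 * x**2
        m2, _ = fit_poly((x, y), degree=2)
        m5, _ = fit_poly((x, y), degree=5)
        assert np.allclose(m5.coeffs[3:], 0.0, atol=1e-8)
        grid = np.linspace(-50, 50, 101)
        assert np.allclose(m5.predict(grid), m2.predict(grid), atol=1e-6)

    def test_poly_at_zero_is_constant_term(self):
        model = PolyModel(coeffs=np.array(POLY2), degree=2)
        assert predict(model, np.array([0.0]))[0] == pytest.approx(0.7420)

    def test_monotonicity_diagnostic(self):
        model = PolyModel(coeffs=np.array(POLY2), degree=2)
        # downward parabola: monotone on the left of the vertex only
        assert is_monotone(model, 0.0, 5.0)
        assert not is_monotone(model, 0.0, 100.0)


class TestPredictAndGof:
    def test_root2only_hand_value(self):
        model = RootModel("root2only", np.array([0, 0, 0.1744, 0, 0]), np.zeros(5))
        assert predict(model, np.array([100.0]))[0] == pytest.approx(1.744)

    def test_empty_series(self):
        model = RootModel("root2only", np.array([0, 0, 0.1744, 0, 0]), np.zeros(5))
        assert predict(model, np.array([])).size == 0

    def test_gof_hand_values(self):
        model = PolyModel(coeffs=np.zeros(3), degree=2)
        x = np.array([1.0, 2.0])
        assert gof_rmse(model, (x, np.array([1.0, -1.0]))) == pytest.approx(1.0)
        assert gof_rmse(model, (x, np.array([3.0, 4.0]))) == pytest.approx(np.sqrt(12.5))

    def test_nested_root_variants_nonincreasing_gof(self, rng):
        x, y = _root2only_data(n=1000, rng=rng)
        y = y + rng.normal(0, 0.1, y.size)
        gofs = [fit_root((x, y), v)[1].rmse_gof for v in ("root2only", "root2", "root3", "root4")]
        assert all(a >= b - 1e-12 for a, b in zip(gofs, gofs[1:]))


class TestMlp:
    def test_linear_data_near_exact(self, rng):
        x = rng.uniform(-1, 1, 400)
        y = 2.0 * x + 1.0
        model, rep = fit_mlp((x, y), hidden_units=1, seed=3)
        assert rep.extras["test_rmse"] < 1e-3

    def test_constant_targets(self, rng):
        x = rng.uniform(-1, 1, 200)
        model, rep = fit_mlp((x, np.full_like(x, 2.5)), hidden_units=3, seed=0)
        assert np.allclose(model.predict(x), 2.5, atol=1e-6)
        assert rep.extras["val_mse_history"][-1] < 1e-6

    def test_deterministic_given_seed(self, rng):
        x = rng.uniform(-1, 1, 300)
        y = np.sin(x)
        m1, _ = fit_mlp((x, y), hidden_units=3, seed=7)
        m2, _ = fit_mlp((x, y), hidden_units=3, seed=7)
        assert np.array_equal(m1.w1, m2.w1) and np.array_equal(m1.w2, m2.w2)

    def test_matches_root4_on_root_shaped_data(self, rng):
        """A 7-unit network fits the square-root cloud as well as the full
        root basis (their goodness of fit is equivalent on noisy data)."""
        x, y = _root2only_data(n=4000, rng=rng)
        y = y + rng.normal(0, 0.05, y.size)
        _, rep_root = fit_root((x, y), variant="root4")
        _, rep_mlp = fit_mlp((x, y), hidden_units=7, seed=3)
        assert rep_mlp.extras["test_rmse"] <= 1.2 * rep_root.rmse_gof

    def test_sklearn_cross_check(self, rng):
        """Independent reference: an off-the-shelf MLP regressor reaches a
        similar error on the same data."""
        sklearn = pytest.importorskip("sklearn.neural_network")
        x, y = _root2only_data(n=2000, rng=rng)
        y = y + rng.normal(0, 0.05, y.size)
        _, rep = fit_mlp((x, y), hidden_units=7, seed=3)
        xs = (x - x.mean()) / x.std()
        ref = sklearn.MLPRegressor(
            hidden_layer_sizes=(7,), activation="logistic", solver="lbfgs",
            max_iter=2000, random_state=0,
        ).fit(xs[:, None], y)
        ref_rmse = float(np.sqrt(np.mean((y - ref.predict(xs[:, None])) ** 2)))
        assert rep.rmse_gof <= 1.3 * ref_rmse


class TestSerialization:
    @pytest.mark.parametrize("name", ["root4", "poly3", "ann2"])
    def test_json_round_trip(self, name, rng):
        x, y = _root2only_data(n=300, rng=rng)
        model, _ = fit_by_name((x, y), name, seed=1)
        doc = json.loads(json.dumps(model_to_dict(model)))
        back = model_from_dict(doc)
        grid = np.linspace(-500, 500, 101)
        assert np.allclose(predict(back, grid), predict(model, grid), rtol=0, atol=1e-12)

    def test_unknown_model_name(self):
        with pytest.raises(ValueError):
            fit_by_name((np.zeros(10), np.zeros(10)), "spline9")
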