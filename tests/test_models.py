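import numpy as np
import pytest

from moltk import descriptors as D
from moltk.fixtures import SyntheticQSARSpec, synthetic_qsar
from moltk.models import (DecisionTree, InputScaler, KohonenMap,
                          LinearRegression, NeuralNetwork, dt_to_logic,
                          model_load, model_save)


def _xy(seed=0, n=120, p=5, noise=0.1):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    w = rng.normal(size=p)
    y = X @ w + 0.7 + rng.normal(scale=noise, size=n)
    return X, y.reshape(-1, 1), w


# -- input scaling ------------------------------------------------------------

def test_scaler_avestd_standardizes():
    X = np.random.default_rng(0).normal(loc=3, scale=2, size=(200, 4))
    s = InputScaler("AveStd").fit(X)
    Z = s.transform(X)
    np.testing.assert_allclose(Z.mean(axis=0), 0, atol=1e-9)
    np.testing.assert_allclose(Z.std(axis=0), 1, atol=1e-9)


def test_scaler_minmax_maps_to_unit_interval():
    X = np.random.default_rng(1).normal(size=(50, 3))
    Z = InputScaler("MinMax").fit(X).transform(X)
    np.testing.assert_allclose(Z.min(axis=0), 0, atol=1e-12)
    np.testing.assert_allclose(Z.max(axis=0), 1, atol=1e-12)


def test_scaler_none_is_identity():
    X = np.random.default_rng(2).normal(size=(10, 2))
    np.testing.assert_array_equal(InputScaler("none").fit(X).transform(X), X)


def test_scaler_round_trips_through_dict():
    X = np.random.default_rng(3).normal(size=(30, 3))
    s = InputScaler("AveStd").fit(X)
    again = InputScaler.from_dict(s.to_dict())
    np.testing.assert_allclose(again.transform(X), s.transform(X))


# -- linear regression --------------------------------------------------------

def test_linreg_matches_lstsq_oracle():
    X, y, _ = _xy()
    model = LinearRegression().fit(X, y)
    A = np.hstack([X, np.ones((len(X), 1))])
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    np.testing.assert_allclose(model.coef_.ravel(), beta[:-1].ravel(),
                               atol=1e-8)
    np.testing.assert_allclose(model.intercept_.ravel(), beta[-1],
                               atol=1e-8)


def test_ridge_matches_sklearn_oracle():
    sklearn_lm = pytest.importorskip("sklearn.linear_model")
    X, y, _ = _xy(seed=4)
    lam = 2.5
    model = LinearRegression(smoothing=lam).fit(X, y)
    ref = sklearn_lm.Ridge(alpha=lam, fit_intercept=True).fit(X, y)
    np.testing.assert_allclose(model.coef_.ravel(), ref.coef_.ravel(),
                               atol=1e-8)
    np.testing.assert_allclose(model.intercept_.ravel(), ref.intercept_,
                               atol=1e-8)


def test_linreg_singular_raises_with_guidance():
    X = np.ones((10, 2))  # rank deficient
    y = np.ones((10, 1))
    with pytest.raises(np.linalg.LinAlgError, match="smoothing"):
        LinearRegression().fit(X, y)
    LinearRegression(smoothing=1.0).fit(X, y)  # regularized succeeds


# -- decision tree ------------------------------------------------------------

def test_tree_fits_separable_data_perfectly():
    rng = np.random.default_rng(5)
    X = rng.normal(size=(100, 3))
    y = (X[:, 1] > 0.2).astype(float)
    for part in ("InformationGain", "Gini", "ROC"):
        model = DecisionTree(partitioner=part).fit(X, y)
        np.testing.assert_array_equal(
            (model.predict(X).ravel() >= 0.5).astype(float), y)


def test_tree_min_split_limits_depth():
    rng = np.random.default_rng(6)
    X = rng.normal(size=(200, 4))
    y = (X[:, 0] + 0.5 * X[:, 1] > 0).astype(float)
    full = DecisionTree().fit(X, y)
    stump = DecisionTree(min_split=90).fit(X, y)
    # a heavily pruned tree has fewer distinct leaf outputs
    assert len(np.unique(stump.predict(X))) <= \
        len(np.unique(full.predict(X)))


def test_tree_rejects_unknown_settings():
    with pytest.raises(ValueError):
        DecisionTree(partitioner="Best")
    with pytest.raises(ValueError):
        DecisionTree(node_score="Biggest")


def test_dt_to_logic_expression_reproduces_predictions():
    rng = np.random.default_rng(7)
    X = rng.normal(size=(150, 2))
    y = ((X[:, 0] > 0) & (X[:, 1] > -0.3)).astype(float)
    model = DecisionTree().fit(X, y)
    names = ["Weight", "TopologicalPolarSurfaceArea"]
    text, expr = dt_to_logic(model, names)
    assert "if" in text
    spec = D.parse_descriptor(expr)
    # evaluate the logic expression on molecules carrying matching values
    from moltk.fixtures import builtin_molecule
    mol = builtin_molecule("toluene")
    w = D.weight(mol)
    tpsa = D.tpsa(mol)
    pred = model.predict(np.array([[w, tpsa]])).ravel()[0]
    got = D.evaluate(spec, mol)[0]
    assert got == float(pred >= 0.5)


# -- neural network -----------------------------------------------------------

def test_ann_regression_learns_squashed_linear_map():
    # sigmoid output covers (0, 1), so target a logistic response
    rng = np.random.default_rng(8)
    X = rng.normal(size=(200, 5))
    w = rng.normal(size=5)
    y = (1.0 / (1.0 + np.exp(-X @ w))).reshape(-1, 1)
    model = NeuralNetwork(hidden_layers=(16,), max_iterations=200,
                          steps_per_update=32, eta=0.5, seed=0).fit(X, y)
    pred = model.predict(X).ravel()
    resid = np.sqrt(np.mean((pred - y.ravel()) ** 2))
    assert resid < 0.5 * np.std(y)


def test_ann_transfer_function_validation():
    X = np.zeros((4, 2))
    y = np.zeros(4)
    with pytest.raises(ValueError, match="transfer"):
        NeuralNetwork(transfer="Step", max_iterations=1).fit(X, y)
    with pytest.raises(ValueError):
        NeuralNetwork(scaling="Robust", max_iterations=1).fit(X, y)


def test_ann_predict_before_fit_raises():
    with pytest.raises(RuntimeError, match="not fitted"):
        NeuralNetwork().predict(np.zeros((1, 3)))


def test_get_set_params_round_trip():
    model = NeuralNetwork(hidden_layers=(8, 4), eta=0.1)
    params = model.get_params()
    clone = NeuralNetwork().set_params(**params)
    assert clone.get_params() == params
    with pytest.raises(ValueError):
        model.set_params(no_such_param=1)


# -- Kohonen map --------------------------------------------------------------

def test_som_predict_returns_node_means():
    ds, _ = synthetic_qsar(SyntheticQSARSpec(seed=9, n_actives=30,
                                             n_inactives=70, n_features=4))
    som = KohonenMap(map_dims=(3, 3), length=20, seed=0).fit(
        ds.X.astype(float), ds.Y.astype(float))
    pred = som.predict(ds.X.astype(float))
    assert pred.shape == (ds.n_rows, 1)
    assert np.all((pred >= 0) & (pred <= 1))


def test_som_ad_score_orders_by_distance():
    rng = np.random.default_rng(10)
    X = rng.normal(size=(100, 3))
    som = KohonenMap(map_dims=(4, 4), length=20, seed=1).fit(X)
    inside = som.ad_score(X)
    outside = som.ad_score(X + 100.0)
    assert np.all(outside >= 0.99)
    assert inside.mean() < outside.mean()


def test_som_invalid_configuration():
    with pytest.raises(ValueError):
        KohonenMap(kernel="Triangle")
    with pytest.raises(ValueError):
        KohonenMap(map_dims=(0, 3)).fit(np.zeros((5, 2)))


# -- storage ------------------------------------------------------------------

def test_model_save_load_identity(tmp_path):
    X, y, _ = _xy(seed=11, n=60)
    Xc = X[:, :3]
    models = [
        LinearRegression().fit(X, y),
        NeuralNetwork(hidden_layers=(6,), max_iterations=20,
                      seed=2).fit(X, (y > 0).astype(float)),
        DecisionTree().fit(X, (y.ravel() > 0).astype(float)),
        KohonenMap(map_dims=(2, 2), length=10, seed=3).fit(X, y),
    ]
    for i, m in enumerate(models):
        model_save(m, tmp_path, "m", i)
    back = model_load(tmp_path, "m")
    assert [type(b).__name__ for b in back] == \
        [type(m).__name__ for m in models]
    for orig, loaded in zip(models, back):
        np.testing.assert_allclose(np.asarray(loaded.predict(X)),
                                   np.asarray(orig.predict(X)), atol=1e-12)


def test_model_load_rejects_corrupt_file(tmp_path):
    (tmp_path / "m000000.model").write_text("{not json")
    with pytest.raises(ValueError, match="corrupt"):
        model_load(tmp_path, "m")
    (tmp_path / "m000000.model").write_text('{"type": "Mystery"}')
    with pytest.raises(ValueError, match="unknown model type"):
        model_load(tmp_path, "m")
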