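import numpy as np
import pytest

from moltk import descriptors as D
from moltk.cv import (Predictions, load_calibration, model_test,
                      prediction_info_property, prediction_mean_property,
                      prediction_merge, run_cv, save_calibration, split_cv)
from moltk.dataset import generate_dataset, randomize
from moltk.fixtures import (SyntheticQSARSpec, builtin_molecule,
                            builtin_names, synthetic_qsar)
from moltk.models import LinearRegression, model_load
from moltk.objectives import local_ppv_fit


def _ds(seed=0, task="regression", noise=0.1):
    ds, _ = synthetic_qsar(SyntheticQSARSpec(seed=seed, n_actives=40,
                                             n_inactives=160, n_features=4,
                                             noise_sd=noise, task=task))
    return ds


def test_split_cv_partitions_rows():
    ds = _ds()
    seen = []
    for fold in range(5):
        train, monitor, independent = split_cv(ds, 5, fold)
        assert monitor.ids == independent.ids
        assert train.n_rows + independent.n_rows == ds.n_rows
        seen.extend(independent.ids)
    assert sorted(seen) == sorted(ds.ids)
    with pytest.raises(ValueError):
        split_cv(ds, 1, 0)
    with pytest.raises(ValueError):
        split_cv(ds, 5, 5)


def test_run_cv_linear_regression_recovers_signal(tmp_path):
    ds = randomize(_ds(noise=0.05), seed=3)
    res = run_cv(ds, LinearRegression, n_folds=5, objective="RMSD",
                 storage=tmp_path, prefix="lin", feature_spec="Weight")
    assert len(res.models) == 5
    assert len(res.pooled.ids) == ds.n_rows
    assert res.pooled_score < 0.2  # low noise: held-out RMSD near noise SD
    # storage layout
    for fold in range(5):
        assert (tmp_path / f"lin{fold:06d}.model").exists()
        assert (tmp_path / f"lin{fold:06d}.predictions.csv").exists()
    assert (tmp_path / "lin.pooled.csv").exists()
    assert (tmp_path / "lin.log_merge.txt").exists()
    assert (tmp_path / "lin.features").read_text().strip() == "Weight"
    # reloaded models reproduce predictions
    back = model_load(tmp_path, "lin")
    for orig, loaded in zip(res.models, back):
        np.testing.assert_allclose(loaded.predict(ds.X.astype(float)),
                                   orig.predict(ds.X.astype(float)),
                                   atol=1e-12)


def test_run_cv_wraps_fold_failures():
    ds = _ds()

    class Broken:
        def fit(self, X, y):
            raise RuntimeError("boom")

    with pytest.raises(RuntimeError, match="fold 0 failed"):
        run_cv(ds, Broken, n_folds=5)


def test_predictions_csv_round_trip(tmp_path):
    p = Predictions(["a", "b"], np.array([[0.25], [0.75]]),
                    np.array([[0.0], [1.0]]))
    path = tmp_path / "p.csv"
    p.save_csv(path)
    back = Predictions.load_csv(path)
    assert back.ids == p.ids
    np.testing.assert_array_equal(back.y_pred, p.y_pred)
    np.testing.assert_array_equal(back.y_actual, p.y_actual)


def test_prediction_merge_averages_shared_ids():
    a = Predictions(["x", "y"], np.array([[1.0], [2.0]]),
                    np.array([[0.0], [1.0]]))
    b = Predictions(["y", "z"], np.array([[4.0], [8.0]]),
                    np.array([[1.0], [0.0]]))
    merged = prediction_merge([a, b])
    assert merged.ids == ["x", "y", "z"]
    np.testing.assert_allclose(merged.y_pred.ravel(), [1.0, 3.0, 8.0])
    wide = Predictions(["q"], np.array([[1.0, 2.0]]), np.array([[0.0, 0.0]]))
    with pytest.raises(ValueError, match="arity"):
        prediction_merge([a, wide])


def test_model_test_committee_average():
    ds = _ds(seed=1)
    models = [LinearRegression().fit(ds.X.astype(float) + i,
                                     ds.Y.astype(float)) for i in range(3)]
    outs = model_test(models, ds)
    assert len(outs) == 3
    avg = model_test(models, ds, average=True)
    np.testing.assert_allclose(avg, np.mean(outs, axis=0), atol=1e-12)


# -- descriptor-backed prediction properties ---------------------------------

def _molecule_storage(tmp_path):
    mols = []
    for name in builtin_names():
        m = builtin_molecule(name)
        m.properties["Activity"] = str(float(D.tpsa(m) > 20.0))
        mols.append(m)
    feat = "Combine(Weight, TopologicalPolarSurfaceArea, HbondDonor)"
    ds = randomize(generate_dataset(mols, feat, "Activity"), seed=2)
    res = run_cv(ds, lambda f: LinearRegression(smoothing=1.0), n_folds=4,
                 objective="RMSD", storage=tmp_path, prefix="m",
                 feature_spec=feat)
    return mols, res


def test_prediction_mean_property_matches_committee(tmp_path):
    mols, res = _molecule_storage(tmp_path)
    spec = prediction_mean_property(tmp_path, "m")
    mol = mols[0]
    got = D.evaluate(spec, mol)[0]
    x = D.evaluate(D.parse_descriptor(
        "Combine(Weight, TopologicalPolarSurfaceArea, HbondDonor)"),
        mol).reshape(1, -1)
    want = float(np.mean([m.predict(x).ravel()[0] for m in res.models]))
    assert got == pytest.approx(want, abs=1e-12)


def test_prediction_info_property_requires_calibration(tmp_path):
    mols, res = _molecule_storage(tmp_path)
    spec = prediction_info_property(tmp_path, "m")
    with pytest.raises(FileNotFoundError, match="calibration"):
        D.evaluate(spec, mols[0])
    curve = local_ppv_fit(res.pooled.y_pred.ravel(),
                          res.pooled.y_actual.ravel(), window=8)
    save_calibration(curve, tmp_path, "m")
    back = load_calibration(tmp_path, "m")
    np.testing.assert_allclose(back.x, curve.x)
    v = D.evaluate(spec, mols[0])[0]
    assert 0.0 <= v <= 1.0


def test_composite_virtual_screening_descriptor(tmp_path):
    # Multiply(PredictionMean, Greater(lhs = PredictionInfo, rhs = 0.5)):
    # the committee prediction gated by its calibrated confidence
    mols, res = _molecule_storage(tmp_path)
    curve = local_ppv_fit(res.pooled.y_pred.ravel(),
                          res.pooled.y_actual.ravel(), window=8)
    save_calibration(curve, tmp_path, "m")
    mean_spec = prediction_mean_property(tmp_path, "m")
    info_spec = prediction_info_property(tmp_path, "m")
    gate = D.DescriptorSpec("operator", "Greater",
                            children=[info_spec,
                                      D.DescriptorSpec("constant",
                                                       values=[0.5])])
    composite = D.DescriptorSpec("operator", "Multiply",
                                 children=[mean_spec, gate])
    for mol in mols[:5]:
        mean = D.evaluate(mean_spec, mol)[0]
        conf = D.evaluate(info_spec, mol)[0]
        got = D.evaluate(composite, mol)[0]
        assert got == pytest.approx(mean * float(conf > 0.5), abs=1e-12)
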