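import numpy as np
import pytest
from hypothesis import given, strategies as st

from moltk import objectives as O

sklearn_metrics = pytest.importorskip("sklearn.metrics")


def _rand_binary(seed, n=200):
    rng = np.random.default_rng(seed)
    actual = (rng.random(n) < 0.3).astype(float)
    pred = np.clip(actual * 0.4 + rng.normal(scale=0.35, size=n) + 0.3,
                   0, 1)
    return pred, actual


def test_contingency_and_accuracy_match_sklearn():
    pred, actual = _rand_binary(0)
    c = O.contingency(pred, actual)
    hard = (pred >= 0.5).astype(int)
    cm = sklearn_metrics.confusion_matrix(actual.astype(int), hard)
    assert (c.TN, c.FP, c.FN, c.TP) == tuple(cm.ravel())
    assert O.accuracy(c) == pytest.approx(
        sklearn_metrics.accuracy_score(actual.astype(int), hard))


def test_mcc_matches_sklearn():
    for seed in range(5):
        pred, actual = _rand_binary(seed)
        hard = (pred >= 0.5).astype(int)
        assert O.mcc(O.contingency(pred, actual)) == pytest.approx(
            sklearn_metrics.matthews_corrcoef(actual.astype(int), hard),
            abs=1e-12)


def test_auc_matches_sklearn():
    for seed in range(5):
        pred, actual = _rand_binary(seed)
        got = O.auc(O.roc_curve(pred, actual))
        want = sklearn_metrics.roc_auc_score(actual, pred)
        assert got == pytest.approx(want, abs=1e-12), seed


def test_parity_zero_flips_class_and_ranking_together():
    # parity 0 makes "below cutoff" the positive class and ranks ascending,
    # so the same predictions yield the same AUC
    pred, actual = _rand_binary(3)
    a = O.auc(O.roc_curve(pred, actual, parity=1))
    b = O.auc(O.roc_curve(pred, actual, parity=0))
    assert a == pytest.approx(b, abs=1e-12)


def test_roc_requires_both_classes():
    with pytest.raises(ValueError):
        O.roc_curve([0.1, 0.9], [1.0, 1.0])


def test_enrichment_perfect_ranking():
    actual = np.array([1.0] * 10 + [0.0] * 90)
    pred = np.linspace(1, 0, 100)  # perfect: actives scored highest
    assert O.enrichment(pred, actual, x_percent=10.0) == pytest.approx(10.0)
    assert O.enrichment(pred, actual, x_percent=100.0) == pytest.approx(1.0)


def test_regression_metrics_match_sklearn():
    rng = np.random.default_rng(1)
    a = rng.normal(size=100)
    p = a + rng.normal(scale=0.3, size=100)
    assert O.mae(p, a) == pytest.approx(
        sklearn_metrics.mean_absolute_error(a, p))
    assert O.rmsd_metric(p, a) == pytest.approx(
        np.sqrt(sklearn_metrics.mean_squared_error(a, p)))
    assert O.rmsd_nstd(p, a) == pytest.approx(O.rmsd_metric(p, a) / a.std())
    assert O.nrmsd(p, a) == pytest.approx(
        O.rmsd_metric(p, a) / (a.max() - a.min()))


def test_mae_nmad_invariances():
    rng = np.random.default_rng(2)
    a = rng.normal(size=80)
    p = a + rng.normal(scale=0.2, size=80)
    base = O.mae_nmad(p, a)
    # scale invariance of the normalized metric
    assert O.mae_nmad(3 * p, 3 * a) == pytest.approx(base)
    with pytest.raises(ValueError):
        O.mae_nmad([1.0, 2.0], [3.0, 3.0])  # zero MAD


def test_isotonic_matches_sklearn():
    from sklearn.isotonic import IsotonicRegression
    rng = np.random.default_rng(4)
    y = rng.normal(size=60)
    got = O._isotonic(y, np.ones(60))
    want = IsotonicRegression().fit_transform(np.arange(60), y)
    np.testing.assert_allclose(got, want, atol=1e-9)


def test_local_ppv_is_monotone_and_bounded():
    pred, actual = _rand_binary(5, n=400)
    curve = O.local_ppv_fit(pred, actual)
    assert np.all(np.diff(curve.y) >= -1e-12)
    assert np.all((curve.y >= 0) & (curve.y <= 1))
    v = O.local_ppv_eval(curve, [curve.x[0] - 10, curve.x[-1] + 10])
    assert v[0] == pytest.approx(curve.y[0])
    assert v[1] == pytest.approx(curve.y[-1])


def test_get_objective_directions():
    assert O.get_objective("AUC").larger_is_better
    assert O.get_objective("MCC").larger_is_better
    assert not O.get_objective("MSE").larger_is_better
    assert not O.get_objective("RMSD").larger_is_better
    with pytest.raises(ValueError):
        O.get_objective("NoSuchObjective")
    pred, actual = _rand_binary(6)
    logauc = O.get_objective("LogAUC")(actual, pred)
    assert 0.0 <= logauc <= 1.0


@given(st.integers(min_value=0, max_value=40))
def test_auc_bounds_and_complement(seed):
    pred, actual = _rand_binary(seed, n=60)
    if actual.sum() in (0, len(actual)):
        return
    a = O.auc(O.roc_curve(pred, actual))
    assert 0.0 <= a <= 1.0
    # reversing the ranking reflects the AUC about 1/2
    b = O.auc(O.roc_curve(-pred, actual))
    assert a + b == pytest.approx(1.0, abs=1e-9)
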