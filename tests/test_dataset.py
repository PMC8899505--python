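import numpy as np
import pytest

from moltk import dataset as DS
from moltk.fixtures import SyntheticQSARSpec, builtin_molecule, synthetic_qsar


def _mols_with_activity():
    mols = []
    for i, name in enumerate(("benzene", "toluene", "ethanol", "aniline")):
        m = builtin_molecule(name)
        if name != "ethanol":  # leave one result missing
            m.properties["Activity"] = str(0.1 * (i + 1))
        mols.append(m)
    return mols


def test_generate_dataset_reads_properties_and_masks_missing():
    ds = DS.generate_dataset(_mols_with_activity(),
                             "Combine(Weight, TopologicalPolarSurfaceArea)",
                             "Activity")
    assert ds.n_rows == 4
    assert ds.n_features == 2
    assert ds.result_mask[:, 0].tolist() == [True, True, False, True]
    assert ds.feature_labels == ["Weight", "TopologicalPolarSurfaceArea"]


def test_generate_dataset_forbid_incomplete_drops_rows():
    ds = DS.generate_dataset(_mols_with_activity(), "Weight", "Activity",
                             forbid_incomplete=True)
    assert ds.n_rows == 3
    assert ds.result_mask.all()


def test_generate_dataset_computed_result():
    ds = DS.generate_dataset([builtin_molecule("benzene")], "Weight",
                             "TopologicalPolarSurfaceArea")
    assert ds.Y[0, 0] == pytest.approx(0.0)


def test_dataset_validation():
    with pytest.raises(ValueError):
        DS.FeatureDataset(["a"], np.zeros((2, 1)), np.zeros((2, 1)),
                          ["f"], ["r"])
    with pytest.raises(ValueError):
        DS.FeatureDataset(["a", "b"], np.zeros((2, 2)), np.zeros((2, 1)),
                          ["f"], ["r"])


# -- binary + CSV storage -----------------------------------------------------

def test_bin_round_trip_with_mask(tmp_path):
    ds = DS.generate_dataset(_mols_with_activity(),
                             "Combine(Weight, LogP)", "Activity")
    path = tmp_path / "d.bin"
    DS.write_bin(ds, path)
    back = DS.read_bin(path)
    assert back.ids == ds.ids
    np.testing.assert_array_equal(back.X, ds.X)
    masked = ds.result_mask
    np.testing.assert_array_equal(back.Y[masked], ds.Y[masked])
    np.testing.assert_array_equal(back.result_mask, masked)
    assert back.feature_labels == ds.feature_labels
    assert back.result_labels == ds.result_labels


def test_bin_rejects_bad_magic_and_truncation(tmp_path):
    bad = tmp_path / "x.bin"
    bad.write_bytes(b"something else entirely")
    with pytest.raises(ValueError, match="magic"):
        DS.read_bin(bad)
    ds, _ = synthetic_qsar(SyntheticQSARSpec(seed=0, n_actives=5,
                                             n_inactives=5, n_features=2))
    path = tmp_path / "t.bin"
    DS.write_bin(ds, path)
    path.write_bytes(path.read_bytes()[:-7])
    with pytest.raises(ValueError, match="truncated"):
        DS.read_bin(path)


def test_csv_round_trip_float32_exact(tmp_path):
    ds, _ = synthetic_qsar(SyntheticQSARSpec(seed=1, n_actives=10,
                                             n_inactives=20, n_features=3))
    path = tmp_path / "d.csv"
    DS.write_csv(ds, path)
    back = DS.read_csv(path, number_result_cols=1,
                       number_id_chars=ds.id_width)
    np.testing.assert_array_equal(back.X, ds.X)
    np.testing.assert_array_equal(back.Y, ds.Y)
    assert [i.strip() for i in back.ids] == [i.strip() for i in ds.ids]


def test_csv_rejects_ragged_and_bad_ids(tmp_path):
    path = tmp_path / "bad.csv"
    path.write_text("aa,1.0,2.0\naa,1.0\n")
    with pytest.raises(ValueError, match="ragged"):
        DS.read_csv(path, number_id_chars=2)
    path.write_text("toolong,1.0\n")
    with pytest.raises(ValueError, match="characters wide"):
        DS.read_csv(path, number_id_chars=2)


# -- transformations ----------------------------------------------------------

def _ds(seed=2, n_act=20, n_inact=80, p=4):
    ds, _ = synthetic_qsar(SyntheticQSARSpec(seed=seed, n_actives=n_act,
                                             n_inactives=n_inact,
                                             n_features=p))
    return ds


def test_randomize_is_seeded_permutation():
    ds = _ds()
    a = DS.randomize(ds, 5)
    b = DS.randomize(ds, 5)
    assert a.ids == b.ids
    assert sorted(a.ids) == sorted(ds.ids)
    assert a.ids != ds.ids


def test_chunks_partition_rows():
    ds = _ds()
    parts = [DS.chunks(ds, 3, [b]) for b in range(3)]
    assert sum(p.n_rows for p in parts) == ds.n_rows
    recon = [i for p in parts for i in p.ids]
    assert recon == ds.ids
    with pytest.raises(ValueError):
        DS.chunks(ds, 3, [3])


def test_combine_columns_and_rows():
    ds = _ds()
    both = DS.combine([ds, ds], axis="columns")
    assert both.n_features == 2 * ds.n_features
    np.testing.assert_array_equal(both.Y, ds.Y)
    stacked = DS.combine([ds, ds], axis="rows")
    assert stacked.n_rows == 2 * ds.n_rows
    other = _ds(seed=3)
    shuffled = DS.randomize(other, 1)
    with pytest.raises(ValueError, match="id sequences differ"):
        DS.combine([ds, shuffled], axis="columns")


def test_balance_reaches_target_ratio():
    ds = _ds(n_act=10, n_inact=90)
    out = DS.balance(ds, target_ratio=0.5, seed=0)
    cls = out.Y[:, 0] >= 0.5
    minor = min(cls.sum(), (~cls).sum())
    major = max(cls.sum(), (~cls).sum())
    assert minor / major >= 0.5 - 1e-9
    # every major-class row retained
    assert (~cls).sum() >= 90 or cls.sum() >= 90


def test_balance_warns_when_capped():
    ds = _ds(n_act=2, n_inact=98)
    with pytest.warns(UserWarning, match="max_repeats"):
        DS.balance(ds, target_ratio=1.0, max_repeats=2, seed=0)


# -- PCA + k-means ------------------------------------------------------------

def test_pca_matches_sklearn_oracle():
    sklearn_decomp = pytest.importorskip("sklearn.decomposition")
    ds = _ds(seed=4, p=6)
    model = DS.pca_train(ds)
    ref = sklearn_decomp.PCA().fit(ds.X.astype(np.float64))
    np.testing.assert_allclose(model.eigenvalues,
                               ref.explained_variance_, atol=1e-6)
    # eigenvectors agree up to sign
    for k in range(3):
        dot = abs(float(model.eigenvectors[:, k] @ ref.components_[k]))
        assert dot == pytest.approx(1.0, abs=1e-6)


def test_pca_apply_keeps_variance_fraction():
    ds = _ds(seed=5, p=6)
    model = DS.pca_train(ds)
    out = DS.pca_apply(ds, model, fraction=0.95)
    kept = model.eigenvalues[:out.n_features].sum()
    assert kept / model.eigenvalues.sum() >= 0.95 - 1e-9
    full = DS.pca_apply(ds, model, fraction=1.0)
    assert full.n_features == ds.n_features
    # projection preserves pairwise distances at full rank
    d0 = np.linalg.norm(ds.X[0].astype(float) - ds.X[1].astype(float))
    d1 = np.linalg.norm(full.X[0].astype(float) - full.X[1].astype(float))
    assert d1 == pytest.approx(d0, rel=1e-5)


def test_kmeans_centroids_are_cluster_means():
    ds = _ds(seed=6)
    out = DS.kmeans(ds, 5, seed=0)
    assert out.n_rows == 5
    X = ds.X.astype(np.float64)
    C = out.X.astype(np.float64)
    assign = ((X[:, None, :] - C[None]) ** 2).sum(axis=2).argmin(axis=1)
    for c in range(5):
        members = assign == c
        assert members.any()
        np.testing.assert_allclose(C[c], X[members].mean(axis=0), atol=1e-5)


def test_summary_shapes():
    ds = _ds()
    s = DS.summary(ds)
    assert s["rows"] == ds.n_rows
    assert len(s["feature_mean"]) == ds.n_features
    assert s["result_density"] == [1.0]
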