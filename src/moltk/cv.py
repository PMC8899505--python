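"""Cross-validation orchestration and prediction-backed properties.

The idiom: randomize a dataset once, split it into k contiguous chunks, and
for fold f train on every chunk except f while chunk f serves as both the
monitoring set and the independent (held-out) evaluation set.  Independent
predictions pooled across folds cover each row exactly once and feed the
final objective.  Trained models, per-fold predictions, the feature
specification and an optional localPPV calibration are stored side by side
so that model output can later be used as a molecular descriptor.
"""

from __future__ import annotations

import inspect
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import descriptors as desc
from .dataset import FeatureDataset, chunks
from .models import model_load, model_save
from .objectives import (CalibrationCurve, get_objective, local_ppv_eval,
                         local_ppv_fit)

__all__ = [
    "CVResult",
    "Predictions",
    "load_calibration",
    "model_test",
    "prediction_info_property",
    "prediction_mean_property",
    "prediction_merge",
    "run_cv",
    "save_calibration",
    "split_cv",
]


def split_cv(ds: FeatureDataset, n_folds: int, fold: int):
    """(train, monitor, independent): independent = monitor = chunk ``fold``,
    train = the remaining chunks.  The caller is responsible for randomizing
    the dataset first; across folds the independents partition the rows."""
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    if not 0 <= fold < n_folds:
        raise ValueError(f"fold {fold} out of range 0..{n_folds - 1}")
    independent = chunks(ds, n_folds, [fold])
    train = chunks(ds, n_folds, [b for b in range(n_folds) if b != fold])
    return train, independent, independent


@dataclass
class Predictions:
    """Held-out predictions with their ids and actual values."""
    ids: list
    y_pred: np.ndarray
    y_actual: np.ndarray

    def save_csv(self, path):
        with open(path, "w") as fh:
            for i, ident in enumerate(self.ids):
                row = [ident]
                row += [repr(float(v)) for v in self.y_pred[i]]
                row += [repr(float(v)) for v in self.y_actual[i]]
                fh.write(",".join(row) + "\n")

    @classmethod
    def load_csv(cls, path, n_results=1):
        ids, pred, act = [], [], []
        for line in Path(path).read_text().splitlines():
            parts = line.split(",")
            ids.append(parts[0])
            vals = list(map(float, parts[1:]))
            pred.append(vals[:n_results])
            act.append(vals[n_results:])
        return cls(ids, np.array(pred), np.array(act))


@dataclass
class CVResult:
    models: list
    fold_predictions: list
    pooled: Predictions
    fold_scores: list
    pooled_score: float
    log: str = ""


def _fit_model(model, train: FeatureDataset, monitor: FeatureDataset):
    """Fit, passing the monitor set when the estimator's fit accepts one."""
    sig = inspect.signature(model.fit)
    kwargs = {}
    if "monitor_X" in sig.parameters:
        kwargs = {"monitor_X": monitor.X.astype(float),
                  "monitor_y": monitor.Y.astype(float)}
    if "result_mask" in sig.parameters:
        kwargs["result_mask"] = train.result_mask
    return model.fit(train.X.astype(float), train.Y.astype(float), **kwargs)


def run_cv(ds: FeatureDataset, make_model, n_folds: int = 5,
           objective="AUC", storage=None, prefix: str = "model",
           feature_spec=None, **objective_kw) -> CVResult:
    """Train one model per fold and score the pooled independent predictions.

    ``make_model`` is a zero- or one-argument factory (the argument, if
    accepted, is the fold index, so per-fold seeds can be derived).  With
    ``storage`` set, models are written as <prefix>NNNNNN.model beside
    per-fold prediction CSVs and a merged log; ``feature_spec`` (descriptor
    text) is stored alongside for later descriptor-backed prediction.
    """
    obj = get_objective(objective, **objective_kw)
    models, fold_preds, fold_scores = [], [], []
    lines = []
    for fold in range(n_folds):
        try:
            train, monitor, independent = split_cv(ds, n_folds, fold)
            factory_sig = inspect.signature(make_model)
            model = make_model(fold) if factory_sig.parameters \
                else make_model()
            _fit_model(model, train, monitor)
            pred = np.asarray(model.predict(independent.X.astype(float)),
                              dtype=float)
            if pred.ndim == 1:
                pred = pred.reshape(-1, 1)
        except Exception as exc:
            raise RuntimeError(f"cross-validation fold {fold} failed: "
                               f"{exc}") from exc
        p = Predictions(list(independent.ids), pred,
                        independent.Y.astype(float))
        score = obj(p.y_actual.ravel(), p.y_pred.ravel())
        models.append(model)
        fold_preds.append(p)
        fold_scores.append(score)
        lines.append(f"fold {fold}: n={len(p.ids)} score={score:.6g}")
        if storage is not None:
            model_save(model, storage, prefix, fold)
            p.save_csv(Path(storage) / f"{prefix}{fold:06d}.predictions.csv")
    pooled = prediction_merge(fold_preds)
    pooled_score = obj(pooled.y_actual.ravel(), pooled.y_pred.ravel())
    lines.append(f"pooled: n={len(pooled.ids)} score={pooled_score:.6g}")
    log = "\n".join(lines)
    if storage is not None:
        (Path(storage) / f"{prefix}.log_merge.txt").write_text(log + "\n")
        pooled.save_csv(Path(storage) / f"{prefix}.pooled.csv")
        if feature_spec is not None:
            text = feature_spec if isinstance(feature_spec, str) \
                else desc.serialize_descriptor(feature_spec)
            (Path(storage) / f"{prefix}.features").write_text(text + "\n")
    return CVResult(models, fold_preds, pooled, fold_scores, pooled_score,
                    log)


def prediction_merge(sets) -> Predictions:
    """Average rows sharing an id; disjoint ids concatenate.  Output order is
    by first appearance across the inputs."""
    if not sets:
        raise ValueError("nothing to merge")
    arity = sets[0].y_pred.shape[1]
    order = []
    acc = {}
    for s in sets:
        if s.y_pred.shape[1] != arity:
            raise ValueError("inconsistent result arity across sets")
        for i, ident in enumerate(s.ids):
            key = ident.strip()
            if key not in acc:
                order.append(key)
                acc[key] = [np.zeros(arity), 0, s.y_actual[i]]
            acc[key][0] = acc[key][0] + s.y_pred[i]
            acc[key][1] += 1
    ids = order
    pred = np.array([acc[k][0] / acc[k][1] for k in order])
    actual = np.array([acc[k][2] for k in order])
    return Predictions(ids, pred, actual)


def model_test(models, ds: FeatureDataset, average: bool = False):
    """Per-model predictions on a dataset; with ``average``, their row-wise
    mean (the merged-committee prediction)."""
    outs = []
    for mi, model in enumerate(models):
        try:
            p = np.asarray(model.predict(ds.X.astype(float)), dtype=float)
        except ValueError as exc:
            raise ValueError(f"model {mi}: {exc}") from exc
        outs.append(p.reshape(len(ds.ids), -1))
    if average:
        return np.mean(outs, axis=0)
    return outs


# ---------------------------------------------------------------------------
# calibration storage + descriptor-backed prediction properties
# ---------------------------------------------------------------------------

def save_calibration(curve: CalibrationCurve, storage,
                     prefix: str = "model"):
    path = Path(storage) / f"{prefix}.calibration"
    path.write_text(json.dumps({"x": curve.x.tolist(),
                                "y": curve.y.tolist()}))
    return path


def load_calibration(storage, prefix: str = "model") -> CalibrationCurve:
    path = Path(storage) / f"{prefix}.calibration"
    if not path.exists():
        raise FileNotFoundError(
            f"{path} missing: fit localPPV on the pooled CV predictions "
            "and store it with save_calibration first")
    d = json.loads(path.read_text())
    return CalibrationCurve(np.asarray(d["x"]), np.asarray(d["y"]))


@dataclass
class _ModelStorage:
    storage: str
    prefix: str = "model"
    _models: list = field(default=None, repr=False)
    _features: "desc.DescriptorSpec" = field(default=None, repr=False)

    def models(self):
        if self._models is None:
            self._models = model_load(self.storage, self.prefix)
            if not self._models:
                raise FileNotFoundError(
                    f"no {self.prefix}NNNNNN.model files in {self.storage}")
        return self._models

    def features(self):
        if self._features is None:
            path = Path(self.storage) / f"{self.prefix}.features"
            if not path.exists():
                raise FileNotFoundError(
                    f"{path} missing: store the feature specification with "
                    "run_cv(feature_spec=...)")
            self._features = desc.parse_descriptor(path.read_text())
        return self._features

    def mean_prediction(self, mol) -> float:
        x = desc.evaluate(self.features(), mol).reshape(1, -1)
        preds = [float(np.asarray(m.predict(x)).ravel()[0])
                 for m in self.models()]
        return float(np.mean(preds))


def prediction_mean_property(storage, prefix: str = "model",
                             name: str = "PredictionMean"):
    """Descriptor leaf whose value is the committee-mean model prediction of
    a molecule (features computed from the stored specification)."""
    ms = _ModelStorage(str(storage), prefix)
    return desc.DescriptorSpec("custom", name,
                               parameters={"fn": ms.mean_prediction})


def prediction_info_property(storage, prefix: str = "model",
                             metric: str = "LocalPPV",
                             name: str = "PredictionInfo"):
    """Descriptor leaf mapping the committee-mean prediction through the
    stored localPPV calibration."""
    if metric != "LocalPPV":
        raise ValueError(f"unsupported metric {metric!r}")
    ms = _ModelStorage(str(storage), prefix)
    curve_holder = {}

    def fn(mol):
        if "curve" not in curve_holder:
            curve_holder["curve"] = load_calibration(storage, prefix)
        v = ms.mean_prediction(mol)
        return float(local_ppv_eval(curve_holder["curve"], v))

    return desc.DescriptorSpec("custom", f"{name}({metric})",
                               parameters={"fn": fn})
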