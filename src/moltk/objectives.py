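"""Objective functions for model evaluation.

Classification metrics are computed from a contingency table at an activity
cutoff, ranking metrics from an ROC threshold sweep with grouped ties, and
regression metrics from the usual residual summaries.  ``local_ppv_fit``
calibrates raw model outputs to a local positive-predictive-value estimate
via a sliding window followed by pool-adjacent-violators isotonic smoothing.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "CalibrationCurve",
    "ContingencyCounts",
    "ROCCurve",
    "accuracy",
    "auc",
    "contingency",
    "enrichment",
    "get_objective",
    "local_ppv_eval",
    "local_ppv_fit",
    "mae",
    "mad",
    "mae_nmad",
    "mcc",
    "nrmsd",
    "ppv",
    "rmsd_metric",
    "rmsd_nstd",
    "roc_curve",
]


# ---------------------------------------------------------------------------
# contingency metrics
# ---------------------------------------------------------------------------

@dataclass
class ContingencyCounts:
    TP: int
    FP: int
    TN: int
    FN: int
    cutoff: float = 0.5
    parity: int = 1

    @property
    def n(self):
        return self.TP + self.FP + self.TN + self.FN

    @property
    def P(self):
        return self.TP + self.FN

    @property
    def N(self):
        return self.TN + self.FP


def _binary(actual, cutoff, parity):
    a = np.asarray(actual, dtype=float)
    pos = a >= cutoff
    return pos if parity == 1 else ~pos


def contingency(pred, actual, cutoff: float = 0.5,
                parity: int = 1) -> ContingencyCounts:
    """Counts with prediction and actual both thresholded at ``cutoff``;
    parity 0 flips which side of the cutoff counts as the positive class."""
    pred = np.asarray(pred, dtype=float)
    if pred.shape != np.shape(actual):
        raise ValueError("pred and actual lengths differ")
    truth = _binary(actual, cutoff, parity)
    call = _binary(pred, cutoff, parity)
    return ContingencyCounts(
        TP=int(np.sum(call & truth)), FP=int(np.sum(call & ~truth)),
        TN=int(np.sum(~call & ~truth)), FN=int(np.sum(~call & truth)),
        cutoff=cutoff, parity=parity)


def accuracy(c: ContingencyCounts) -> float:
    if c.n == 0:
        warnings.warn("empty contingency table; accuracy defined as 0")
        return 0.0
    return (c.TP + c.TN) / c.n


def ppv(c: ContingencyCounts) -> float:
    if c.TP + c.FP == 0:
        warnings.warn("no positive calls; PPV defined as 0")
        return 0.0
    return c.TP / (c.TP + c.FP)


def mcc(c: ContingencyCounts) -> float:
    denom = math.sqrt(float(c.TP + c.FP) * (c.TP + c.FN)
                      * (c.TN + c.FP) * (c.TN + c.FN))
    if denom == 0:
        warnings.warn("MCC denominator is 0; defined as 0")
        return 0.0
    return (c.TP * c.TN - c.FP * c.FN) / denom


def enrichment(pred, actual, x_percent: float = 1.0, cutoff: float = 0.5,
               parity: int = 1) -> float:
    """PPV among the top x% highest-scored rows divided by the prevalence
    (the PPV of taking everything)."""
    pred = np.asarray(pred, dtype=float)
    truth = _binary(actual, cutoff, parity)
    n = len(pred)
    if n == 0:
        raise ValueError("empty input")
    prevalence = truth.mean()
    if prevalence == 0:
        warnings.warn("no positives; enrichment defined as 0")
        return 0.0
    k = max(1, int(round(n * x_percent / 100.0)))
    score = pred if parity == 1 else -pred
    top = np.argsort(-score, kind="stable")[:k]
    return float(truth[top].mean() / prevalence)


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------

@dataclass
class ROCCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray


def roc_curve(pred, actual, cutoff: float = 0.5, parity: int = 1) -> ROCCurve:
    """Threshold sweep from the most to the least confident prediction with
    tied prediction values grouped into a single step; starts at (0,0) and
    ends at (1,1)."""
    pred = np.asarray(pred, dtype=float)
    truth = _binary(actual, cutoff, parity)
    P = int(truth.sum())
    N = int((~truth).sum())
    if P == 0 or N == 0:
        raise ValueError("ROC requires both classes present")
    score = pred if parity == 1 else -pred
    order = np.argsort(-score, kind="stable")
    s = score[order]
    t = truth[order]
    # group ties: indices where the threshold value changes
    distinct = np.flatnonzero(np.diff(s)) + 1
    cuts = np.concatenate([distinct, [len(s)]])
    tp = np.cumsum(t)[cuts - 1]
    fp = cuts - tp
    fpr = np.concatenate([[0.0], fp / N])
    tpr = np.concatenate([[0.0], tp / P])
    thr = np.concatenate([[np.inf], s[cuts - 1]])
    return ROCCurve(fpr, tpr, thr)


def _interp_tpr(curve: ROCCurve, x: float) -> float:
    return float(np.interp(x, curve.fpr, curve.tpr))


def auc(curve: ROCCurve, min_fpr: float = 0.0, max_fpr: float = 1.0,
        x_axis_log: bool = False) -> float:
    """Trapezoidal area of TPR over FPR in [min_fpr, max_fpr], normalized by
    the (log-)span of the x axis.  In log mode the x axis is log10(FPR) and
    the result is the span-normalized integral (Table-style logAUC)."""
    if not 0 <= min_fpr < max_fpr <= 1:
        raise ValueError(f"invalid FPR range [{min_fpr}, {max_fpr}]")
    if x_axis_log and min_fpr <= 0:
        raise ValueError("log-axis AUC requires min_fpr > 0")
    sel = (curve.fpr >= min_fpr) & (curve.fpr <= max_fpr)
    # keep duplicate FPR values: vertical segments carry the TPR jump that
    # grid interpolation would otherwise flatten
    xs = np.concatenate([[min_fpr], curve.fpr[sel], [max_fpr]])
    ys = np.concatenate([[_interp_tpr(curve, min_fpr)], curve.tpr[sel],
                         [_interp_tpr(curve, max_fpr)]])
    if x_axis_log:
        lx = np.log10(xs)
        area = np.trapezoid(ys, lx)
        return float(area / (lx[-1] - lx[0]))
    area = np.trapezoid(ys, xs)
    return float(area / (xs[-1] - xs[0]))


# ---------------------------------------------------------------------------
# regression metrics
# ---------------------------------------------------------------------------

def _pair(pred, actual):
    p = np.asarray(pred, dtype=float).ravel()
    a = np.asarray(actual, dtype=float).ravel()
    if p.shape != a.shape:
        raise ValueError("pred and actual lengths differ")
    return p, a


def mae(pred, actual) -> float:
    p, a = _pair(pred, actual)
    return float(np.mean(np.abs(p - a)))


def mad(actual) -> float:
    a = np.asarray(actual, dtype=float).ravel()
    return float(np.mean(np.abs(a - a.mean())))


def mae_nmad(pred, actual) -> float:
    p, a = _pair(pred, actual)
    if len(a) < 2:
        raise ValueError("normalized metrics need n >= 2")
    m = mad(a)
    if m == 0:
        raise ValueError("zero mean absolute deviation of actuals")
    return mae(p, a) / m


def rmsd_metric(pred, actual) -> float:
    p, a = _pair(pred, actual)
    return float(np.sqrt(np.mean((p - a) ** 2)))


def nrmsd(pred, actual) -> float:
    p, a = _pair(pred, actual)
    if len(a) < 2:
        raise ValueError("normalized metrics need n >= 2")
    span = float(a.max() - a.min())
    if span == 0:
        raise ValueError("zero range of actuals")
    return rmsd_metric(p, a) / span


def rmsd_nstd(pred, actual) -> float:
    p, a = _pair(pred, actual)
    if len(a) < 2:
        raise ValueError("normalized metrics need n >= 2")
    sd = float(a.std())
    if sd == 0:
        raise ValueError("zero standard deviation of actuals")
    return rmsd_metric(p, a) / sd


# ---------------------------------------------------------------------------
# localPPV calibration
# ---------------------------------------------------------------------------

@dataclass
class CalibrationCurve:
    """Monotone map from raw model output to a local PPV estimate."""
    x: np.ndarray  # sorted model output values
    y: np.ndarray  # isotonic local PPV in [0, 1]


def _isotonic(y, weights):
    """Pool-adjacent-violators for a non-decreasing fit."""
    vals = list(map(float, y))
    wts = list(map(float, weights))
    blocks = [[v, w] for v, w in zip(vals, wts)]
    out = []
    for v, w in blocks:
        out.append([v, w])
        while len(out) > 1 and out[-2][0] > out[-1][0]:
            v2, w2 = out.pop()
            v1, w1 = out.pop()
            out.append([(v1 * w1 + v2 * w2) / (w1 + w2), w1 + w2])
    res = []
    i = 0
    for v, w in out:
        k = 0
        total = 0.0
        while total < w - 1e-9:
            total += wts[i + k]
            k += 1
        res.extend([v] * k)
        i += k
    return np.array(res)


def local_ppv_fit(pred, actual, cutoff: float = 0.5, parity: int = 1,
                  window: int | None = None) -> CalibrationCurve:
    """Sliding-window PPV over prediction-sorted rows, then isotonic
    smoothing (non-decreasing along increasing score for parity 1).

    The window defaults to 1% of the rows, with a floor of 50.
    """
    p, _ = _pair(pred, actual)
    truth = _binary(actual, cutoff, parity).astype(float)
    n = len(p)
    if window is None:
        window = max(50, int(round(0.01 * n)))
    if n < window:
        raise ValueError(f"need at least window={window} rows, got {n}")
    score = p if parity == 1 else -p
    order = np.argsort(score, kind="stable")
    s = score[order]
    t = truth[order]
    half = window // 2
    xs, ys = [], []
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, lo + window)
        lo = max(0, hi - window)
        xs.append(s[i])
        ys.append(t[lo:hi].mean())
    ys = _isotonic(np.array(ys), np.ones(n))
    xs = np.array(xs)
    if parity != 1:
        xs = -xs[::-1]
        ys = ys[::-1]
    return CalibrationCurve(xs, np.clip(ys, 0.0, 1.0))


def local_ppv_eval(curve: CalibrationCurve, v) -> np.ndarray:
    """Piecewise-linear interpolation, clamped to the curve's endpoints."""
    out = np.interp(np.asarray(v, dtype=float), curve.x, curve.y)
    return np.clip(out, 0.0, 1.0)


# ---------------------------------------------------------------------------
# named objectives for training monitors
# ---------------------------------------------------------------------------

class Objective:
    """Callable (actual, pred) -> score with a preferred direction."""

    def __init__(self, fn, larger_is_better):
        self.fn = fn
        self.larger_is_better = larger_is_better

    def __call__(self, actual, pred):
        return float(self.fn(actual, pred))


def _auc_obj(min_fpr=0.0, max_fpr=1.0, x_axis_log=False, cutoff=0.5,
             parity=1):
    def fn(actual, pred):
        return auc(roc_curve(pred, actual, cutoff, parity), min_fpr,
                   max_fpr, x_axis_log)
    return Objective(fn, True)


def get_objective(name, **kw) -> Objective:
    """Resolve an objective by name: MSE, RMSD, MAE, Accuracy, MCC, AUC,
    LogAUC (keyword arguments forwarded: cutoff, parity, min_fpr, max_fpr)."""
    if isinstance(name, Objective):
        return name
    if callable(name):
        return Objective(name, kw.get("larger_is_better", False))
    key = name.lower()
    if key == "mse":
        return Objective(lambda a, p: rmsd_metric(p, a) ** 2, False)
    if key == "rmsd":
        return Objective(lambda a, p: rmsd_metric(p, a), False)
    if key == "mae":
        return Objective(lambda a, p: mae(p, a), False)
    if key == "accuracy":
        return Objective(
            lambda a, p: accuracy(contingency(p, a, kw.get("cutoff", 0.5),
                                              kw.get("parity", 1))), True)
    if key == "mcc":
        return Objective(
            lambda a, p: mcc(contingency(p, a, kw.get("cutoff", 0.5),
                                         kw.get("parity", 1))), True)
    if key == "auc":
        return _auc_obj(kw.get("min_fpr", 0.0), kw.get("max_fpr", 1.0),
                        False, kw.get("cutoff", 0.5), kw.get("parity", 1))
    if key == "logauc":
        return _auc_obj(kw.get("min_fpr", 0.001), kw.get("max_fpr", 0.1),
                        True, kw.get("cutoff", 0.5), kw.get("parity", 1))
    raise ValueError(f"unknown objective {name!r}")
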