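"""Trainable models with a uniform estimator interface.

Each model is an estimator class in the familiar style: hyperparameters are
constructor arguments, ``fit(X, y)`` learns and sets trailing-underscore
attributes, ``predict(X)`` maps features to outputs, and ``get_params`` /
``set_params`` expose the configuration.  Input scaling (AveStd or MinMax) is
fitted on the training data inside ``fit`` and applied transparently in
``predict``.

Models: a dropout feed-forward neural network trained by backpropagation
with momentum, a best-first decision tree with pluggable split partitioners,
ridge-regularized linear regression solved by Cholesky factorization, and a
Kohonen self-organizing map doubling as an applicability-domain model.
All training is deterministic given the seed.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.linalg

__all__ = [
    "DecisionTree",
    "InputScaler",
    "KohonenMap",
    "LinearRegression",
    "NeuralNetwork",
    "dt_to_logic",
    "model_load",
    "model_save",
]


# ---------------------------------------------------------------------------
# scaling
# ---------------------------------------------------------------------------

class InputScaler:
    """Per-column rescaling: AveStd (zero mean, unit SD; zero-SD columns pass
    through with SD treated as 1), MinMax (onto [0, 1]), or none."""

    def __init__(self, mode: str = "AveStd"):
        if mode not in ("AveStd", "MinMax", "none"):
            raise ValueError(f"unknown scaling mode {mode!r}")
        self.mode = mode

    def fit(self, X):
        X = np.asarray(X, dtype=float)
        if self.mode == "AveStd":
            self.center_ = X.mean(axis=0)
            sd = X.std(axis=0)
            self.scale_ = np.where(sd == 0, 1.0, sd)
        elif self.mode == "MinMax":
            self.center_ = X.min(axis=0)
            span = X.max(axis=0) - self.center_
            self.scale_ = np.where(span == 0, 1.0, span)
        else:
            self.center_ = np.zeros(X.shape[1])
            self.scale_ = np.ones(X.shape[1])
        return self

    def transform(self, X):
        return (np.asarray(X, dtype=float) - self.center_) / self.scale_

    def to_dict(self):
        return {"mode": self.mode, "center": self.center_.tolist(),
                "scale": self.scale_.tolist()}

    @classmethod
    def from_dict(cls, d):
        s = cls(d["mode"])
        s.center_ = np.asarray(d["center"], dtype=float)
        s.scale_ = np.asarray(d["scale"], dtype=float)
        return s


class _Estimator:
    """Minimal get_params/set_params provider."""

    _params: tuple = ()

    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k) for k in self._params}

    def set_params(self, **kwargs):
        for k, v in kwargs.items():
            if k not in self._params:
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def __repr__(self):
        args = ", ".join(f"{k}={getattr(self, k)!r}" for k in self._params)
        return f"{type(self).__name__}({args})"

    def _check_fitted(self):
        if not getattr(self, "_fitted", False):
            raise RuntimeError(f"{type(self).__name__} is not fitted")


def _as_2d(a):
    a = np.asarray(a, dtype=float)
    return a.reshape(-1, 1) if a.ndim == 1 else a


# ---------------------------------------------------------------------------
# neural network
# ---------------------------------------------------------------------------

_TRANSFERS = {
    "Sigmoid": (lambda z: 1.0 / (1.0 + np.exp(-z)),
                lambda z, y: y * (1.0 - y)),
    "Linear": (lambda z: z, lambda z, y: np.ones_like(z)),
}


def _rectifier(leak):
    return (lambda z: np.where(z > 0, z, leak * z),
            lambda z, y: np.where(z > 0, 1.0, leak))


class NeuralNetwork(_Estimator):
    """Feed-forward network trained by backpropagation with momentum.

    Forward pass per layer: z(l+1) = w(l+1) (r(l) o y(l)) + b(l+1),
    y = f(z), where r(l) is a Bernoulli dropout mask drawn per batch at rate
    p(l) (``dropout`` lists one rate per non-output layer, input first).  In
    test mode no masks are drawn and each layer's outgoing weights are scaled
    by (1 - p) instead.  The loss is mean squared error; masked (missing)
    result entries contribute zero gradient.  The weight update is classical
    momentum: dW_t = -eta * grad + alpha * dW_{t-1}.

    A monitor set may be supplied to ``fit``; the returned model is the one
    from the best-monitor-score epoch under ``objective`` (default MSE).
    """

    _params = ("hidden_layers", "transfer", "leak", "alpha", "eta",
               "dropout", "steps_per_update", "shuffle", "max_iterations",
               "objective", "seed", "scaling")

    def __init__(self, hidden_layers=(32,), transfer="Sigmoid", leak=0.05,
                 alpha=0.5, eta=0.05, dropout=None, steps_per_update=0,
                 shuffle=True, max_iterations=100, objective="MSE",
                 seed=0, scaling="AveStd"):
        self.hidden_layers = tuple(hidden_layers)
        self.transfer = transfer
        self.leak = leak
        self.alpha = alpha
        self.eta = eta
        self.dropout = dropout
        self.steps_per_update = steps_per_update
        self.shuffle = shuffle
        self.max_iterations = max_iterations
        self.objective = objective
        self.seed = seed
        self.scaling = scaling

    # -- forward ----------------------------------------------------------
    def _transfer_fns(self):
        if self.transfer == "Rectifier":
            return _rectifier(self.leak)
        if self.transfer not in _TRANSFERS:
            raise ValueError(f"unknown transfer {self.transfer!r}")
        return _TRANSFERS[self.transfer]

    def forward(self, X, train_mode=False, masks=None):
        """Returns (output, cache) on already-scaled input."""
        f, _ = self._transfer_fns()
        p = self._dropout_rates()
        y = np.asarray(X, dtype=float)
        zs, ys = [], [y]
        for li, (w, b) in enumerate(zip(self.weights_, self.biases_)):
            inp = y
            if train_mode:
                if masks is not None:
                    inp = inp * masks[li]
            elif p[li] > 0:
                w = w * (1.0 - p[li])
            z = inp @ w.T + b
            y = f(z)
            zs.append(z)
            ys.append(y)
        return y, (zs, ys)

    def _dropout_rates(self):
        n_mask_layers = 1 + len(self.hidden_layers)
        if self.dropout is None:
            return [0.0] * n_mask_layers
        p = list(self.dropout)
        if len(p) != n_mask_layers:
            raise ValueError(f"dropout needs {n_mask_layers} rates "
                             "(input layer first)")
        if any(not 0 <= v < 1 for v in p):
            raise ValueError("dropout rates must be in [0, 1)")
        return p

    def _gradients(self, X, T, mask, masks):
        """Mean-squared-error gradients for one (scaled) batch."""
        f, fprime = self._transfer_fns()
        out, (zs, ys) = self.forward(X, train_mode=True, masks=masks)
        n = X.shape[0]
        err = (out - T) * mask
        delta = (2.0 / (n * T.shape[1])) * err * fprime(zs[-1], ys[-1])
        gw, gb = [None] * len(self.weights_), [None] * len(self.weights_)
        for li in range(len(self.weights_) - 1, -1, -1):
            inp = ys[li] * masks[li] if masks is not None else ys[li]
            gw[li] = delta.T @ inp
            gb[li] = delta.sum(axis=0)
            if li > 0:
                delta = (delta @ self.weights_[li]) \
                    * fprime(zs[li - 1], ys[li])
                if masks is not None:
                    delta = delta * masks[li]
        return gw, gb, float(np.mean((err * mask) ** 2))

    # -- training ---------------------------------------------------------
    def fit(self, X, y, monitor_X=None, monitor_y=None, result_mask=None):
        X = _as_2d(X)
        T = _as_2d(y)
        if result_mask is None:
            mask_all = (~np.isnan(T)).astype(float)
        else:
            mask_all = np.asarray(result_mask, dtype=float).reshape(T.shape)
        T = np.nan_to_num(T)
        rng = np.random.default_rng(self.seed)
        self.scaler_ = InputScaler(self.scaling).fit(X)
        Xs = self.scaler_.transform(X)
        sizes = [Xs.shape[1], *self.hidden_layers, T.shape[1]]
        self.layer_sizes_ = sizes
        self.weights_ = [rng.uniform(-0.5, 0.5, size=(sizes[i + 1], sizes[i]))
                         / math.sqrt(sizes[i])
                         for i in range(len(sizes) - 1)]
        self.biases_ = [rng.uniform(-0.1, 0.1, size=sizes[i + 1])
                        for i in range(len(sizes) - 1)]
        vel_w = [np.zeros_like(w) for w in self.weights_]
        vel_b = [np.zeros_like(b) for b in self.biases_]
        p = self._dropout_rates()
        n = Xs.shape[0]
        batch = n if self.steps_per_update in (0, None) \
            else min(self.steps_per_update, n)
        from .objectives import get_objective
        obj = get_objective(self.objective)
        has_monitor = monitor_X is not None and monitor_y is not None
        self._fitted = True  # weights exist; predict is valid mid-training
        best_score = None
        best_state = None
        self.history_ = []
        for epoch in range(self.max_iterations):
            order = rng.permutation(n) if self.shuffle else np.arange(n)
            for start in range(0, n, batch):
                rows = order[start:start + batch]
                masks = None
                if any(v > 0 for v in p):
                    masks = [(rng.random((len(rows), sizes[li])) >= p[li])
                             .astype(float) for li in range(len(p))]
                gw, gb, loss = self._gradients(Xs[rows], T[rows],
                                               mask_all[rows], masks)
                if not math.isfinite(loss):
                    raise FloatingPointError(
                        f"non-finite training loss at epoch {epoch}; "
                        "reduce eta or check the input scaling")
                for li in range(len(self.weights_)):
                    vel_w[li] = -self.eta * gw[li] + self.alpha * vel_w[li]
                    vel_b[li] = -self.eta * gb[li] + self.alpha * vel_b[li]
                    self.weights_[li] += vel_w[li]
                    self.biases_[li] += vel_b[li]
            if has_monitor:
                pred = self.predict(monitor_X)
                score = obj(np.asarray(monitor_y, dtype=float).ravel()
                            if pred.shape[1] == 1 else _as_2d(monitor_y),
                            pred.ravel() if pred.shape[1] == 1 else pred)
            else:
                pred, _ = self.forward(Xs)
                score = obj(T.ravel() if T.shape[1] == 1 else T,
                            pred.ravel() if T.shape[1] == 1 else pred)
            self.history_.append(score)
            better = (best_score is None
                      or (score > best_score if obj.larger_is_better
                          else score < best_score))
            if better:
                best_score = score
                best_state = ([w.copy() for w in self.weights_],
                              [b.copy() for b in self.biases_])
        if best_state is not None:
            self.weights_, self.biases_ = best_state
        self.best_score_ = best_score
        self._fitted = True
        return self

    def predict(self, X):
        self._check_fitted()
        Xs = self.scaler_.transform(_as_2d(X))
        if Xs.shape[1] != self.layer_sizes_[0]:
            raise ValueError(f"expected {self.layer_sizes_[0]} features, "
                             f"got {Xs.shape[1]}")
        out, _ = self.forward(Xs)
        return out

    # -- serialization ----------------------------------------------------
    def _state(self):
        return {"type": "NeuralNetwork",
                "params": {k: (list(v) if isinstance(v, tuple) else v)
                           for k, v in self.get_params().items()},
                "scaler": self.scaler_.to_dict(),
                "layer_sizes": self.layer_sizes_,
                "weights": [w.tolist() for w in self.weights_],
                "biases": [b.tolist() for b in self.biases_]}

    @classmethod
    def _from_state(cls, d):
        params = dict(d["params"])
        params["hidden_layers"] = tuple(params["hidden_layers"])
        if params.get("dropout") is not None:
            params["dropout"] = tuple(params["dropout"])
        m = cls(**params)
        m.scaler_ = InputScaler.from_dict(d["scaler"])
        m.layer_sizes_ = list(d["layer_sizes"])
        m.weights_ = [np.asarray(w, dtype=float) for w in d["weights"]]
        m.biases_ = [np.asarray(b, dtype=float) for b in d["biases"]]
        m._fitted = True
        return m


# ---------------------------------------------------------------------------
# decision tree
# ---------------------------------------------------------------------------

def _entropy(pos, total):
    if total == 0 or pos == 0 or pos == total:
        return 0.0
    f = pos / total
    return -(f * math.log2(f) + (1 - f) * math.log2(1 - f))


def _gini(pos, total):
    if total == 0:
        return 0.0
    f = pos / total
    return 2 * f * (1 - f)


@dataclass
class _TreeNode:
    feature: int = -1          # -1 for leaves
    threshold: float = 0.0
    left: "._TreeNode | None" = None
    right: "._TreeNode | None" = None
    fraction: float = 0.0      # active-class fraction of training rows
    count: int = 0
    mean_activity: float = 0.0


class DecisionTree(_Estimator):
    """Best-first binary decision tree on a thresholded activity.

    Split candidates are midpoints between consecutive sorted unique feature
    values, rated by the partitioner:
      InformationGain -- parent entropy minus weighted child entropy
      Gini            -- parent Gini impurity minus weighted child impurity
      ROC             -- balanced accuracy of the split (mean of the child
                         purity rates), the two-point ROC area
      Sequence        -- admissible only if a child is pure; rated by the
                         fraction of rows in pure children
    Ties break toward the lowest feature index, then lowest threshold.
    Expansion order follows ``node_score`` (relevant when ``max_nodes``
    bounds tree size); a node stops splitting when its misclassified count
    is <= ``min_split`` or no admissible split exists.  Leaves predict the
    active-class fraction.
    """

    _params = ("partitioner", "node_score", "activity_cutoff", "min_split",
               "max_nodes")

    def __init__(self, partitioner="InformationGain",
                 node_score="SplitRating", activity_cutoff=0.5, min_split=0,
                 max_nodes=None):
        if partitioner not in ("InformationGain", "Gini", "ROC", "Sequence"):
            raise ValueError(f"unknown partitioner {partitioner!r}")
        if node_score not in ("SplitRating", "InitialNumIncorrect",
                              "RatingTimesInitialNumIncorrect",
                              "InitialIncorrectPlusFinalCorrect"):
            raise ValueError(f"unknown node score {node_score!r}")
        self.partitioner = partitioner
        self.node_score = node_score
        self.activity_cutoff = activity_cutoff
        self.min_split = min_split
        self.max_nodes = max_nodes

    def _rate_split(self, y, left_mask):
        n = len(y)
        nl = int(left_mask.sum())
        nr = n - nl
        if nl == 0 or nr == 0:
            return None
        pos = int(y.sum())
        pl = int(y[left_mask].sum())
        pr = pos - pl
        if self.partitioner == "InformationGain":
            return _entropy(pos, n) - (nl / n) * _entropy(pl, nl) \
                - (nr / n) * _entropy(pr, nr)
        if self.partitioner == "Gini":
            return _gini(pos, n) - (nl / n) * _gini(pl, nl) \
                - (nr / n) * _gini(pr, nr)
        if self.partitioner == "ROC":
            # orient the split so the right child is the "positive" call
            tpr = pr / pos if pos else 0.0
            fpr = (nr - pr) / (n - pos) if n - pos else 0.0
            a = (1 + tpr - fpr) / 2.0
            return max(a, 1 - a)
        # Sequence: require at least one pure child
        pure = 0
        if pl in (0, nl):
            pure += nl
        if pr in (0, nr):
            pure += nr
        if pure == 0:
            return None
        return pure / n

    def _best_split(self, X, y):
        best = None
        for f in range(X.shape[1]):
            vals = np.unique(X[:, f])
            if len(vals) < 2:
                continue
            for t in (vals[:-1] + vals[1:]) / 2.0:
                rating = self._rate_split(y, X[:, f] < t)
                if rating is None:
                    continue
                key = (-rating, f, t)
                if best is None or key < best[0]:
                    best = (key, f, float(t), rating)
        if best is None:
            return None
        return best[1], best[2], best[3]

    def _incorrect(self, y):
        pos = int(y.sum())
        return min(pos, len(y) - pos)

    def _priority(self, rating, y, left_mask):
        incorrect = self._incorrect(y)
        if self.node_score == "SplitRating":
            return rating
        if self.node_score == "InitialNumIncorrect":
            return float(incorrect)
        if self.node_score == "RatingTimesInitialNumIncorrect":
            return rating * incorrect
        final_correct = (len(y) - self._incorrect(y[left_mask])
                         - self._incorrect(y[~left_mask]))
        return float(incorrect + final_correct)

    def fit(self, X, y):
        X = _as_2d(X)
        yv = np.asarray(y, dtype=float).ravel()
        if len(yv) == 0:
            raise ValueError("empty training set")
        yb = (yv >= self.activity_cutoff).astype(int)

        def make_leaf(rows):
            return _TreeNode(fraction=float(yb[rows].mean()),
                             count=len(rows),
                             mean_activity=float(yv[rows].mean()))

        root_rows = np.arange(len(yv))
        self.root_ = make_leaf(root_rows)
        frontier = [(self.root_, root_rows)]
        n_internal = 0
        while frontier:
            scored = []
            for node, rows in frontier:
                if self._incorrect(yb[rows]) <= self.min_split:
                    continue
                found = self._best_split(X[rows], yb[rows])
                if found is None:
                    continue
                f, t, rating = found
                prio = self._priority(rating, yb[rows], X[rows, f] < t)
                scored.append((prio, node, rows, f, t))
            if not scored:
                break
            scored.sort(key=lambda s: -s[0])
            _, node, rows, f, t = scored[0]
            if self.max_nodes is not None and n_internal >= self.max_nodes:
                break
            left_rows = rows[X[rows, f] < t]
            right_rows = rows[X[rows, f] >= t]
            node.feature = f
            node.threshold = t
            node.left = make_leaf(left_rows)
            node.right = make_leaf(right_rows)
            n_internal += 1
            frontier = [(node.left, left_rows), (node.right, right_rows)]
            frontier += [(n2, r2) for (_, n2, r2, _, _) in scored[1:]]
        self.n_features_ = X.shape[1]
        self._fitted = True
        return self

    def predict(self, X):
        self._check_fitted()
        X = _as_2d(X)
        out = np.empty(X.shape[0])
        for i, row in enumerate(X):
            node = self.root_
            while node.feature >= 0:
                node = node.left if row[node.feature] < node.threshold \
                    else node.right
            out[i] = node.fraction
        return out.reshape(-1, 1)

    def _state(self):
        def enc(node):
            if node is None:
                return None
            return {"feature": node.feature, "threshold": node.threshold,
                    "fraction": node.fraction, "count": node.count,
                    "mean_activity": node.mean_activity,
                    "left": enc(node.left), "right": enc(node.right)}
        return {"type": "DecisionTree", "params": self.get_params(),
                "n_features": self.n_features_, "root": enc(self.root_)}

    @classmethod
    def _from_state(cls, d):
        def dec(e):
            if e is None:
                return None
            return _TreeNode(e["feature"], e["threshold"], dec(e["left"]),
                             dec(e["right"]), e["fraction"], e["count"],
                             e["mean_activity"])
        m = cls(**d["params"])
        m.root_ = dec(d["root"])
        m.n_features_ = d["n_features"]
        m._fitted = True
        return m


def dt_to_logic(model: DecisionTree, feature_names=None):
    """Readable if/else text plus an equivalent descriptor expression.

    The expression sums, over all root-to-leaf paths, the product of the
    path's branch conditions times the leaf's class (its active fraction
    thresholded at 0.5), using only Add/Multiply/Less/Greater/Constant
    nodes.  It evaluates identically to ``predict >= 0.5`` except exactly at
    a split threshold, where both Less and Greater are 0.
    """
    model._check_fitted()
    if feature_names is None:
        feature_names = [f"Feature{i}" for i in range(model.n_features_)]

    lines = []

    def walk_text(node, indent):
        pad = "  " * indent
        if node.feature < 0:
            cls = int(node.fraction >= 0.5)
            lines.append(f"{pad}predict {node.fraction:.6g} "
                         f"(class {cls}, n={node.count})")
            return
        lines.append(f"{pad}if {feature_names[node.feature]} "
                     f"< {node.threshold:.6g}:")
        walk_text(node.left, indent + 1)
        lines.append(f"{pad}else:")
        walk_text(node.right, indent + 1)

    walk_text(model.root_, 0)

    terms = []

    def walk_expr(node, conds):
        if node.feature < 0:
            if node.fraction >= 0.5:
                terms.append(conds)
            return
        name = feature_names[node.feature]
        t = f"{node.threshold!r}"
        walk_expr(node.left,
                  conds + [f"Less(lhs = {name}, rhs = Constant({t}))"])
        walk_expr(node.right,
                  conds + [f"Greater(lhs = {name}, rhs = Constant({t}))"])

    walk_expr(model.root_, [])
    if not terms:
        expr = "Constant(0)"
    else:
        prods = []
        for conds in terms:
            if not conds:
                prods.append("Constant(1)")
            elif len(conds) == 1:
                prods.append(conds[0])
            else:
                prods.append("Multiply(" + ", ".join(conds) + ")")
        expr = prods[0] if len(prods) == 1 else \
            "Add(" + ", ".join(prods) + ")"
    return "\n".join(lines), expr


# ---------------------------------------------------------------------------
# linear regression
# ---------------------------------------------------------------------------

class LinearRegression(_Estimator):
    """Ridge-regularized least squares solved by Cholesky factorization of
    (X'X + lambda I); the intercept is unpenalized (data are centred)."""

    _params = ("smoothing", "scaling")

    def __init__(self, smoothing: float = 0.0, scaling: str = "none"):
        if smoothing < 0:
            raise ValueError("smoothing must be >= 0")
        self.smoothing = smoothing
        self.scaling = scaling

    def fit(self, X, y):
        X = _as_2d(X)
        Y = _as_2d(y)
        self.scaler_ = InputScaler(self.scaling).fit(X)
        Xs = self.scaler_.transform(X)
        xm = Xs.mean(axis=0)
        ym = Y.mean(axis=0)
        Xc = Xs - xm
        Yc = Y - ym
        A = Xc.T @ Xc + self.smoothing * np.eye(Xs.shape[1])
        if self.smoothing == 0 and (A.size == 0 or
                                    np.linalg.cond(A) > 1e12):
            raise np.linalg.LinAlgError(
                "singular normal equations; set smoothing > 0")
        try:
            cf = scipy.linalg.cho_factor(A)
            beta = scipy.linalg.cho_solve(cf, Xc.T @ Yc)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                "singular normal equations; set smoothing > 0") from exc
        except scipy.linalg.LinAlgError as exc:  # type: ignore[attr-defined]
            raise np.linalg.LinAlgError(
                "singular normal equations; set smoothing > 0") from exc
        self.coef_ = beta
        self.intercept_ = ym - xm @ beta
        self._fitted = True
        return self

    def predict(self, X):
        self._check_fitted()
        Xs = self.scaler_.transform(_as_2d(X))
        return Xs @ self.coef_ + self.intercept_

    def _state(self):
        return {"type": "LinearRegression", "params": self.get_params(),
                "scaler": self.scaler_.to_dict(),
                "coef": self.coef_.tolist(),
                "intercept": self.intercept_.tolist()}

    @classmethod
    def _from_state(cls, d):
        m = cls(**d["params"])
        m.scaler_ = InputScaler.from_dict(d["scaler"])
        m.coef_ = np.asarray(d["coef"], dtype=float)
        m.intercept_ = np.asarray(d["intercept"], dtype=float)
        m._fitted = True
        return m


# ---------------------------------------------------------------------------
# Kohonen self-organizing map + applicability domain
# ---------------------------------------------------------------------------

class KohonenMap(_Estimator):
    """Self-organizing map on a rectangular grid.

    The neighborhood radius decays linearly with the iteration count:
    radius(t) = radius0 * (1 - (t + 1) / (4 * length)), reaching exactly 0
    at t = 4*length - 1.  Each iteration processes one batch of
    ``steps_per_update`` rows (0 = the whole dataset); for each row the best
    matching unit (BMU) minimizes the squared Euclidean distance, and every
    node within grid radius of the BMU moves by
    w += alpha * beta * (x - w), with beta = 0.8 for the BMU and 0.2
    otherwise, and alpha = 1 (Bubble kernel) or exp(-d^2 / (2 radius^2))
    (Gaussian, d = grid distance).  Updates accumulate over the batch before
    being applied.  ``freeze_radius`` pins the radius (0 = winner-only
    updates, the online k-means limit).

    After fitting, each training row's distance to its closest node is
    retained; ``ad_score(x)`` returns the fraction of training rows whose
    own closest-node distance is strictly smaller than x's (a score of 0.90
    means farther from the map than 90% of the training data).
    """

    _params = ("map_dims", "radius0", "length", "kernel", "steps_per_update",
               "seed", "scaling", "freeze_radius")

    def __init__(self, map_dims=(10, 10), radius0=7.5, length=140,
                 kernel="Gaussian", steps_per_update=0, seed=0,
                 scaling="AveStd", freeze_radius=None):
        if kernel not in ("Bubble", "Gaussian"):
            raise ValueError(f"unknown kernel {kernel!r}")
        self.map_dims = tuple(map_dims)
        self.radius0 = radius0
        self.length = length
        self.kernel = kernel
        self.steps_per_update = steps_per_update
        self.seed = seed
        self.scaling = scaling
        self.freeze_radius = freeze_radius

    def radius_at(self, t: int) -> float:
        """Linear decay schedule; exactly 0 at the final iteration."""
        if self.freeze_radius is not None:
            return float(self.freeze_radius)
        return self.radius0 * (1.0 - (t + 1) / (4.0 * self.length))

    def fit(self, X, y=None):
        X = _as_2d(X)
        if any(d < 1 for d in self.map_dims):
            raise ValueError("map dimensions must be positive")
        if self.freeze_radius is None and self.radius0 <= 0:
            raise ValueError("initial radius must be positive")
        rng = np.random.default_rng(self.seed)
        self.scaler_ = InputScaler(self.scaling).fit(X)
        Xs = self.scaler_.transform(X)
        Y = _as_2d(y) if y is not None else np.zeros((Xs.shape[0], 1))
        nx, ny = self.map_dims
        n_nodes = nx * ny
        self.grid_ = np.array([(i, j) for i in range(nx) for j in range(ny)],
                              dtype=float)
        init_rows = rng.choice(Xs.shape[0], size=n_nodes,
                               replace=n_nodes > Xs.shape[0])
        self.weights_ = Xs[init_rows].copy()
        grid_d = np.linalg.norm(self.grid_[:, None, :]
                                - self.grid_[None, :, :], axis=2)
        n = Xs.shape[0]
        batch = n if self.steps_per_update in (0, None) \
            else min(self.steps_per_update, n)
        total_iters = 4 * self.length
        order = rng.permutation(n)
        pos = 0
        for t in range(total_iters):
            radius = self.radius_at(t)
            rows = []
            for _ in range(batch):
                if pos == n:
                    order = rng.permutation(n)
                    pos = 0
                rows.append(order[pos])
                pos += 1
            delta = np.zeros_like(self.weights_)
            for r in rows:
                x = Xs[r]
                d2 = np.sum((self.weights_ - x) ** 2, axis=1)
                bmu = int(d2.argmin())
                in_radius = grid_d[bmu] <= radius
                beta = np.where(np.arange(n_nodes) == bmu, 0.8, 0.2)
                if self.kernel == "Bubble":
                    alpha = np.ones(n_nodes)
                else:
                    if radius > 0:
                        alpha = np.exp(-grid_d[bmu] ** 2
                                       / (2.0 * radius ** 2))
                    else:
                        alpha = np.zeros(n_nodes)
                        alpha[bmu] = 1.0
                coef = np.where(in_radius, alpha * beta, 0.0)
                delta += coef[:, None] * (x - self.weights_)
            # batch updates are averaged so step size is batch-invariant
            self.weights_ += delta / len(rows)
        d = np.sqrt(((Xs[:, None, :] - self.weights_[None, :, :]) ** 2)
                    .sum(axis=2))
        closest = d.argmin(axis=1)
        self.training_distances_ = np.sort(d.min(axis=1))
        self.node_distances_ = {int(c): np.sort(d[closest == c, c])
                                for c in np.unique(closest)}
        self.node_results_ = np.array(
            [Y[closest == c].mean(axis=0) if (closest == c).any()
             else np.full(Y.shape[1], np.nan) for c in range(n_nodes)])
        self._fitted = True
        return self

    def _closest(self, X):
        Xs = self.scaler_.transform(_as_2d(X))
        d = np.sqrt(((Xs[:, None, :] - self.weights_[None, :, :]) ** 2)
                    .sum(axis=2))
        return d.argmin(axis=1), d.min(axis=1)

    def predict(self, X):
        """Mean training result of the best-matching node per row."""
        self._check_fitted()
        nodes, _ = self._closest(X)
        return self.node_results_[nodes]

    def ad_score(self, X):
        """Applicability-domain score in [0, 1] per row: the fraction of
        training rows strictly closer to the map (pooled over nodes)."""
        self._check_fitted()
        _, dist = self._closest(X)
        ranks = np.searchsorted(self.training_distances_, dist, side="left")
        return ranks / len(self.training_distances_)

    def _state(self):
        return {"type": "KohonenMap",
                "params": {k: (list(v) if isinstance(v, tuple) else v)
                           for k, v in self.get_params().items()},
                "scaler": self.scaler_.to_dict(),
                "weights": self.weights_.tolist(),
                "training_distances": self.training_distances_.tolist(),
                "node_results": self.node_results_.tolist()}

    @classmethod
    def _from_state(cls, d):
        params = dict(d["params"])
        params["map_dims"] = tuple(params["map_dims"])
        m = cls(**params)
        m.scaler_ = InputScaler.from_dict(d["scaler"])
        m.weights_ = np.asarray(d["weights"], dtype=float)
        nx, ny = m.map_dims
        m.grid_ = np.array([(i, j) for i in range(nx) for j in range(ny)],
                           dtype=float)
        m.training_distances_ = np.asarray(d["training_distances"],
                                           dtype=float)
        m.node_results_ = np.asarray(d["node_results"], dtype=float)
        m.node_distances_ = {}
        m._fitted = True
        return m


# ---------------------------------------------------------------------------
# storage
# ---------------------------------------------------------------------------

_MODEL_TYPES = {"NeuralNetwork": NeuralNetwork,
                "DecisionTree": DecisionTree,
                "LinearRegression": LinearRegression,
                "KohonenMap": KohonenMap}


def model_save(model, directory, prefix: str = "model",
               index: int = 0) -> Path:
    """Write ``<directory>/<prefix>NNNNNN.model`` as self-describing JSON
    text (a type tag plus full parameters and fitted arrays)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    path = directory / f"{prefix}{index:06d}.model"
    path.write_text(json.dumps(model._state(), indent=1))
    return path


def model_load(directory, prefix: str = "model") -> list:
    """Load every ``<prefix>NNNNNN.model`` in the directory, sorted by
    index.  Save-then-load is an identity on predictions."""
    directory = Path(directory)
    pattern = re.compile(re.escape(prefix) + r"(\d{6})\.model$")
    found = sorted((int(m.group(1)), p) for p in directory.iterdir()
                   if (m := pattern.fullmatch(p.name)))
    models = []
    for _, path in found:
        try:
            state = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise ValueError(f"{path}: corrupt model file") from exc
        tag = state.get("type")
        if tag not in _MODEL_TYPES:
            raise ValueError(f"{path}: unknown model type tag {tag!r}")
        models.append(_MODEL_TYPES[tag]._from_state(state))
    return models
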