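"""Feature datasets: generation from molecules, binary/CSV storage, and
row/column transformations (randomize, chunks, combine, balance, PCA,
k-means).

Storage is float32 ("partial binary") with fixed-width string ids; all
in-memory arithmetic is 64-bit.  The ``.bin`` format is self-describing: an
ASCII header (magic + version, id label and width, per-label feature and
result widths, row count) followed by little-endian float32 payload rows.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import descriptors as desc

__all__ = [
    "FeatureDataset",
    "PCAModel",
    "balance",
    "chunks",
    "combine",
    "generate_dataset",
    "kmeans",
    "pca_apply",
    "pca_train",
    "randomize",
    "read_bin",
    "read_csv",
    "summary",
    "write_bin",
    "write_csv",
]

_MAGIC = "moltk-bin 1"


@dataclass
class FeatureDataset:
    ids: list
    X: np.ndarray
    Y: np.ndarray
    feature_labels: list
    result_labels: list
    id_label: str = "ID"
    result_mask: np.ndarray | None = None  # True where a result is present

    def __post_init__(self):
        self.X = np.ascontiguousarray(np.asarray(self.X, dtype=np.float32))
        self.Y = np.ascontiguousarray(np.asarray(self.Y, dtype=np.float32))
        if self.X.ndim != 2 or self.Y.ndim != 2:
            raise ValueError("X and Y must be 2-D")
        n = self.X.shape[0]
        if self.Y.shape[0] != n or len(self.ids) != n:
            raise ValueError("row counts of ids, X, Y differ")
        if len(self.feature_labels) != self.X.shape[1]:
            raise ValueError("feature label count != feature columns")
        if len(self.result_labels) != self.Y.shape[1]:
            raise ValueError("result label count != result columns")
        width = max((len(i) for i in self.ids), default=1)
        self.ids = [str(i).ljust(width) for i in self.ids]
        if self.result_mask is None:
            self.result_mask = ~np.isnan(self.Y)
        self.result_mask = np.asarray(self.result_mask, dtype=bool)
        if self.result_mask.shape != self.Y.shape:
            raise ValueError("result mask shape mismatch")

    @property
    def n_rows(self):
        return self.X.shape[0]

    @property
    def n_features(self):
        return self.X.shape[1]

    @property
    def n_results(self):
        return self.Y.shape[1]

    @property
    def id_width(self):
        return max((len(i) for i in self.ids), default=1)

    def select_rows(self, indices) -> "FeatureDataset":
        idx = np.asarray(indices, dtype=int)
        return FeatureDataset([self.ids[i] for i in idx], self.X[idx],
                              self.Y[idx], list(self.feature_labels),
                              list(self.result_labels), self.id_label,
                              self.result_mask[idx])


def _column_labels(spec) -> list:
    """One label per output column of a descriptor spec (probe-free for
    fixed-arity nodes; multi-column nodes get indexed labels)."""
    if spec.kind == "operator" and spec.name == "Combine":
        out = []
        for c in spec.children:
            out.extend(_column_labels(c))
        return out
    text = desc.serialize_descriptor(spec)
    return [text]


def generate_dataset(mols, feature_spec, result_spec="Constant(0)",
                     id_label="Name", forbid_incomplete=False,
                     strict=False) -> FeatureDataset:
    """One row per molecule: X from ``feature_spec``, Y from ``result_spec``.

    A result label naming an MDL property on the molecule reads that property
    (missing values are masked); otherwise the result is computed as a
    descriptor.  With ``forbid_incomplete`` rows missing any result value are
    dropped.  A feature-evaluation failure drops the row with a warning
    (lenient) or raises (``strict``).
    """
    aliases = {}
    if isinstance(feature_spec, str):
        feature_spec = desc.parse_descriptor(feature_spec, aliases)
    result_names = ([s.strip() for s in result_spec.split(",")]
                    if isinstance(result_spec, str) and
                    "(" not in result_spec and "[" not in result_spec
                    else None)
    result_tree = None
    if result_names is None:
        result_tree = (desc.parse_descriptor(result_spec, aliases)
                       if isinstance(result_spec, str) else result_spec)
    ids, rows_x, rows_y, rows_m = [], [], [], []
    feat_labels = None
    for mi, mol in enumerate(mols):
        try:
            x = desc.evaluate(feature_spec, mol)
        except Exception as exc:
            if strict:
                raise
            warnings.warn(f"molecule {mi} ({mol.name!r}): feature "
                          f"evaluation failed ({exc}); row dropped")
            continue
        if feat_labels is None:
            labels = _column_labels(feature_spec)
            if len(labels) != x.size:
                labels = [f"{labels[0] if len(labels) == 1 else 'f'}[{i}]"
                          for i in range(x.size)]
            feat_labels = labels
        y, m = [], []
        if result_names is not None:
            for name in result_names:
                if name in mol.properties:
                    try:
                        y.append(float(str(mol.properties[name]).split()[0]))
                        m.append(True)
                    except ValueError:
                        y.append(np.nan)
                        m.append(False)
                elif name in desc.MOLECULE_PROPERTIES:
                    y.append(float(desc.MOLECULE_PROPERTIES[name](mol)))
                    m.append(True)
                else:
                    y.append(np.nan)
                    m.append(False)
        else:
            yv = desc.evaluate(result_tree, mol)
            y = list(map(float, yv))
            m = [not math.isnan(v) for v in y]
        if forbid_incomplete and not all(m):
            continue
        if id_label == "Name" or id_label not in mol.properties:
            ids.append(mol.name if id_label == "Name"
                       else str(mol.properties.get(id_label, mol.name)))
        else:
            ids.append(str(mol.properties[id_label]))
        rows_x.append(x)
        rows_y.append(y)
        rows_m.append(m)
    n_feat = len(feat_labels) if feat_labels else 0
    n_res = len(rows_y[0]) if rows_y else (
        len(result_names) if result_names else 1)
    res_labels = (result_names if result_names is not None
                  else _column_labels(result_tree))
    if len(res_labels) != n_res:
        res_labels = [f"{res_labels[0]}[{i}]" for i in range(n_res)]
    X = np.array(rows_x, dtype=np.float32).reshape(len(rows_x), n_feat)
    Y = np.array(rows_y, dtype=np.float32).reshape(len(rows_y), n_res)
    M = np.array(rows_m, dtype=bool).reshape(len(rows_m), n_res)
    return FeatureDataset(ids, X, Y, feat_labels or [], res_labels,
                          id_label, M)


# ---------------------------------------------------------------------------
# binary format
# ---------------------------------------------------------------------------

def write_bin(ds: FeatureDataset, path) -> None:
    header = [_MAGIC,
              f"id {ds.id_label} {ds.id_width}",
              f"features {ds.n_features}"]
    header += [f"{lab} 4" for lab in ds.feature_labels]
    header.append(f"results {ds.n_results}")
    header += [f"{lab} 4" for lab in ds.result_labels]
    header.append(f"rows {ds.n_rows}")
    header.append("end")
    payload = bytearray()
    w = ds.id_width
    for i in range(ds.n_rows):
        payload += ds.ids[i].ljust(w).encode("ascii")
        payload += ds.X[i].astype("<f4").tobytes()
        payload += ds.Y[i].astype("<f4").tobytes()
        payload += ds.result_mask[i].astype(np.uint8).tobytes()
    Path(path).write_bytes(("\n".join(header) + "\n").encode("ascii")
                           + bytes(payload))


def read_bin(path) -> FeatureDataset:
    raw = Path(path).read_bytes()
    end = raw.find(b"end\n")
    if not raw.startswith(_MAGIC.encode()) or end < 0:
        raise ValueError(f"{path}: not a recognized dataset file "
                         "(bad magic or missing header terminator)")
    lines = raw[:end].decode("ascii").splitlines()
    it = iter(lines[1:])
    id_line = next(it).split()
    id_label, id_width = " ".join(id_line[1:-1]), int(id_line[-1])
    n_feat = int(next(it).split()[1])
    feat_labels = [" ".join(next(it).split()[:-1]) for _ in range(n_feat)]
    n_res = int(next(it).split()[1])
    res_labels = [" ".join(next(it).split()[:-1]) for _ in range(n_res)]
    n_rows = int(next(it).split()[1])
    offset = end + 4
    row_bytes = id_width + 4 * n_feat + 4 * n_res + n_res
    need = n_rows * row_bytes
    if len(raw) - offset < need:
        raise ValueError(f"{path}: truncated payload at byte "
                         f"{len(raw)} (need {offset + need})")
    ids, X, Y, M = [], [], [], []
    pos = offset
    for _ in range(n_rows):
        ids.append(raw[pos:pos + id_width].decode("ascii"))
        pos += id_width
        X.append(np.frombuffer(raw, "<f4", n_feat, pos))
        pos += 4 * n_feat
        Y.append(np.frombuffer(raw, "<f4", n_res, pos))
        pos += 4 * n_res
        M.append(np.frombuffer(raw, np.uint8, n_res, pos).astype(bool))
        pos += n_res
    X = np.array(X, dtype=np.float32).reshape(n_rows, n_feat)
    Y = np.array(Y, dtype=np.float32).reshape(n_rows, n_res)
    M = np.array(M, dtype=bool).reshape(n_rows, n_res)
    return FeatureDataset(ids, X, Y, feat_labels, res_labels, id_label, M)


# ---------------------------------------------------------------------------
# CSV
# ---------------------------------------------------------------------------

def _fmt32(v: np.float32) -> str:
    if np.isnan(v):
        return "nan"
    return np.format_float_positional(np.float32(v), unique=True, trim="0")


def write_csv(ds: FeatureDataset, path) -> None:
    """Rows of ``id,features...,results...`` with float32-exact formatting
    and no header line (labels are not representable in plain CSV)."""
    with open(path, "w") as fh:
        for i in range(ds.n_rows):
            vals = [_fmt32(v) for v in ds.X[i]]
            vals += [_fmt32(v) if ds.result_mask[i, j] else "nan"
                     for j, v in enumerate(ds.Y[i])]
            fh.write(",".join([ds.ids[i]] + vals) + "\n")


def read_csv(path, number_result_cols: int = 1, number_id_chars: int = 2,
             feature_labels=None, result_labels=None,
             id_label="ID") -> FeatureDataset:
    """First field is a fixed-width id; the last ``number_result_cols``
    numeric columns are results.  Placeholder labels f0..fN-1 / r0..rM-1 are
    generated unless supplied."""
    ids, rows = [], []
    for ln, line in enumerate(Path(path).read_text().splitlines()):
        if not line.strip():
            continue
        parts = line.split(",")
        ident = parts[0]
        if len(ident) != number_id_chars:
            raise ValueError(f"{path}:{ln + 1}: id {ident!r} is not "
                             f"{number_id_chars} characters wide")
        try:
            vals = [np.float32(p) for p in parts[1:]]
        except ValueError as exc:
            raise ValueError(f"{path}:{ln + 1}: non-numeric field") from exc
        if rows and len(vals) != len(rows[0]):
            raise ValueError(f"{path}:{ln + 1}: ragged row "
                             f"({len(vals)} fields, expected {len(rows[0])})")
        ids.append(ident)
        rows.append(vals)
    arr = np.array(rows, dtype=np.float32).reshape(len(rows),
                                                   len(rows[0]) if rows else 0)
    n_res = number_result_cols
    n_feat = arr.shape[1] - n_res
    if n_feat < 0:
        raise ValueError("fewer columns than number_result_cols")
    X, Y = arr[:, :n_feat], arr[:, n_feat:]
    if feature_labels is None:
        feature_labels = [f"f{i}" for i in range(n_feat)]
    if result_labels is None:
        result_labels = [f"r{i}" for i in range(n_res)]
    return FeatureDataset(ids, X, Y, list(feature_labels),
                          list(result_labels), id_label)


# ---------------------------------------------------------------------------
# transformations
# ---------------------------------------------------------------------------

def randomize(ds: FeatureDataset, seed: int) -> FeatureDataset:
    perm = np.random.default_rng(seed).permutation(ds.n_rows)
    return ds.select_rows(perm)


def chunks(ds: FeatureDataset, number_chunks: int, selected) -> FeatureDataset:
    """Divide rows into ``number_chunks`` nearly equal contiguous blocks
    (block b spans rows floor(b*n/k)..floor((b+1)*n/k)) and concatenate the
    selected blocks in ascending block order."""
    n, k = ds.n_rows, number_chunks
    if not 1 <= k <= max(n, 1):
        raise ValueError(f"number_chunks {k} outside 1..{n}")
    sel = sorted(set(int(s) for s in selected))
    if sel and (sel[0] < 0 or sel[-1] >= k):
        raise ValueError(f"chunk index out of range 0..{k - 1}")
    rows = []
    for b in sel:
        rows.extend(range(b * n // k, (b + 1) * n // k))
    return ds.select_rows(rows)


def combine(datasets, axis: str = "columns") -> FeatureDataset:
    """columns: join feature columns over identical id sequences, keeping the
    first dataset's results; rows: stack rows of identically labelled sets."""
    if not datasets:
        raise ValueError("nothing to combine")
    first = datasets[0]
    if axis == "columns":
        for d in datasets[1:]:
            if [i.strip() for i in d.ids] != [i.strip() for i in first.ids]:
                raise ValueError("id sequences differ; cannot combine columns")
        X = np.hstack([d.X for d in datasets])
        labels = [lab for d in datasets for lab in d.feature_labels]
        return FeatureDataset(list(first.ids), X, first.Y.copy(), labels,
                              list(first.result_labels), first.id_label,
                              first.result_mask.copy())
    if axis == "rows":
        for d in datasets[1:]:
            if d.feature_labels != first.feature_labels or \
                    d.result_labels != first.result_labels:
                raise ValueError("labels differ; cannot combine rows")
        return FeatureDataset(
            [i for d in datasets for i in d.ids],
            np.vstack([d.X for d in datasets]),
            np.vstack([d.Y for d in datasets]),
            list(first.feature_labels), list(first.result_labels),
            first.id_label, np.vstack([d.result_mask for d in datasets]))
    raise ValueError(f"unknown axis {axis!r}")


def balance(ds: FeatureDataset, target_ratio: float = 0.1,
            max_repeats: int = 100, cutoff: float = 0.5,
            seed: int = 0) -> FeatureDataset:
    """Oversample the minor class of a binary result column (class = first
    result >= cutoff) until minor/major >= target_ratio, repeating no row more
    than ``max_repeats`` times; output rows are shuffled (seeded)."""
    if ds.n_results != 1:
        raise ValueError("balance expects a single result column")
    cls = ds.Y[:, 0] >= cutoff
    pos = np.flatnonzero(cls)
    neg = np.flatnonzero(~cls)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("one class is empty; cannot balance")
    minor, major = (pos, neg) if len(pos) <= len(neg) else (neg, pos)
    rng = np.random.default_rng(seed)
    needed = int(math.ceil(target_ratio * len(major)))
    target = max(needed, len(minor))
    cap = max_repeats * len(minor)
    if target > cap:
        warnings.warn(f"balance: target ratio {target_ratio} needs "
                      f"{target} minor rows but max_repeats allows {cap}")
        target = cap
    order = minor[rng.permutation(len(minor))]
    reps = [order[i % len(minor)] for i in range(target)]
    rows = np.concatenate([major, np.asarray(reps, dtype=int)])
    rows = rows[rng.permutation(len(rows))]
    return ds.select_rows(rows)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAModel:
    means: np.ndarray
    eigenvectors: np.ndarray  # columns, descending eigenvalue
    eigenvalues: np.ndarray


def pca_train(ds: FeatureDataset) -> PCAModel:
    if ds.n_rows < 2:
        raise ValueError("PCA needs at least 2 rows")
    X = ds.X.astype(np.float64)
    means = X.mean(axis=0)
    cov = np.cov(X - means, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    return PCAModel(means, vecs[:, order], np.maximum(vals[order], 0.0))


def pca_apply(ds: FeatureDataset, model: PCAModel,
              fraction: float = 0.95) -> FeatureDataset:
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    total = model.eigenvalues.sum()
    if total <= 0:
        k = 1
    else:
        cum = np.cumsum(model.eigenvalues) / total
        k = int(np.searchsorted(cum, fraction - 1e-12) + 1)
    proj = (ds.X.astype(np.float64) - model.means) @ model.eigenvectors[:, :k]
    return FeatureDataset(list(ds.ids), proj.astype(np.float32),
                          ds.Y.copy(), [f"pc{i}" for i in range(k)],
                          list(ds.result_labels), ds.id_label,
                          ds.result_mask.copy())


# ---------------------------------------------------------------------------
# k-means
# ---------------------------------------------------------------------------

def _kmeans_pp_init(X, k, rng):
    n = X.shape[0]
    centers = [X[rng.integers(n)]]
    for _ in range(1, k):
        d2 = np.min([np.sum((X - c) ** 2, axis=1) for c in centers], axis=0)
        total = d2.sum()
        if total <= 0:
            centers.append(X[rng.integers(n)])
            continue
        centers.append(X[rng.choice(n, p=d2 / total)])
    return np.array(centers)


def kmeans(ds: FeatureDataset, k: int, seed: int = 0,
           max_iter: int = 300) -> FeatureDataset:
    """Lloyd's algorithm with seeded k-means++ initialization.  Returns a
    dataset of k centroid rows; Y is the per-cluster mean result and ids are
    synthesized C000000..  An emptied cluster is re-seeded from the point
    farthest from its centroid."""
    if not 1 <= k <= ds.n_rows:
        raise ValueError(f"k={k} outside 1..{ds.n_rows}")
    X = ds.X.astype(np.float64)
    rng = np.random.default_rng(seed)
    centers = _kmeans_pp_init(X, k, rng)
    assign = None
    for _ in range(max_iter):
        d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        new_assign = d2.argmin(axis=1)
        for c in range(k):
            members = new_assign == c
            if members.any():
                centers[c] = X[members].mean(axis=0)
            else:
                far = d2.min(axis=1).argmax()
                centers[c] = X[far]
                new_assign[far] = c
        if assign is not None and np.array_equal(assign, new_assign):
            break
        assign = new_assign
    Y = np.zeros((k, ds.n_results))
    for c in range(k):
        members = assign == c
        Y[c] = ds.Y[members].astype(np.float64).mean(axis=0) \
            if members.any() else np.nan
    ids = [f"C{i:06d}" for i in range(k)]
    return FeatureDataset(ids, centers.astype(np.float32),
                          Y.astype(np.float32), list(ds.feature_labels),
                          list(ds.result_labels), ds.id_label)


# ---------------------------------------------------------------------------
# summary
# ---------------------------------------------------------------------------

def summary(ds: FeatureDataset) -> dict:
    """Row count, per-column mean/SD (population), and result density."""
    X = ds.X.astype(np.float64)
    return {
        "rows": ds.n_rows,
        "feature_mean": X.mean(axis=0).tolist() if ds.n_rows else [],
        "feature_sd": X.std(axis=0).tolist() if ds.n_rows else [],
        "result_density": (ds.result_mask.mean(axis=0).tolist()
                           if ds.n_rows else []),
    }
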