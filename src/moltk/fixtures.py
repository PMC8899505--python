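"""Bundled reference structures and seeded synthetic data generators.

The molecule registry embeds canonical small molecules and drug structures
as V2000 connection tables so that every example and test runs offline.
``synthetic_qsar`` fabricates feature datasets with known ground truth for
model-recovery checks, standing in for large public screening datasets.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np

from ._structures import SDF_BLOCKS
from .dataset import FeatureDataset
from .graph import MoleculeGraph
from .sdf import read_sdf_string

__all__ = [
    "SyntheticQSARSpec",
    "builtin_molecule",
    "builtin_names",
    "random_molecule",
    "registry_checksum",
    "synthetic_qsar",
]


def builtin_names() -> list:
    return sorted(SDF_BLOCKS)


def builtin_molecule(name: str) -> MoleculeGraph:
    """A fresh parse of a registry structure (callers may mutate freely)."""
    if name not in SDF_BLOCKS:
        raise KeyError(f"unknown builtin molecule {name!r}; "
                       f"available: {', '.join(builtin_names())}")
    return read_sdf_string(SDF_BLOCKS[name], strict=True)[0]


def registry_checksum() -> str:
    """SHA-256 over the registry in name order; pins the structures that the
    similarity worked-example numbers depend on."""
    h = hashlib.sha256()
    for name in sorted(SDF_BLOCKS):
        h.update(name.encode())
        h.update(SDF_BLOCKS[name].encode())
    return h.hexdigest()


_VALENCE = {"C": 4, "N": 3, "O": 2}


def random_molecule(seed: int, size_range=(3, 12)) -> MoleculeGraph:
    """Seeded random valence-legal molecule over {C, N, O}.

    Grows a random tree (occasionally closing one ring and upgrading some
    bonds to double where valence allows), with random coordinates, for
    fuzzing parsers, uniqueness and descriptor code paths.
    """
    lo, hi = size_range
    if lo < 1 or hi < lo:
        raise ValueError("invalid size range")
    rng = np.random.default_rng(seed)
    n = int(rng.integers(lo, hi + 1))
    mol = MoleculeGraph(name=f"random-{seed}")
    elements = rng.choice(["C", "C", "C", "N", "O"], size=n)
    remaining = []
    for i in range(n):
        mol.add_atom(str(elements[i]), 0, tuple(rng.normal(size=3) * 2.0))
        remaining.append(_VALENCE[str(elements[i])])
    for i in range(1, n):
        j = int(rng.integers(0, i))
        tries = 0
        while remaining[j] < 1 and tries < n:
            j = int(rng.integers(0, i))
            tries += 1
        if remaining[j] < 1:
            j = max(range(i), key=lambda k: remaining[k])
        order = 1
        if remaining[i] >= 2 and remaining[j] >= 2 and rng.random() < 0.15:
            order = 2
        mol.add_bond(i, j, order)
        remaining[i] -= order
        remaining[j] -= order
    # close one ring when possible
    if n >= 3 and rng.random() < 0.5:
        cands = [(i, j) for i in range(n) for j in range(i + 2, n)
                 if remaining[i] >= 1 and remaining[j] >= 1
                 and mol.bond_between(i, j) is None]
        if cands:
            i, j = cands[int(rng.integers(0, len(cands)))]
            mol.add_bond(i, j, 1)
            remaining[i] -= 1
            remaining[j] -= 1
    from .graph import perceive_rings_and_aromaticity
    perceive_rings_and_aromaticity(mol)
    return mol


@dataclass
class SyntheticQSARSpec:
    """Seeded synthetic feature dataset with known generating rule.

    Features are standard normal; the latent score is w.x (optionally
    squashed by tanh) plus Gaussian noise of ``noise_sd``.  For
    classification the activity threshold is placed so that exactly
    ``n_actives`` of the rows score above it (then ``label_noise`` flips
    labels at random); for regression Y is the noisy latent score itself.
    """
    n_actives: int = 50
    n_inactives: int = 450
    n_features: int = 10
    noise_sd: float = 0.0
    nonlinearity: str = "linear"
    label_noise: float = 0.0
    task: str = "classification"
    seed: int = 0

    def __post_init__(self):
        if self.n_actives < 1 or self.n_inactives < 1:
            raise ValueError("class counts must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise SD must be >= 0")
        if self.nonlinearity not in ("linear", "tanh"):
            raise ValueError(f"unknown nonlinearity {self.nonlinearity!r}")
        if self.task not in ("classification", "regression"):
            raise ValueError(f"unknown task {self.task!r}")


def synthetic_qsar(spec: SyntheticQSARSpec):
    """Returns (FeatureDataset, truth) with truth = {weights, threshold,
    scores} for parameter-recovery tests."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_actives + spec.n_inactives
    w = rng.normal(size=spec.n_features)
    X = rng.normal(size=(n, spec.n_features))
    score = X @ w
    if spec.nonlinearity == "tanh":
        score = np.tanh(score)
    score = score + rng.normal(scale=spec.noise_sd, size=n) \
        if spec.noise_sd > 0 else score
    if spec.task == "regression":
        Y = score.reshape(-1, 1)
        threshold = float("nan")
    else:
        order = np.sort(score)[::-1]
        threshold = float((order[spec.n_actives - 1]
                           + order[spec.n_actives]) / 2.0) \
            if spec.n_actives < n else float(order[-1] - 1.0)
        labels = (score > threshold).astype(float)
        if spec.label_noise > 0:
            flip = rng.random(n) < spec.label_noise
            labels = np.where(flip, 1.0 - labels, labels)
        Y = labels.reshape(-1, 1)
    width = len(str(n - 1))
    ids = [f"{i:0{width}d}" for i in range(n)]
    ds = FeatureDataset(ids, X.astype(np.float32), Y.astype(np.float32),
                        [f"f{i}" for i in range(spec.n_features)],
                        ["Activity"], "ID")
    truth = {"weights": w, "threshold": threshold, "scores": score}
    return ds, truth
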