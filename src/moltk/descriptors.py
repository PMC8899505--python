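"""Composable molecular descriptors.

A descriptor is a small expression tree ("code object") built from named
properties, operators and constants, parsed from a text grammar in which
``(``, ``[`` and ``{`` are interchangeable::

    Combine (Weight, LogP, HbondDonor, HbondAcceptor)
    Define [VeberDruglike = Less (lhs = LipinskiViolationsVeber, rhs = 1)]
    2DASmoothSign (property = Atom_SigmaCharge, steps = 11)

Molecule-level properties evaluate to length-1 vectors, atomic properties to
one value per atom in index order, and ``Combine`` concatenates.  Evaluation
never mutates the molecule and is deterministic.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .graph import ATOMIC_MASS, MoleculeGraph, add_hydrogens, sssr

__all__ = [
    "AutocorrelationConfig",
    "DescriptorError",
    "DescriptorSpec",
    "ParseError",
    "autocorrelation",
    "evaluate",
    "parse_descriptor",
    "serialize_descriptor",
    "MOLECULE_PROPERTIES",
    "ATOMIC_PROPERTIES",
]


class DescriptorError(ValueError):
    """Evaluation failure (property undefined for a molecule, etc.)."""


class ParseError(ValueError):
    def __init__(self, message, position=None):
        if position is not None:
            message = f"{message} (at position {position})"
        super().__init__(message)
        self.position = position


# ---------------------------------------------------------------------------
# named molecule properties
# ---------------------------------------------------------------------------

def weight(mol: MoleculeGraph) -> float:
    """Molecular weight including implicit hydrogens."""
    return mol.molecular_weight()


def hbond_donor(mol: MoleculeGraph) -> int:
    """Heavy N/O atoms bearing at least one hydrogen (each counted once)."""
    return sum(1 for a in mol.atoms
               if a.element in ("N", "O") and mol.total_hydrogens(a.index) > 0)


def hbond_acceptor(mol: MoleculeGraph) -> int:
    """Count of N and O atoms."""
    return sum(1 for a in mol.atoms if a.element in ("N", "O"))


def n_rot_bond(mol: MoleculeGraph) -> int:
    """Non-ring single bonds between heavy atoms of heavy-degree >= 2,
    excluding amide C-N bonds."""
    heavy_degree = {a.index: sum(1 for n in mol.neighbors(a.index)
                                 if mol.atoms[n].element != "H")
                    for a in mol.atoms}
    count = 0
    for b in mol.bonds:
        if b.order != 1 or b.aromatic or b.in_ring or b.amide:
            continue
        e1, e2 = mol.atoms[b.a1].element, mol.atoms[b.a2].element
        if e1 == "H" or e2 == "H":
            continue
        if heavy_degree[b.a1] >= 2 and heavy_degree[b.a2] >= 2:
            count += 1
    return count


def n_rings(mol: MoleculeGraph) -> int:
    return len(sssr(mol))


def n_aromatic_rings(mol: MoleculeGraph) -> int:
    return sum(1 for ring in sssr(mol)
               if all(mol.atoms[i].aromatic for i in ring))


def log_p(mol: MoleculeGraph) -> float:
    """Mannhold atom-count estimate: 1.46 + 0.11 nC - 0.11 nHET."""
    n_c = sum(1 for a in mol.atoms if a.element == "C")
    n_het = sum(1 for a in mol.atoms if a.element not in ("C", "H"))
    return 1.46 + 0.11 * n_c - 0.11 * n_het


# ---------------------------------------------------------------------------
# Ertl topological polar surface area
# ---------------------------------------------------------------------------
# Fragment contributions from Ertl, Rohde & Selzer (2000).  Keys:
#   aliphatic: (element, charge, nH, n_single, n_double, n_triple, in_3ring)
#   aromatic:  ("ar", element, charge, nH, n_aromatic_bonds, n_extra_single,
#               n_extra_double)

_TPSA_ALIPHATIC = {
    ("N", 0, 0, 3, 0, 0, False): 3.24,
    ("N", 0, 0, 3, 0, 0, True): 3.01,
    ("N", 0, 0, 1, 1, 0, False): 12.36,
    ("N", 0, 0, 1, 1, 0, True): 12.36,
    ("N", 0, 0, 0, 0, 1, False): 23.79,
    ("N", 0, 0, 1, 2, 0, False): 11.68,
    ("N", 0, 0, 0, 1, 1, False): 13.60,
    ("N", 0, 1, 2, 0, 0, False): 12.03,
    ("N", 0, 1, 2, 0, 0, True): 21.94,
    ("N", 0, 1, 0, 1, 0, False): 23.85,
    ("N", 0, 2, 1, 0, 0, False): 26.02,
    ("N", 1, 0, 4, 0, 0, False): 0.00,
    ("N", 1, 0, 2, 1, 0, False): 3.01,
    ("N", 1, 0, 0, 0, 1, False): 4.36,
    ("N", 1, 1, 3, 0, 0, False): 4.44,
    ("N", 1, 1, 1, 1, 0, False): 13.97,
    ("N", 1, 2, 2, 0, 0, False): 16.61,
    ("N", 1, 2, 0, 1, 0, False): 25.59,
    ("N", 1, 3, 1, 0, 0, False): 27.64,
    ("O", 0, 0, 2, 0, 0, False): 9.23,
    ("O", 0, 0, 2, 0, 0, True): 12.53,
    ("O", 0, 0, 0, 1, 0, False): 17.07,
    ("O", 0, 1, 1, 0, 0, False): 20.23,
    ("O", -1, 0, 1, 0, 0, False): 23.06,
    ("S", 0, 0, 2, 0, 0, False): 25.30,
    ("S", 0, 0, 0, 1, 0, False): 32.09,
    ("S", 0, 0, 2, 1, 0, False): 19.21,
    ("S", 0, 0, 2, 2, 0, False): 8.38,
    ("S", 0, 1, 1, 0, 0, False): 38.80,
    ("P", 0, 0, 3, 0, 0, False): 13.59,
    ("P", 0, 0, 1, 1, 0, False): 34.14,
    ("P", 0, 0, 3, 1, 0, False): 9.81,
    ("P", 0, 1, 2, 1, 0, False): 23.47,
}

_TPSA_AROMATIC = {
    ("N", 0, 0, 2, 0, 0): 12.89,
    ("N", 0, 0, 3, 0, 0): 4.41,
    ("N", 0, 0, 2, 1, 0): 4.93,
    ("N", 0, 0, 2, 0, 1): 8.39,
    ("N", 0, 1, 2, 0, 0): 15.79,
    ("N", 1, 0, 3, 0, 0): 4.10,
    ("N", 1, 0, 2, 1, 0): 3.88,
    ("N", 1, 1, 2, 0, 0): 14.14,
    ("O", 0, 0, 2, 0, 0): 13.14,
    ("S", 0, 0, 2, 0, 0): 28.24,
    ("S", 0, 0, 2, 0, 1): 21.70,
}

_TPSA_ELEMENTS_DEFAULT = frozenset({"N", "O"})


def atom_tpsa(mol: MoleculeGraph, include_sp: bool = False) -> np.ndarray:
    """Per-atom Ertl polar-surface-area contribution.

    N and O contribute by default; ``include_sp`` adds the S and P fragment
    values.  Atoms that match no published fragment contribute 0.
    """
    elements = (_TPSA_ELEMENTS_DEFAULT | {"S", "P"}) if include_sp \
        else _TPSA_ELEMENTS_DEFAULT
    three_ring = set()
    for ring in sssr(mol):
        if len(ring) == 3:
            three_ring.update(ring)
    out = np.zeros(mol.n_atoms)
    for a in mol.atoms:
        if a.element not in elements:
            continue
        n_h = mol.total_hydrogens(a.index)
        if a.aromatic:
            n_ar = n_s = n_d = 0
            for b in mol.bonds_of(a.index):
                other = mol.atoms[b.other(a.index)]
                if other.element == "H":
                    continue
                if b.aromatic:
                    n_ar += 1
                elif b.order == 1:
                    n_s += 1
                elif b.order == 2:
                    n_d += 1
            out[a.index] = _TPSA_AROMATIC.get(
                (a.element, a.formal_charge, n_h, n_ar, n_s, n_d), 0.0)
        else:
            n_s = n_d = n_t = 0  # non-H connections; H count is keyed apart
            for b in mol.bonds_of(a.index):
                if mol.atoms[b.other(a.index)].element == "H":
                    continue
                if b.order == 1:
                    n_s += 1
                elif b.order == 2:
                    n_d += 1
                elif b.order == 3:
                    n_t += 1
            key = (a.element, a.formal_charge, n_h, n_s, n_d, n_t,
                   a.index in three_ring)
            if key not in _TPSA_ALIPHATIC:
                key = key[:-1] + (False,)
            out[a.index] = _TPSA_ALIPHATIC.get(key, 0.0)
    return out


def tpsa(mol: MoleculeGraph, include_sp: bool = False) -> float:
    return float(atom_tpsa(mol, include_sp=include_sp).sum())


# ---------------------------------------------------------------------------
# Gasteiger-Marsili sigma charges (PEOE)
# ---------------------------------------------------------------------------
# Electronegativity chi = a + b q + c q^2 per (element, hybridization).

_PEOE_PARAMS = {
    ("H", "s"): (7.17, 6.24, -0.56),
    ("C", "sp3"): (7.98, 9.18, 1.88),
    ("C", "sp2"): (8.79, 9.32, 1.51),
    ("C", "sp"): (10.39, 9.45, 0.73),
    ("N", "sp3"): (11.54, 10.82, 1.36),
    ("N", "sp2"): (12.87, 11.15, 0.85),
    ("N", "sp"): (15.68, 11.70, -0.27),
    ("O", "sp3"): (14.18, 12.92, 1.39),
    ("O", "sp2"): (17.07, 13.79, 0.47),
    ("F", "sp3"): (14.66, 13.85, 2.31),
    ("Cl", "sp3"): (11.00, 9.69, 1.35),
    ("Br", "sp3"): (10.08, 8.47, 1.16),
    ("I", "sp3"): (9.90, 7.96, 0.96),
    ("S", "sp3"): (10.14, 9.13, 1.38),
    ("S", "sp2"): (10.88, 9.49, 1.33),
}

_H_CATION_CHI = 20.02


def _peoe_hybridization(mol, idx):
    a = mol.atoms[idx]
    if a.element == "H":
        return "s"
    bonds = [b for b in mol.bonds_of(idx)]
    if any(b.order == 3 for b in bonds):
        return "sp"
    n_double = sum(1 for b in bonds if b.order == 2)
    if n_double >= 2:
        return "sp"
    if n_double == 1 or a.aromatic:
        return "sp2"
    if a.element in ("N", "O", "S"):
        # lone-pair donor conjugated into an adjacent pi system
        for j in mol.neighbors(idx):
            nb = mol.atoms[j]
            if nb.aromatic or any(b.order > 1 for b in mol.bonds_of(j)):
                return "sp2"
    return "sp3"


def atom_sigma_charge(mol: MoleculeGraph, n_iterations: int = 6) -> np.ndarray:
    """Partial-equalization (Gasteiger-Marsili) sigma charges.

    Implicit hydrogens are added internally and their converged charges are
    folded back into the parent heavy atom, so the returned vector has one
    entry per input atom and sums to the total formal charge.
    """
    work = add_hydrogens(mol.copy())
    parent = {}  # index of added H -> heavy parent
    for i in range(mol.n_atoms, work.n_atoms):
        parent[i] = work.neighbors(i)[0]
    params = []
    for a in work.atoms:
        key = (a.element, _peoe_hybridization(work, a.index))
        if key not in _PEOE_PARAMS:
            raise DescriptorError(
                f"molecule {mol.name!r}: Atom_SigmaCharge has no "
                f"electronegativity parameters for {key}")
        params.append(_PEOE_PARAMS[key])
    q = np.array([float(a.formal_charge) for a in work.atoms])
    chi_plus = np.array([_H_CATION_CHI if a.element == "H" else sum(p)
                         for a, p in zip(work.atoms, params)])
    abc = np.array(params)
    pairs = [(b.a1, b.a2) for b in work.bonds]
    for k in range(1, n_iterations + 1):
        chi = abc[:, 0] + abc[:, 1] * q + abc[:, 2] * q * q
        damp = 0.5 ** k
        dq = np.zeros_like(q)
        for i, j in pairs:
            if chi[j] > chi[i]:
                flow = (chi[j] - chi[i]) / chi_plus[i] * damp
                dq[i] += flow
                dq[j] -= flow
            elif chi[i] > chi[j]:
                flow = (chi[i] - chi[j]) / chi_plus[j] * damp
                dq[j] += flow
                dq[i] -= flow
        q = q + dq
    out = q[:mol.n_atoms].copy()
    for h_idx, heavy in parent.items():
        out[heavy] += q[h_idx]
    return out


def atom_mass(mol: MoleculeGraph) -> np.ndarray:
    return np.array([ATOMIC_MASS[a.element] for a in mol.atoms])


# ---------------------------------------------------------------------------
# druglikeness
# ---------------------------------------------------------------------------

def lipinski_violations(mol: MoleculeGraph) -> int:
    """Failures of {HBD <= 5, HBA <= 10, MW < 500, logP < 5}."""
    v = 0
    v += hbond_donor(mol) > 5
    v += hbond_acceptor(mol) > 10
    v += weight(mol) >= 500
    v += log_p(mol) >= 5
    return int(v)


def lipinski_violations_veber(mol: MoleculeGraph) -> int:
    """Failures of {TPSA < 140, NRotBond <= 10}."""
    return int(tpsa(mol) >= 140) + int(n_rot_bond(mol) > 10)


def lipinski_druglike(mol: MoleculeGraph) -> int:
    return int(lipinski_violations(mol) < 2)


MOLECULE_PROPERTIES = {
    "Weight": weight,
    "HbondDonor": hbond_donor,
    "HbondAcceptor": hbond_acceptor,
    "NRotBond": n_rot_bond,
    "NRings": n_rings,
    "NAromaticRings": n_aromatic_rings,
    "TopologicalPolarSurfaceArea": tpsa,
    "LogP": log_p,
    "LipinskiViolations": lipinski_violations,
    "LipinskiViolationsVeber": lipinski_violations_veber,
    "LipinskiDruglike": lipinski_druglike,
}

ATOMIC_PROPERTIES = {
    "Atom_SigmaCharge": atom_sigma_charge,
    "Atom_TopologicalPolarSurfaceArea": atom_tpsa,
    "Atom_TPSA": atom_tpsa,
    "Atom_Mass": atom_mass,
}


# ---------------------------------------------------------------------------
# autocorrelation (Eq.-style signed 2DA/3DA)
# ---------------------------------------------------------------------------

@dataclass
class AutocorrelationConfig:
    """Pairwise property-product autocorrelation.

    For every ordered atom pair (i, j), including i == j, the product
    P_i * P_j is added to the distance bin containing r_ij -- bond count in
    2D mode, Euclidean angstroms in 3D mode.  In signed mode each distance
    bin splits into three sign sub-bins ordered (-/-, +/+, -/+), with the
    mixed-sign pairs pooled; zero counts as positive.  3D mode spreads each
    contribution over the two nearest bin centres with triangular (linear
    interpolation) weights.
    """
    atom_property: "DescriptorSpec | str" = "Atom_SigmaCharge"
    distance_mode: str = "bonds_2D"
    n_bins: int = 11
    bin_width: float = 1.0
    signed: bool = True
    smoothing: bool = False

    def __post_init__(self):
        if self.distance_mode not in ("bonds_2D", "euclidean_3D"):
            raise ValueError(f"unknown distance_mode {self.distance_mode!r}")
        if self.n_bins < 1 or self.bin_width <= 0:
            raise ValueError("bins must be positive")


def autocorrelation(mol: MoleculeGraph, config: AutocorrelationConfig,
                    ) -> np.ndarray:
    spec = config.atom_property
    if isinstance(spec, str):
        spec = parse_descriptor(spec)
    p = evaluate(spec, mol)
    if p.shape[0] != mol.n_atoms:
        raise DescriptorError(
            f"molecule {mol.name!r}: autocorrelation property is not atomic "
            f"(got length {p.shape[0]} for {mol.n_atoms} atoms)")
    n = mol.n_atoms
    if config.distance_mode == "bonds_2D":
        g = mol.to_networkx()
        dist = dict(nx.all_pairs_shortest_path_length(g))
        pair_iter = []
        skipped = False
        for i in range(n):
            for j in range(n):
                if j in dist[i]:
                    pair_iter.append((i, j, float(dist[i][j])))
                else:
                    skipped = True
        if skipped:
            warnings.warn(f"molecule {mol.name!r}: unreachable atom pairs "
                          "skipped in 2D autocorrelation")
    else:
        coords = mol.coords
        if n > 1 and np.allclose(coords, coords[0]):
            raise DescriptorError(
                f"molecule {mol.name!r}: 3D autocorrelation requires "
                "coordinates")
        d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2)
        pair_iter = [(i, j, float(d[i, j])) for i in range(n)
                     for j in range(n)]
    n_sub = 3 if config.signed else 1
    out = np.zeros(config.n_bins * n_sub)
    w = config.bin_width
    smooth = config.smoothing and config.distance_mode == "euclidean_3D"
    for i, j, r in pair_iter:
        prod = p[i] * p[j]
        if config.signed:
            si = p[i] >= 0
            sj = p[j] >= 0
            sub = 1 if (si and sj) else (0 if (not si and not sj) else 2)
        else:
            sub = 0
        if smooth:
            # triangular kernel: split between the two nearest bin centres
            x = r / w - 0.5  # bin-centre coordinate
            b0 = math.floor(x)
            frac = x - b0
            for b, wt in ((b0, 1.0 - frac), (b0 + 1, frac)):
                if 0 <= b < config.n_bins and wt > 0:
                    out[b * n_sub + sub] += wt * prod
        else:
            b = int(r // w)
            if 0 <= b < config.n_bins:
                out[b * n_sub + sub] += prod
    return out


# ---------------------------------------------------------------------------
# grammar
# ---------------------------------------------------------------------------

@dataclass
class DescriptorSpec:
    kind: str  # named_property | operator | constant | alias_ref
    name: str = ""
    children: list = field(default_factory=list)
    parameters: dict = field(default_factory=dict)
    values: list = field(default_factory=list)


_OPERATORS = {"Combine", "Define", "Less", "Greater", "Multiply", "Add",
              "Constant",
              "MoleculeSum", "MoleculeMean", "MoleculeMin", "MoleculeMax",
              "MoleculeSD", "2DASmoothSign", "3daSmoothSign"}

_OPEN = {"(": ")", "[": "]", "{": "}"}
_CLOSE = set(_OPEN.values())

_TOKEN_RE = re.compile(
    r"\s*(?:(?P<num>[-+]?\d+\.?\d*(?:[eE][-+]?\d+)?)(?![\w.])"
    r"|(?P<name>[A-Za-z0-9_]+)"
    r"|(?P<at>@[^\s()\[\]{},=]+)"
    r"|(?P<punct>[()\[\]{},=]))")


def _tokenize(text, base_dir):
    tokens = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            if text[pos:].strip() == "":
                break
            raise ParseError(f"unexpected character {text[pos]!r}", pos)
        if m.group("at"):
            path = Path(m.group("at")[1:])
            if base_dir is not None and not path.is_absolute():
                path = Path(base_dir) / path
            try:
                included = path.read_text()
            except OSError as exc:
                raise ParseError(f"cannot include {path}: {exc}",
                                 m.start()) from exc
            tokens.extend(_tokenize(included, path.parent))
        else:
            kind = "num" if m.group("num") else (
                "name" if m.group("name") else "punct")
            tokens.append((kind, m.group(kind), m.start()))
        pos = m.end()
    return tokens


class _Parser:
    def __init__(self, tokens, aliases):
        self.tokens = tokens
        self.i = 0
        self.aliases = aliases

    def peek(self):
        return self.tokens[self.i] if self.i < len(self.tokens) else None

    def next(self):
        tok = self.peek()
        if tok is None:
            raise ParseError("unexpected end of descriptor")
        self.i += 1
        return tok

    def parse_all(self):
        items = []
        while self.peek() is not None:
            items.append(self.parse_expr())
            if self.peek() and self.peek()[1] == ",":
                self.next()
        real = [it for it in items if it.name != "Define"]
        if len(items) == 1:
            return items[0]
        if len(real) == 1 and len(items) != 1:
            # Defines plus one expression: keep Defines for side effect order
            return DescriptorSpec("operator", "Combine", children=items)
        return DescriptorSpec("operator", "Combine", children=items)

    def parse_expr(self):
        kind, value, pos = self.next()
        if kind == "num":
            return DescriptorSpec("constant", "Constant",
                                  values=[float(value)])
        if kind != "name":
            raise ParseError(f"expected a name, got {value!r}", pos)
        nxt = self.peek()
        if nxt is None or nxt[1] not in _OPEN:
            return self.resolve_leaf(value, pos)
        opener = self.next()[1]
        closer = _OPEN[opener]
        args, params = [], {}
        while True:
            tok = self.peek()
            if tok is None:
                raise ParseError(f"missing closing {closer!r}", pos)
            if tok[1] in _CLOSE:
                if tok[1] != closer:
                    raise ParseError(
                        f"mismatched bracket {tok[1]!r}", tok[2])
                self.next()
                break
            if tok[1] == ",":
                self.next()
                continue
            # lookahead for name '=' value
            if tok[0] == "name" and self.i + 1 < len(self.tokens) \
                    and self.tokens[self.i + 1][1] == "=":
                key = self.next()[1]
                self.next()  # '='
                params[key] = self.parse_expr()
            else:
                args.append(self.parse_expr())
        return self.build(value, args, params, pos)

    def resolve_leaf(self, name, pos):
        if name in self.aliases:
            return self.aliases[name]
        if name in MOLECULE_PROPERTIES or name in ATOMIC_PROPERTIES:
            return DescriptorSpec("named_property", name)
        raise ParseError(f"unknown descriptor name {name!r}", pos)

    def build(self, name, args, params, pos):
        if name == "Define":
            if len(params) != 1 or args:
                raise ParseError("Define expects exactly [Alias = Expr]", pos)
            alias, spec = next(iter(params.items()))
            self.aliases[alias] = spec
            return DescriptorSpec("operator", "Define",
                                  parameters={alias: spec})
        if name == "Constant":
            vals = []
            for a in args:
                if a.kind != "constant":
                    raise ParseError("Constant takes numbers only", pos)
                vals.extend(a.values)
            if not vals:
                raise ParseError("Constant needs at least one value", pos)
            return DescriptorSpec("constant", "Constant", values=vals)
        if name in ("Less", "Greater"):
            if set(params) == {"lhs", "rhs"} and not args:
                children = [params["lhs"], params["rhs"]]
            elif len(args) == 2 and not params:
                children = args
            else:
                raise ParseError(f"{name} expects lhs=..., rhs=...", pos)
            return DescriptorSpec("operator", name, children=children)
        if name in ("Multiply", "Add"):
            if len(args) < 2 or params:
                raise ParseError(f"{name} expects at least two arguments",
                                 pos)
            return DescriptorSpec("operator", name, children=args)
        if name == "Combine":
            if not args or params:
                raise ParseError("Combine expects positional arguments", pos)
            return DescriptorSpec("operator", name, children=args)
        if name in ("MoleculeSum", "MoleculeMean", "MoleculeMin",
                    "MoleculeMax", "MoleculeSD"):
            if len(args) != 1 or params:
                raise ParseError(f"{name} expects one argument", pos)
            return DescriptorSpec("operator", name, children=args)
        if name in ("2DASmoothSign", "3daSmoothSign"):
            if "property" not in params or args:
                raise ParseError(f"{name} expects property=...", pos)
            node = DescriptorSpec("operator", name,
                                  children=[params.pop("property")])
            for key, val in params.items():
                if key not in ("steps", "step_size"):
                    raise ParseError(f"{name}: unknown parameter {key!r}",
                                     pos)
                if val.kind != "constant" or len(val.values) != 1:
                    raise ParseError(f"{name}: {key} must be a number", pos)
                node.parameters[key] = val.values[0]
            return node
        if name in MOLECULE_PROPERTIES or name in ATOMIC_PROPERTIES:
            if args or params:
                raise ParseError(f"{name} takes no arguments", pos)
            return DescriptorSpec("named_property", name)
        raise ParseError(f"unknown descriptor name {name!r}", pos)


def parse_descriptor(text: str, aliases: dict | None = None,
                     base_dir=None) -> DescriptorSpec:
    """Parse descriptor text into a spec tree.

    ``aliases`` is an optional mutable registry shared across calls so that a
    ``Define`` in one parse is visible to the next.  ``base_dir`` anchors
    relative ``@file`` inclusions.
    """
    if aliases is None:
        aliases = {}
    tokens = _tokenize(text, base_dir)
    if not tokens:
        raise ParseError("empty descriptor")
    parser = _Parser(tokens, aliases)
    spec = parser.parse_all()
    if parser.peek() is not None:
        raise ParseError("trailing input", parser.peek()[2])
    return spec


def serialize_descriptor(spec: DescriptorSpec) -> str:
    """Canonical text form; re-parsing reproduces an equivalent tree."""
    if spec.kind == "named_property":
        return spec.name
    if spec.kind == "constant":
        return "Constant(" + ", ".join(_fmt(v) for v in spec.values) + ")"
    if spec.name == "Define":
        alias, sub = next(iter(spec.parameters.items()))
        return f"Define({alias} = {serialize_descriptor(sub)})"
    if spec.name in ("Less", "Greater"):
        return (f"{spec.name}(lhs = {serialize_descriptor(spec.children[0])},"
                f" rhs = {serialize_descriptor(spec.children[1])})")
    if spec.name in ("2DASmoothSign", "3daSmoothSign"):
        parts = [f"property = {serialize_descriptor(spec.children[0])}"]
        parts += [f"{k} = {_fmt(v)}" for k, v in spec.parameters.items()]
        return f"{spec.name}({', '.join(parts)})"
    inner = ", ".join(serialize_descriptor(c) for c in spec.children)
    return f"{spec.name}({inner})"


def _fmt(v: float) -> str:
    return str(int(v)) if float(v).is_integer() else repr(float(v))


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def _broadcast(name, a, b):
    if a.shape == b.shape:
        return a, b
    if a.shape == (1,):
        return np.full_like(b, a[0]), b
    if b.shape == (1,):
        return a, np.full_like(a, b[0])
    raise DescriptorError(f"{name}: incompatible argument lengths "
                          f"{a.shape[0]} and {b.shape[0]}")


def evaluate(spec: DescriptorSpec, mol: MoleculeGraph) -> np.ndarray:
    """Evaluate a descriptor spec on one molecule; returns a float vector."""
    if spec.kind == "named_property":
        if spec.name in MOLECULE_PROPERTIES:
            return np.atleast_1d(
                np.asarray(MOLECULE_PROPERTIES[spec.name](mol), dtype=float))
        return np.asarray(ATOMIC_PROPERTIES[spec.name](mol), dtype=float)
    if spec.kind == "constant":
        return np.asarray(spec.values, dtype=float)
    if spec.kind == "custom":
        # programmatically registered property (e.g. model-backed)
        return np.atleast_1d(
            np.asarray(spec.parameters["fn"](mol), dtype=float))
    name = spec.name
    if name == "Define":
        return np.zeros(0)
    if name == "Combine":
        parts = [evaluate(c, mol) for c in spec.children]
        return np.concatenate(parts) if parts else np.zeros(0)
    if name in ("Less", "Greater"):
        a = evaluate(spec.children[0], mol)
        b = evaluate(spec.children[1], mol)
        a, b = _broadcast(name, a, b)
        return (a < b).astype(float) if name == "Less" \
            else (a > b).astype(float)
    if name in ("Multiply", "Add"):
        out = evaluate(spec.children[0], mol)
        for c in spec.children[1:]:
            nxt = evaluate(c, mol)
            out, nxt = _broadcast(name, out, nxt)
            out = out * nxt if name == "Multiply" else out + nxt
        return out
    if name in ("MoleculeSum", "MoleculeMean", "MoleculeMin", "MoleculeMax",
                "MoleculeSD"):
        v = evaluate(spec.children[0], mol)
        if v.size == 0:
            raise DescriptorError(f"{name}: empty argument")
        fn = {"MoleculeSum": np.sum, "MoleculeMean": np.mean,
              "MoleculeMin": np.min, "MoleculeMax": np.max,
              "MoleculeSD": np.std}[name]
        return np.atleast_1d(np.asarray(fn(v), dtype=float))
    if name == "2DASmoothSign":
        cfg = AutocorrelationConfig(
            atom_property=spec.children[0], distance_mode="bonds_2D",
            n_bins=int(spec.parameters.get("steps", 11)), bin_width=1.0,
            signed=True, smoothing=False)
        return autocorrelation(mol, cfg)
    if name == "3daSmoothSign":
        cfg = AutocorrelationConfig(
            atom_property=spec.children[0], distance_mode="euclidean_3D",
            n_bins=int(spec.parameters.get("steps", 24)),
            bin_width=float(spec.parameters.get("step_size", 0.25)),
            signed=True, smoothing=True)
        return autocorrelation(mol, cfg)
    raise DescriptorError(f"cannot evaluate node {name!r}")
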