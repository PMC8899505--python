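"""Molecular graph data model and standardization.

Molecules are undirected graphs whose nodes are atoms and whose edges are
bonds.  Bond orders are always stored kekulized (1, 2 or 3); aromaticity is a
separate perceived flag on atoms and bonds.  This keeps valence bookkeeping
exact while still supporting aromatic-aware matching and aromatic SDF output.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np

__all__ = [
    "Atom",
    "Bond",
    "MoleculeGraph",
    "add_hydrogens",
    "connected_components",
    "kekulize",
    "neutralize",
    "perceive_rings_and_aromaticity",
    "validate_atom_types",
]

# Standard atomic masses (most common elements in druglike molecules).
ATOMIC_MASS = {
    "H": 1.008, "B": 10.811, "C": 12.011, "N": 14.007, "O": 15.999,
    "F": 18.998, "Na": 22.990, "Mg": 24.305, "Si": 28.086, "P": 30.974,
    "S": 32.065, "Cl": 35.453, "K": 39.098, "Ca": 40.078, "Br": 79.904,
    "I": 126.904, "Li": 6.941, "Zn": 65.38, "Fe": 55.845, "Se": 78.971,
}

# Neutral-atom standard valences.  Multi-valent elements list every allowed
# valence; hydrogen filling and validity use the smallest one that fits.
STANDARD_VALENCES = {
    "H": (1,), "B": (3,), "C": (4,), "N": (3,), "O": (2,), "F": (1,),
    "Si": (4,), "P": (3, 5), "S": (2, 4, 6), "Cl": (1,), "Br": (1,),
    "I": (1,), "Se": (2, 4, 6), "Li": (1,), "Na": (1,), "K": (1,),
    "Mg": (2,), "Ca": (2,), "Zn": (2,), "Fe": (2, 3),
}

# Elements whose anions/cations shift valence by +charge (N+ is tetravalent)
# or -|charge| (O- is monovalent).
_POSITIVE_SHIFT = {"N", "P", "O", "S", "C"}
_NEGATIVE_SHIFT = {"O", "S", "N", "C", "Se"}


def allowed_valences(element: str, formal_charge: int = 0) -> tuple[int, ...]:
    """Allowed bond-order sums for *element* carrying *formal_charge*."""
    base = STANDARD_VALENCES.get(element)
    if base is None:
        return ()  # unknown element: validity is not enforced
    if formal_charge > 0 and element in _POSITIVE_SHIFT:
        return tuple(v + formal_charge for v in base)
    if formal_charge < 0 and element in _NEGATIVE_SHIFT:
        return tuple(max(v + formal_charge, 0) for v in base)
    return base


@dataclass
class Atom:
    element: str
    formal_charge: int = 0
    coords: np.ndarray = field(default_factory=lambda: np.zeros(3))
    aromatic: bool = False
    index: int = 0

    def copy(self) -> "Atom":
        return Atom(self.element, self.formal_charge,
                    np.array(self.coords, dtype=float), self.aromatic,
                    self.index)


@dataclass
class Bond:
    a1: int
    a2: int
    order: int = 1
    aromatic: bool = False
    in_ring: bool = False
    amide: bool = False
    stereo: str = "none"  # none | E | Z

    def copy(self) -> "Bond":
        return Bond(self.a1, self.a2, self.order, self.aromatic,
                    self.in_ring, self.amide, self.stereo)

    def other(self, idx: int) -> int:
        return self.a2 if idx == self.a1 else self.a1


class MoleculeGraph:
    """A molecule: atoms, bonds, 3-D coordinates and MDL data-block properties."""

    def __init__(self, name: str = "", atoms=None, bonds=None, properties=None):
        self.name = name
        self.atoms: list[Atom] = list(atoms or [])
        self.bonds: list[Bond] = list(bonds or [])
        self.properties: dict[str, str] = dict(properties or {})
        self._reindex()

    # -- construction helpers -------------------------------------------------
    def _reindex(self):
        for i, a in enumerate(self.atoms):
            a.index = i

    def add_atom(self, element, formal_charge=0, coords=(0.0, 0.0, 0.0)) -> int:
        self.atoms.append(Atom(element, formal_charge,
                               np.asarray(coords, dtype=float),
                               index=len(self.atoms)))
        return len(self.atoms) - 1

    def add_bond(self, a1, a2, order=1, **kw) -> Bond:
        if a1 == a2:
            raise ValueError("self-bonds are not allowed")
        if self.bond_between(a1, a2) is not None:
            raise ValueError(f"duplicate bond {a1}-{a2}")
        b = Bond(a1, a2, order, **kw)
        self.bonds.append(b)
        return b

    def copy(self) -> "MoleculeGraph":
        return MoleculeGraph(self.name, [a.copy() for a in self.atoms],
                             [b.copy() for b in self.bonds],
                             dict(self.properties))

    # -- queries --------------------------------------------------------------
    def __len__(self):
        return len(self.atoms)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def neighbors(self, idx: int) -> list[int]:
        return [b.other(idx) for b in self.bonds if idx in (b.a1, b.a2)]

    def bonds_of(self, idx: int) -> list[Bond]:
        return [b for b in self.bonds if idx in (b.a1, b.a2)]

    def bond_between(self, a1: int, a2: int) -> Bond | None:
        for b in self.bonds:
            if {b.a1, b.a2} == {a1, a2}:
                return b
        return None

    def bond_order_sum(self, idx: int) -> int:
        return sum(b.order for b in self.bonds_of(idx))

    def implicit_hydrogens(self, idx: int) -> int:
        """Hydrogens needed to fill the smallest allowed valence."""
        a = self.atoms[idx]
        if a.element == "H":
            return 0
        s = self.bond_order_sum(idx)
        for v in allowed_valences(a.element, a.formal_charge):
            if v >= s:
                return v - s
        return 0

    def total_hydrogens(self, idx: int) -> int:
        explicit = sum(1 for n in self.neighbors(idx)
                       if self.atoms[n].element == "H")
        return explicit + self.implicit_hydrogens(idx)

    def heavy_atom_indices(self) -> list[int]:
        return [a.index for a in self.atoms if a.element != "H"]

    @property
    def coords(self) -> np.ndarray:
        if not self.atoms:
            return np.zeros((0, 3))
        return np.array([a.coords for a in self.atoms], dtype=float)

    def has_coordinates(self) -> bool:
        return self.n_atoms > 0 and bool(np.any(np.abs(self.coords) > 1e-12))

    def to_networkx(self, heavy_only: bool = False) -> nx.Graph:
        g = nx.Graph()
        for a in self.atoms:
            if heavy_only and a.element == "H":
                continue
            g.add_node(a.index, element=a.element, charge=a.formal_charge,
                       aromatic=a.aromatic)
        for b in self.bonds:
            if b.a1 in g and b.a2 in g:
                g.add_edge(b.a1, b.a2, order=b.order, aromatic=b.aromatic,
                           in_ring=b.in_ring, amide=b.amide)
        return g

    def molecular_weight(self) -> float:
        w = 0.0
        for a in self.atoms:
            w += ATOMIC_MASS.get(a.element, 0.0)
            if a.element != "H":
                w += ATOMIC_MASS["H"] * self.implicit_hydrogens(a.index)
        return w

    def remove_atoms(self, indices) -> "MoleculeGraph":
        """Return a copy with *indices* (and incident bonds) deleted."""
        drop = set(indices)
        keep = [i for i in range(self.n_atoms) if i not in drop]
        remap = {old: new for new, old in enumerate(keep)}
        atoms = [self.atoms[i].copy() for i in keep]
        bonds = [Bond(remap[b.a1], remap[b.a2], b.order, b.aromatic,
                      b.in_ring, b.amide, b.stereo)
                 for b in self.bonds if b.a1 in remap and b.a2 in remap]
        return MoleculeGraph(self.name, atoms, bonds, dict(self.properties))


# ---------------------------------------------------------------------------
# Ring perception, aromaticity, kekulization
# ---------------------------------------------------------------------------

def sssr(mol: MoleculeGraph) -> list[list[int]]:
    """Smallest set of smallest rings (minimum cycle basis)."""
    g = mol.to_networkx()
    return [sorted(c) for c in nx.minimum_cycle_basis(g)]


def _pi_electrons(mol: MoleculeGraph, idx: int, ring: set[int]) -> int | None:
    """Hueckel pi-electron contribution of ring atom *idx*, or None if the
    atom cannot take part in an aromatic system."""
    a = mol.atoms[idx]
    ring_bonds = [b for b in mol.bonds_of(idx) if b.other(idx) in ring]
    if len(ring_bonds) < 2:
        return None
    other_bonds = [b for b in mol.bonds_of(idx) if b.other(idx) not in ring]
    has_ring_double = any(b.order == 2 for b in ring_bonds)
    exo_double = [b for b in other_bonds if b.order >= 2]
    if any(b.order == 3 for b in mol.bonds_of(idx)):
        return None
    heavy_degree = len(mol.neighbors(idx)) + mol.implicit_hydrogens(idx)
    el, q = a.element, a.formal_charge
    if el == "C":
        if has_ring_double:
            return 1
        if exo_double:
            return 0  # quinoid carbon: sp2, contributes an empty/exo pi
        if q == -1:
            return 2
        if q == 1:
            return 0
        return None  # sp3 carbon
    if el in ("N", "P"):
        if has_ring_double:
            return 1
        if exo_double:  # N-oxide style
            return 1
        if q == 1 and heavy_degree == 4:
            return None if not has_ring_double else 1
        return 2  # pyrrole-type lone pair
    if el in ("O", "S", "Se"):
        if has_ring_double or exo_double:
            return None if el == "O" and has_ring_double else 1
        return 2
    if el == "B":
        return 0
    return None


def _ring_is_aromatic(mol: MoleculeGraph, ring: list[int]) -> bool:
    rs = set(ring)
    total = 0
    for idx in ring:
        pi = _pi_electrons(mol, idx, rs)
        if pi is None:
            return False
        total += pi
    return total % 4 == 2


def perceive_rings_and_aromaticity(mol: MoleculeGraph) -> MoleculeGraph:
    """Flag ring bonds (SSSR) and aromatic atoms/bonds (Hueckel 4n+2) in place.

    Individual SSSR rings are tested first; fused-ring envelopes are then
    tested as whole pi systems so cases like azulene are caught.
    """
    for a in mol.atoms:
        a.aromatic = False
    for b in mol.bonds:
        b.aromatic = False
        b.in_ring = False
    rings = sssr(mol)
    ring_atoms = set(itertools.chain.from_iterable(rings))
    for b in mol.bonds:
        if b.a1 in ring_atoms and b.a2 in ring_atoms:
            for r in rings:
                if b.a1 in r and b.a2 in r:
                    b.in_ring = True
                    break
    aromatic_atoms: set[int] = set()
    for r in rings:
        if _ring_is_aromatic(mol, r):
            aromatic_atoms.update(r)
    # fused envelopes: union of SSSR rings sharing a bond
    fused = nx.Graph()
    fused.add_nodes_from(range(len(rings)))
    for i, j in itertools.combinations(range(len(rings)), 2):
        if len(set(rings[i]) & set(rings[j])) >= 2:
            fused.add_edge(i, j)
    for comp in nx.connected_components(fused):
        if len(comp) < 2:
            continue
        env = sorted(set(itertools.chain.from_iterable(rings[i] for i in comp)))
        if not set(env) <= aromatic_atoms and _ring_is_aromatic(mol, env):
            aromatic_atoms.update(env)
    for idx in aromatic_atoms:
        mol.atoms[idx].aromatic = True
    for b in mol.bonds:
        if b.in_ring and b.a1 in aromatic_atoms and b.a2 in aromatic_atoms:
            # only flag bonds interior to one aromatic ring/envelope
            b.aromatic = True
    _flag_amides(mol)
    return mol


def _flag_amides(mol: MoleculeGraph):
    for b in mol.bonds:
        b.amide = False
        if b.order != 1 or b.aromatic:
            continue
        for c_idx, n_idx in ((b.a1, b.a2), (b.a2, b.a1)):
            if mol.atoms[c_idx].element == "C" and mol.atoms[n_idx].element == "N":
                if any(ob.order == 2 and mol.atoms[ob.other(c_idx)].element == "O"
                       for ob in mol.bonds_of(c_idx)):
                    b.amide = True


def kekulize(mol: MoleculeGraph, provisional: bool = False) -> MoleculeGraph:
    """Assign alternating single/double orders within aromatic systems.

    Aromatic atoms that still need one double bond (sp2 atoms without an
    existing double bond or donating lone pair) are perfectly matched along
    aromatic bonds; an odd system with no valid matching raises ValueError.

    With ``provisional=True`` the aromatic bond orders are treated as
    placeholders (SDF order-4 input): nitrogen classification then relies on
    explicit substituents/hydrogens only, since implicit hydrogen counts are
    not yet meaningful.
    """
    mol = mol.copy()
    arom_bonds = [b for b in mol.bonds if b.aromatic]
    if not arom_bonds:
        return mol
    needs_double: set[int] = set()
    for idx in {i for b in arom_bonds for i in (b.a1, b.a2)}:
        a = mol.atoms[idx]
        non_arom_double = any(b.order >= 2 and not b.aromatic
                              for b in mol.bonds_of(idx))
        if non_arom_double:
            continue
        el, q = a.element, a.formal_charge
        if provisional:
            degree = len(mol.neighbors(idx))
        else:
            degree = len(mol.neighbors(idx)) + mol.implicit_hydrogens(idx)
        if el == "C" and q == 0:
            needs_double.add(idx)
        elif el in ("N", "P"):
            if provisional:
                # pyrrole-type N carries an explicit H or third substituent
                if (q == 0 and degree == 2) or q == 1:
                    needs_double.add(idx)
            elif (q == 0 and degree == 2) or (q == 1 and degree == 3):
                needs_double.add(idx)
        # O, S, pyrrole-type N: lone-pair donors, no double bond needed
    # reset aromatic bonds to single, then place doubles via matching
    for b in arom_bonds:
        b.order = 1
    sub = nx.Graph()
    sub.add_nodes_from(needs_double)
    for b in arom_bonds:
        if b.a1 in needs_double and b.a2 in needs_double:
            sub.add_edge(b.a1, b.a2)
    matching = nx.max_weight_matching(sub, maxcardinality=True)
    matched = {i for e in matching for i in e}
    unmatched = needs_double - matched
    if unmatched:
        raise ValueError(
            f"cannot kekulize aromatic system; unmatched ring atoms {sorted(unmatched)}")
    for u, v in matching:
        mol.bond_between(u, v).order = 2
    return mol


def connected_components(mol: MoleculeGraph) -> list[MoleculeGraph]:
    """Split disconnected parts, largest (by atom count, then weight) first."""
    g = mol.to_networkx()
    comps = [sorted(c) for c in nx.connected_components(g)]
    parts = [mol.remove_atoms(set(range(mol.n_atoms)) - set(c)) for c in comps]
    parts.sort(key=lambda m: (-m.n_atoms, -m.molecular_weight()))
    return parts


# ---------------------------------------------------------------------------
# Hydrogen handling and neutralization
# ---------------------------------------------------------------------------

def add_hydrogens(mol: MoleculeGraph) -> MoleculeGraph:
    """Saturate every heavy atom with explicit hydrogens (idempotent)."""
    out = mol.copy()
    for idx in list(range(out.n_atoms)):
        a = out.atoms[idx]
        if a.element == "H":
            continue
        s = out.bond_order_sum(idx)
        vals = allowed_valences(a.element, a.formal_charge)
        if vals and s > max(vals):
            raise ValueError(
                f"atom {idx} ({a.element}) exceeds its valence ({s} > {max(vals)})")
        for _ in range(out.implicit_hydrogens(idx)):
            h = out.add_atom("H", coords=a.coords)
            out.add_bond(idx, h, 1)
    out._reindex()
    return out


def remove_hydrogens(mol: MoleculeGraph) -> MoleculeGraph:
    return mol.remove_atoms([a.index for a in mol.atoms if a.element == "H"])


def neutralize(mol: MoleculeGraph, scheme: str = "default") -> MoleculeGraph:
    """Best-effort removal of formal charges.

    default      protonation-state changes and bond-order adjustment
    pH_only      protonation-state changes only
    bond_order_only  adjacent (+,-) pairs resolved by bond-order increment only
    none         no-op
    """
    if scheme not in ("default", "pH_only", "bond_order_only", "none"):
        raise ValueError(f"unknown neutralization scheme {scheme!r}")
    if scheme == "none":
        return mol.copy()
    out = mol.copy()
    if scheme in ("default", "bond_order_only"):
        # ylide resolution: adjacent +/- pair, increment the bond
        for b in out.bonds:
            x, y = out.atoms[b.a1], out.atoms[b.a2]
            if {x.formal_charge, y.formal_charge} == {1, -1} and b.order < 3:
                anion = x if x.formal_charge == -1 else y
                cation = x if x.formal_charge == 1 else y
                new_vals = allowed_valences(anion.element, 0)
                if new_vals and out.bond_order_sum(anion.index) + 1 <= max(new_vals):
                    b.order += 1
                    anion.formal_charge = 0
                    cation.formal_charge = 0
    if scheme in ("default", "pH_only"):
        to_remove: list[int] = []
        for a in out.atoms:
            if a.element in ("O", "S") and a.formal_charge == -1:
                # skip delocalized oxyanion partners of N-oxide/nitro (N+)
                if any(out.atoms[n].element == "N" and
                       out.atoms[n].formal_charge == 1
                       for n in out.neighbors(a.index)):
                    continue
                a.formal_charge = 0
                h = out.add_atom("H", coords=a.coords)
                out.add_bond(a.index, h, 1)
            elif a.element == "N" and a.formal_charge == 1:
                hs = [n for n in out.neighbors(a.index)
                      if out.atoms[n].element == "H"]
                if hs:
                    to_remove.append(hs[0])
                    a.formal_charge = 0
                elif out.implicit_hydrogens(a.index) > 0:
                    a.formal_charge = 0
        if to_remove:
            out = out.remove_atoms(to_remove)
    out._reindex()
    return out


def validate_atom_types(mol: MoleculeGraph) -> list[int]:
    """Indices of atoms whose bond-order sum exceeds every allowed valence."""
    bad = []
    for a in mol.atoms:
        vals = allowed_valences(a.element, a.formal_charge)
        if not vals:
            continue
        s = mol.bond_order_sum(a.index)
        if a.element == "H":
            if s > 1:
                bad.append(a.index)
            continue
        if s > max(vals):
            bad.append(a.index)
    return bad
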