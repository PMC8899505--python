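"""Substructure comparison, similarity coefficients and pose metrics.

The central primitive is the maximum common substructure (MCS) between two
molecular graphs, found as a maximum clique in the modular product graph via a
connected-clique branch-and-bound (Koch-style).  Atom and bond equivalence is
configurable through :class:`ComparisonTypeConfig`.  The Tanimoto and Tversky
coefficients are computed over matched heavy atoms.

Matching is *non-induced* by default: two mapped substructures must share the
mapped bonds, but extra bonds between mapped atoms on one side only are
tolerated (common-substructure rather than common-induced-subgraph
semantics).  Hydrogens are excluded from all substructure comparisons.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from networkx.algorithms import isomorphism as nxiso

from .graph import MoleculeGraph, remove_hydrogens

__all__ = [
    "ComparisonTypeConfig",
    "MCSResult",
    "MCSResourceError",
    "align_to_scaffold",
    "compare_ensembles",
    "contains_substructure",
    "kabsch_superimpose",
    "mcs",
    "rmsd",
    "symmetry_rmsd",
    "tanimoto",
    "tversky",
]

ATOM_LEVELS = ("ElementType", "AtomType")
BOND_LEVELS = ("BondOrder", "BondOrderOrAromatic",
               "BondOrderAmideWithIsometryOrAromaticWithRingness")


def hybridization(mol: MoleculeGraph, idx: int) -> str:
    """sp/sp2/sp3 inferred from bond orders and aromaticity."""
    bonds = mol.bonds_of(idx)
    if any(b.order == 3 for b in bonds):
        return "sp"
    n_double = sum(1 for b in bonds if b.order == 2)
    if n_double >= 2:
        return "sp"
    if n_double == 1 or mol.atoms[idx].aromatic:
        return "sp2"
    return "sp3"


@dataclass(frozen=True)
class ComparisonTypeConfig:
    """Equivalence classes for atoms and bonds during substructure search.

    atom_level:
        ElementType  -- atoms match on element only
        AtomType     -- element plus inferred hybridization
    bond_level:
        BondOrder            -- exact kekulized order, aromatic flag equal
        BondOrderOrAromatic  -- aromatic bonds match aromatic bonds; ordered
                                (non-aromatic) bonds match each other
        BondOrderAmideWithIsometryOrAromaticWithRingness
                             -- as BondOrder, plus equal amide/ring flags and
                                E/Z isometry
    """
    atom_level: str = "ElementType"
    bond_level: str = "BondOrderOrAromatic"

    def __post_init__(self):
        if self.atom_level not in ATOM_LEVELS:
            raise ValueError(f"unknown atom_level {self.atom_level!r}")
        if self.bond_level not in BOND_LEVELS:
            raise ValueError(f"unknown bond_level {self.bond_level!r}")

    def atom_key(self, mol, idx):
        a = mol.atoms[idx]
        if self.atom_level == "ElementType":
            return a.element
        return (a.element, hybridization(mol, idx))

    def bonds_match(self, molA, bondA, molB, bondB) -> bool:
        if self.bond_level == "BondOrder":
            return (bondA.order == bondB.order
                    and bondA.aromatic == bondB.aromatic)
        if self.bond_level == "BondOrderOrAromatic":
            return bondA.aromatic == bondB.aromatic
        return (bondA.order == bondB.order
                and bondA.aromatic == bondB.aromatic
                and bondA.in_ring == bondB.in_ring
                and bondA.amide == bondB.amide
                and bondA.stereo == bondB.stereo)


DEFAULT_COMPARISON = ComparisonTypeConfig()


@dataclass
class MCSResult:
    mapping: list[tuple[int, int]]
    size: int
    connected: bool
    size_a: int
    size_b: int
    pieces: list[int] = field(default_factory=list)


class MCSResourceError(RuntimeError):
    """Raised when the clique search exceeds its node budget."""


# ---------------------------------------------------------------------------
# modular-product clique search
# ---------------------------------------------------------------------------

class _ModularProduct:
    """Vertices are compatible heavy-atom pairs; edges are strong (both sides
    share a matching bond) or weak (pair-compatible without a shared bond)."""

    def __init__(self, molA, molB, cmp: ComparisonTypeConfig, induced: bool):
        self.vertices: list[tuple[int, int]] = []
        keysB: dict = {}
        for b in molB.heavy_atom_indices():
            keysB.setdefault(cmp.atom_key(molB, b), []).append(b)
        for a in molA.heavy_atom_indices():
            for b in keysB.get(cmp.atom_key(molA, a), ()):
                self.vertices.append((a, b))
        n = len(self.vertices)
        bondsA = {frozenset((bo.a1, bo.a2)): bo for bo in molA.bonds}
        bondsB = {frozenset((bo.a1, bo.a2)): bo for bo in molB.bonds}
        self.strong = [set() for _ in range(n)]
        self.weak = [set() for _ in range(n)]
        for i in range(n):
            a1, b1 = self.vertices[i]
            for j in range(i + 1, n):
                a2, b2 = self.vertices[j]
                if a1 == a2 or b1 == b2:
                    continue
                ba = bondsA.get(frozenset((a1, a2)))
                bb = bondsB.get(frozenset((b1, b2)))
                if ba is not None and bb is not None and \
                        cmp.bonds_match(molA, ba, molB, bb):
                    self.strong[i].add(j)
                    self.strong[j].add(i)
                elif ba is None and bb is None:
                    self.weak[i].add(j)
                    self.weak[j].add(i)
                elif not induced:
                    # bond on one side only: tolerated, not shared
                    self.weak[i].add(j)
                    self.weak[j].add(i)


def _distinct_bound(vertices, cand):
    atoms_a = {vertices[v][0] for v in cand}
    atoms_b = {vertices[v][1] for v in cand}
    return min(len(atoms_a), len(atoms_b))


def _max_common_subgraph(molA, molB, cmp, connected, induced,
                         node_budget=2_000_000):
    mp = _ModularProduct(molA, molB, cmp, induced)
    n = len(mp.vertices)
    best: list = [0, []]
    counter = [0]

    def record(clique):
        if len(clique) > best[0]:
            best[0] = len(clique)
            best[1] = sorted(clique)

    def expand(clique, P, D):
        counter[0] += 1
        if counter[0] > node_budget:
            raise MCSResourceError(
                "substructure search exceeded its node budget; lower the "
                "comparison resolution or raise the budget")
        if len(clique) + _distinct_bound(mp.vertices, P | D) <= best[0]:
            return
        if not P:
            record(clique)
            return
        Pl = sorted(P)
        P = set(P)
        for v in Pl:
            if v not in P:
                continue
            if len(clique) + _distinct_bound(mp.vertices, P | D) <= best[0]:
                return
            P.discard(v)
            nb_all = mp.strong[v] | mp.weak[v]
            P2 = (P & nb_all) | (D & mp.strong[v])
            D2 = (D & mp.weak[v]) - mp.strong[v]
            clique.append(v)
            if P2:
                expand(clique, P2, D2)
            else:
                record(clique)
            clique.pop()

    if connected:
        allowed = set(range(n))
        for u in range(n):
            allowed.discard(u)
            expand([u], mp.strong[u] & allowed, mp.weak[u] & allowed)
    else:
        # unconstrained clique: every vertex may follow every compatible one
        def expand_u(clique, cand):
            counter[0] += 1
            if counter[0] > node_budget:
                raise MCSResourceError("substructure search exceeded budget")
            if len(clique) + _distinct_bound(mp.vertices, cand) <= best[0]:
                return
            if not cand:
                record(clique)
                return
            for v in sorted(cand):
                if len(clique) + _distinct_bound(mp.vertices, cand) <= best[0]:
                    return
                cand = cand - {v}
                clique.append(v)
                expand_u(clique, cand & (mp.strong[v] | mp.weak[v]))
                clique.pop()

        expand_u([], set(range(n)))
    return [mp.vertices[i] for i in best[1]]


def _mapping_pieces(A, B, cmp, mapping):
    """Sizes of the connected pieces of a common-substructure mapping
    (adjacency = matching bonds present on both sides), largest first."""
    if not mapping:
        return []
    bondsA = {frozenset((bo.a1, bo.a2)): bo for bo in A.bonds}
    bondsB = {frozenset((bo.a1, bo.a2)): bo for bo in B.bonds}
    g = nx.Graph()
    g.add_nodes_from(range(len(mapping)))
    for i in range(len(mapping)):
        a1, b1 = mapping[i]
        for j in range(i + 1, len(mapping)):
            a2, b2 = mapping[j]
            ba = bondsA.get(frozenset((a1, a2)))
            bb = bondsB.get(frozenset((b1, b2)))
            if ba is not None and bb is not None and \
                    cmp.bonds_match(A, ba, B, bb):
                g.add_edge(i, j)
    return sorted((len(c) for c in nx.connected_components(g)),
                  reverse=True)


def mcs(molA: MoleculeGraph, molB: MoleculeGraph,
        cmp: ComparisonTypeConfig = DEFAULT_COMPARISON,
        connected: bool = True, induced: bool = False,
        min_piece: int = 2, node_budget: int = 2_000_000) -> MCSResult:
    """Maximum common (connected or disconnected) substructure.

    The disconnected variant extracts connected pieces greedily: find the
    largest connected common substructure, remove its atoms from both
    molecules, and repeat while pieces of at least ``min_piece`` atoms remain;
    the piece sizes are summed into the intersection size.  With
    ``min_piece=1`` the search is instead a single exhaustive unconstrained
    clique search (globally maximal, single atoms allowed).
    """
    A = remove_hydrogens(molA)
    B = remove_hydrogens(molB)
    size_a, size_b = A.n_atoms, B.n_atoms
    if connected:
        mapping = _max_common_subgraph(A, B, cmp, True, induced, node_budget)
        return MCSResult(sorted(mapping), len(mapping), True, size_a, size_b,
                         [len(mapping)] if mapping else [])
    if min_piece <= 1:
        mapping = _max_common_subgraph(A, B, cmp, False, induced,
                                       node_budget)
        return MCSResult(sorted(mapping), len(mapping), False, size_a,
                         size_b, _mapping_pieces(A, B, cmp, mapping))
    # greedy iterative extraction of connected pieces
    mapping: list[tuple[int, int]] = []
    pieces: list[int] = []
    idxA = list(range(size_a))
    idxB = list(range(size_b))
    curA, curB = A, B
    while curA.n_atoms >= min_piece and curB.n_atoms >= min_piece:
        piece = _max_common_subgraph(curA, curB, cmp, True, induced,
                                     node_budget)
        if len(piece) < min_piece:
            break
        mapping.extend((idxA[a], idxB[b]) for a, b in piece)
        pieces.append(len(piece))
        usedA = {a for a, _ in piece}
        usedB = {b for _, b in piece}
        idxA = [idxA[i] for i in range(curA.n_atoms) if i not in usedA]
        idxB = [idxB[i] for i in range(curB.n_atoms) if i not in usedB]
        curA = curA.remove_atoms(usedA)
        curB = curB.remove_atoms(usedB)
    return MCSResult(sorted(mapping), len(mapping), False, size_a, size_b,
                     pieces)


def tanimoto(result: MCSResult) -> float:
    """|A∩B| / (|A| + |B| - |A∩B|) over matched heavy atoms."""
    if result.size_a == 0 and result.size_b == 0:
        raise ValueError("both molecules are empty")
    return result.size / (result.size_a + result.size_b - result.size)


def tversky(result: MCSResult, alpha: float, beta: float) -> float:
    if result.size_a == 0 and result.size_b == 0:
        raise ValueError("both molecules are empty")
    inter = result.size
    return inter / (inter + alpha * (result.size_a - inter)
                    + beta * (result.size_b - inter))


# ---------------------------------------------------------------------------
# substructure containment and automorphisms
# ---------------------------------------------------------------------------

def _nx_heavy(mol, cmp):
    g = nx.Graph()
    h = remove_hydrogens(mol)
    for a in h.atoms:
        g.add_node(a.index, key=cmp.atom_key(h, a.index))
    for b in h.bonds:
        g.add_edge(b.a1, b.a2, bond=b)
    return h, g


def contains_substructure(mol: MoleculeGraph, query: MoleculeGraph,
                          cmp: ComparisonTypeConfig = DEFAULT_COMPARISON) -> bool:
    """True iff *query* embeds as a (monomorphic) substructure of *mol*."""
    hq, gq = _nx_heavy(query, cmp)
    hm, gm = _nx_heavy(mol, cmp)
    if gq.number_of_nodes() > gm.number_of_nodes():
        return False
    matcher = nxiso.GraphMatcher(
        gm, gq,
        node_match=lambda n1, n2: n1["key"] == n2["key"],
        edge_match=lambda e1, e2: cmp.bonds_match(hm, e1["bond"],
                                                  hq, e2["bond"]))
    return matcher.subgraph_is_monomorphic()


def _automorphisms(mol: MoleculeGraph, cap: int = 5000):
    """Heavy-atom graph automorphisms under ElementType/BondOrder."""
    cmp = ComparisonTypeConfig("ElementType", "BondOrder")
    h, g = _nx_heavy(mol, cmp)
    matcher = nxiso.GraphMatcher(
        g, g,
        node_match=lambda n1, n2: n1["key"] == n2["key"],
        edge_match=lambda e1, e2: cmp.bonds_match(h, e1["bond"],
                                                  h, e2["bond"]))
    out = []
    for m in matcher.isomorphisms_iter():
        out.append(m)
        if len(out) >= cap:
            import warnings
            warnings.warn("automorphism cap reached; symmetry search truncated")
            break
    return out


def _canonical_key(mol: MoleculeGraph) -> tuple:
    """Morgan-style refinement key of the heavy-atom constitution."""
    h = remove_hydrogens(mol)
    labels = {a.index: (a.element, a.formal_charge) for a in h.atoms}
    for _ in range(max(1, h.n_atoms)):
        new = {}
        for a in h.atoms:
            nb = sorted((labels[bo.other(a.index)], bo.order)
                        for bo in h.bonds_of(a.index))
            new[a.index] = (labels[a.index], tuple(nb))
        if len(set(new.values())) == len(set(labels.values())):
            labels = new
            break
        labels = new
    return tuple(sorted(str(v) for v in labels.values()))


def rmsd(molA: MoleculeGraph, molB: MoleculeGraph,
         remove_h: bool = True) -> float:
    """In-place coordinate RMSD between constitutionally identical molecules
    using identity atom order (no superposition)."""
    A = remove_hydrogens(molA) if remove_h else molA
    B = remove_hydrogens(molB) if remove_h else molB
    if _canonical_key(A) != _canonical_key(B):
        raise ValueError("molecules are not constitutionally identical")
    if A.n_atoms != B.n_atoms:
        raise ValueError("atom count mismatch")
    d = A.coords - B.coords
    return float(np.sqrt(np.mean(np.sum(d * d, axis=1))))


def symmetry_rmsd(molA: MoleculeGraph, molB: MoleculeGraph,
                  remove_h: bool = True, cap: int = 5000) -> float:
    """Minimum in-place RMSD over heavy-atom graph automorphisms."""
    A = remove_hydrogens(molA) if remove_h else molA
    B = remove_hydrogens(molB) if remove_h else molB
    if _canonical_key(A) != _canonical_key(B):
        raise ValueError("molecules are not constitutionally identical")
    autos = _automorphisms(A, cap=cap)
    if not autos:
        return rmsd(A, B, remove_h=False)
    ca, cb = A.coords, B.coords
    best = np.inf
    for m in autos:
        perm = [m[i] for i in range(A.n_atoms)]
        d = ca[perm] - cb
        best = min(best, float(np.sqrt(np.mean(np.sum(d * d, axis=1)))))
    return best


# ---------------------------------------------------------------------------
# rigid superposition and alignment
# ---------------------------------------------------------------------------

def kabsch_superimpose(coordsA: np.ndarray, coordsB: np.ndarray):
    """Least-squares proper rotation + translation mapping B onto A.

    Returns ``(rotation, translation, rmsd)`` such that
    ``coordsB @ rotation.T + translation`` best fits ``coordsA``.
    """
    A = np.asarray(coordsA, dtype=float)
    B = np.asarray(coordsB, dtype=float)
    if A.shape != B.shape or A.shape[0] < 3:
        raise ValueError("need two equal sets of at least 3 points")
    ca, cb = A.mean(axis=0), B.mean(axis=0)
    A0, B0 = A - ca, B - cb
    H = B0.T @ A0
    U, S, Vt = np.linalg.svd(H)
    if S[-1] < 1e-12 and S[-2] < 1e-12:
        raise ValueError("rank-deficient point sets")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = ca - R @ cb
    fit = (R @ B.T).T + t
    err = float(np.sqrt(np.mean(np.sum((fit - A) ** 2, axis=1))))
    return R, t, err


def align_to_scaffold(scaffold: MoleculeGraph, mols,
                      mode: str = "mcs",
                      cmp: ComparisonTypeConfig = DEFAULT_COMPARISON,
                      scaffold_atoms=None, ensemble_atoms=None):
    """Rigidly transform each molecule so its atoms mapped to the scaffold
    (via MCS, the scaffold's largest rigid component, or explicit atom lists)
    superimpose onto the scaffold's.  Internal geometry is unchanged."""
    import warnings
    if mode not in ("mcs", "rigid", "atoms"):
        raise ValueError(f"unknown alignment mode {mode!r}")
    out = []
    for mol in mols:
        if mode == "atoms":
            if scaffold_atoms is None or ensemble_atoms is None or \
                    len(scaffold_atoms) != len(ensemble_atoms):
                raise ValueError("explicit mode needs equal-length atom lists")
            pairs = list(zip(ensemble_atoms, scaffold_atoms))
        else:
            ref = scaffold
            if mode == "rigid":
                ref = _largest_rigid_component(scaffold)
            res = mcs(ref, mol, cmp=cmp, connected=True)
            if res.size < 3:
                warnings.warn(f"molecule {mol.name!r}: common substructure "
                              "below 3 atoms; skipped")
                out.append(mol.copy())
                continue
            pairs = [(b, a) for a, b in res.mapping]  # (mol atom, ref atom)
            if mode == "rigid":
                pass  # ref indexing equals scaffold's rigid component copy
        mol_idx = [p[0] for p in pairs]
        scaf_idx = [p[1] for p in pairs]
        target = (scaffold if mode != "rigid" else
                  _largest_rigid_component(scaffold)).coords[scaf_idx]
        R, t, _ = kabsch_superimpose(target, mol.coords[mol_idx])
        new = mol.copy()
        moved = (R @ new.coords.T).T + t
        for a, c in zip(new.atoms, moved):
            a.coords = c
        out.append(new)
    return out


def _largest_rigid_component(mol: MoleculeGraph) -> MoleculeGraph:
    """Largest fragment after breaking non-ring, non-amide single bonds."""
    h = remove_hydrogens(mol)
    g = nx.Graph()
    g.add_nodes_from(range(h.n_atoms))
    for b in h.bonds:
        if b.order > 1 or b.in_ring or b.amide or b.aromatic:
            g.add_edge(b.a1, b.a2)
    comp = max(nx.connected_components(g), key=len)
    return h.remove_atoms(set(range(h.n_atoms)) - comp)


# ---------------------------------------------------------------------------
# ensemble comparison
# ---------------------------------------------------------------------------

_METHODS = {
    "LargestCommonSubstructureTanimoto":
        lambda a, b: tanimoto(mcs(a, b, connected=True)),
    "LargestCommonDisconnectedSubstructureTanimoto":
        lambda a, b: tanimoto(mcs(a, b, connected=False)),
    "RMSD": rmsd,
    "SymmetryRMSD": symmetry_rmsd,
}


def compare_ensembles(setA, setB=None, method="LargestCommonSubstructureTanimoto",
                      threads: int = 1):
    """Pairwise score matrix.

    One set: full |A| x |A| matrix over ``setA``.  Two sets: |B| x |A| matrix,
    each molecule of the second set compared against the first set.  Failures
    become NaN entries with a warning.  Results are independent of ``threads``
    (kept for interface compatibility; evaluation is sequential and
    deterministic).
    """
    import warnings
    if method not in _METHODS:
        raise ValueError(f"unknown method {method!r}; choose from "
                         f"{sorted(_METHODS)}")
    if threads < 1:
        raise ValueError("threads must be positive")
    fn = _METHODS[method]
    if setB is None:
        n = len(setA)
        out = np.full((n, n), np.nan)
        for i in range(n):
            for j in range(n):
                try:
                    out[i, j] = fn(setA[i], setA[j])
                except Exception as exc:  # noqa: BLE001 - per-pair isolation
                    warnings.warn(f"pair ({i},{j}) failed: {exc}")
        return out
    out = np.full((len(setB), len(setA)), np.nan)
    for i, mb in enumerate(setB):
        for j, ma in enumerate(setA):
            try:
                out[i, j] = fn(ma, mb)
            except Exception as exc:  # noqa: BLE001
                warnings.warn(f"pair ({i},{j}) failed: {exc}")
    return out
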