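"""Molecule-level applications: filter, unique, reorder, split, coordinates.

These mirror the classic command-line workflows: sequentially filter an input
set with per-stage elimination counts, deduplicate at a configurable level of
structural resolution, sort by any descriptor, and decompose molecules into
scaffold/ring/chain fragments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import descriptors as desc
from .graph import MoleculeGraph, connected_components, sssr
from .similarity import (DEFAULT_COMPARISON, ComparisonTypeConfig,
                         _automorphisms, _canonical_key, contains_substructure,
                         kabsch_superimpose, mcs, remove_hydrogens)

__all__ = [
    "FilterCriterion",
    "UniqueLevel",
    "centroid",
    "filter_molecules",
    "recenter",
    "reorder_molecules",
    "split_molecules",
    "unique_molecules",
]


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

_COMPARATORS = {
    "less": lambda a, b: a < b,
    "less_equal": lambda a, b: a <= b,
    "greater": lambda a, b: a > b,
    "greater_equal": lambda a, b: a >= b,
    "equal": lambda a, b: a == b,
}


@dataclass
class FilterCriterion:
    """One filter stage.

    kinds:
      property_compare      -- scalar descriptor vs threshold
      contains_substructure -- every query molecule embeds in the candidate
      contains_fragments_from -- at least one query embeds
      defined_atom_types    -- every atom has a recognized element/valence
      simple_connectivity   -- single connected component
    """
    kind: str = "property_compare"
    property: "desc.DescriptorSpec | str | None" = None
    comparator: str = "less"
    threshold: float = 0.0
    query_molecules: list = field(default_factory=list)
    comparison: ComparisonTypeConfig = field(
        default_factory=lambda: DEFAULT_COMPARISON)

    def __post_init__(self):
        kinds = ("property_compare", "contains_substructure",
                 "contains_fragments_from", "defined_atom_types",
                 "simple_connectivity")
        if self.kind not in kinds:
            raise ValueError(f"unknown criterion kind {self.kind!r}")
        if self.kind == "property_compare":
            if self.property is None:
                raise ValueError("property_compare needs a property")
            if self.comparator not in _COMPARATORS:
                raise ValueError(f"unknown comparator {self.comparator!r}")
            if isinstance(self.property, str):
                self.property = desc.parse_descriptor(self.property)
        elif self.kind in ("contains_substructure",
                           "contains_fragments_from"):
            if not self.query_molecules:
                raise ValueError(f"{self.kind} needs query molecules")

    def matches(self, mol: MoleculeGraph) -> bool:
        if self.kind == "property_compare":
            v = desc.evaluate(self.property, mol)
            if v.shape != (1,):
                raise desc.DescriptorError(
                    f"filter property is not scalar (length {v.size})")
            return bool(_COMPARATORS[self.comparator](float(v[0]),
                                                      self.threshold))
        if self.kind == "contains_substructure":
            return all(contains_substructure(mol, q, self.comparison)
                       for q in self.query_molecules)
        if self.kind == "contains_fragments_from":
            return any(contains_substructure(mol, q, self.comparison)
                       for q in self.query_molecules)
        if self.kind == "defined_atom_types":
            from .graph import validate_atom_types
            return not validate_atom_types(mol)
        return len(connected_components(mol)) == 1


def filter_molecules(mols, criteria, mode: str = "all"):
    """Partition molecules into (matched, unmatched, log).

    mode="all": criteria are applied sequentially; the log records how many
    molecules entered and were removed at each stage (so staged elimination
    counts can be reported).  mode="any": a molecule matches if it satisfies
    at least one criterion.  A descriptor failure routes the molecule to
    unmatched with a logged reason.  Input order is preserved in both output
    lists and matched + unmatched is always a partition of the input.
    """
    if not criteria:
        raise ValueError("criteria must be non-empty")
    if mode not in ("all", "any"):
        raise ValueError(f"unknown mode {mode!r}")
    log = {"stages": [], "errors": []}
    order = {id(m): i for i, m in enumerate(mols)}
    if mode == "all":
        survivors = list(mols)
        rejected = []
        for ci, crit in enumerate(criteria):
            kept = []
            n_in = len(survivors)
            for mol in survivors:
                try:
                    ok = crit.matches(mol)
                except Exception as exc:  # descriptor failure -> unmatched
                    log["errors"].append((mol.name, str(exc)))
                    ok = False
                (kept if ok else rejected).append(mol)
            log["stages"].append(
                {"criterion": ci, "in": n_in, "removed": n_in - len(kept)})
            survivors = kept
        matched = survivors
        unmatched = sorted(rejected, key=lambda m: order[id(m)])
    else:
        matched, unmatched = [], []
        n_match_per = [0] * len(criteria)
        for mol in mols:
            hit = False
            for ci, crit in enumerate(criteria):
                try:
                    if crit.matches(mol):
                        n_match_per[ci] += 1
                        hit = True
                except Exception as exc:
                    log["errors"].append((mol.name, str(exc)))
            (matched if hit else unmatched).append(mol)
        log["stages"] = [{"criterion": ci, "in": len(mols), "matched": n}
                         for ci, n in enumerate(n_match_per)]
    return matched, unmatched, log


# ---------------------------------------------------------------------------
# uniqueness
# ---------------------------------------------------------------------------

@dataclass
class UniqueLevel:
    """Resolution at which two molecules count as the same.

    Constitutions: heavy-atom elements + connectivity + bond orders.
    Configurations: adds stereo (E/Z and tetrahedral parity from coordinates).
    Conformations: adds 3D identity (best-match RMSD < 1e-4 A after rigid
    superposition over heavy-atom automorphisms).
    Exact: serialized structure records compared field-wise.
    dupes_policy: first (keep first occurrence's properties), merge (copy
    missing property keys from duplicates, first value wins), overwrite
    (later duplicate values win).
    """
    level: str = "Constitutions"
    dupes_policy: str = "first"

    def __post_init__(self):
        if self.level not in ("Constitutions", "Configurations",
                              "Conformations", "Exact"):
            raise ValueError(f"unknown level {self.level!r}")
        if self.dupes_policy not in ("first", "merge", "overwrite"):
            raise ValueError(f"unknown dupes policy {self.dupes_policy!r}")


def _constitution_ranks(mol: MoleculeGraph) -> dict:
    """Stable Morgan-refinement rank per heavy atom."""
    labels = {a.index: (a.element, a.formal_charge) for a in mol.atoms}
    for _ in range(mol.n_atoms):
        new = {}
        for a in mol.atoms:
            nb = sorted((labels[b.other(a.index)], b.order, b.aromatic)
                        for b in mol.bonds_of(a.index))
            new[a.index] = (labels[a.index], tuple(nb))
        if len(set(new.values())) == len(set(labels.values())):
            labels = new
            break
        labels = new
    distinct = sorted(set(str(v) for v in labels.values()))
    rank = {s: i for i, s in enumerate(distinct)}
    return {i: rank[str(v)] for i, v in labels.items()}


def _tetrahedral_parities(mol: MoleculeGraph, ranks) -> list:
    out = []
    for a in mol.atoms:
        nbs = mol.neighbors(a.index)
        if len(nbs) not in (3, 4):
            continue
        r = [ranks[n] for n in nbs]
        if len(set(r)) != len(r):
            continue  # not a stereocentre at this resolution
        ordered = [n for _, n in sorted(zip(r, nbs))]
        c = mol.coords
        if len(ordered) == 4:
            v = c[ordered[1:]] - c[ordered[0]]
        else:
            v = c[ordered] - c[a.index]
        det = float(np.linalg.det(v))
        if abs(det) < 1e-6:
            continue  # planar (2D record): parity undefined
        out.append((ranks[a.index], tuple(sorted(r)), int(np.sign(det))))
    return sorted(out)


def _double_bond_geometry(mol: MoleculeGraph, ranks) -> list:
    out = []
    c = mol.coords
    for b in mol.bonds:
        if b.order != 2 or b.aromatic or b.in_ring:
            continue
        n1 = [n for n in mol.neighbors(b.a1) if n != b.a2]
        n2 = [n for n in mol.neighbors(b.a2) if n != b.a1]
        if not n1 or not n2:
            continue
        if len(n1) == 2 and ranks[n1[0]] == ranks[n1[1]]:
            continue
        if len(n2) == 2 and ranks[n2[0]] == ranks[n2[1]]:
            continue
        hi1 = max(n1, key=lambda n: ranks[n])
        hi2 = max(n2, key=lambda n: ranks[n])
        axis = c[b.a2] - c[b.a1]
        u = c[hi1] - c[b.a1]
        v = c[hi2] - c[b.a2]
        axis_n = axis / max(np.linalg.norm(axis), 1e-12)
        up = u - np.dot(u, axis_n) * axis_n
        vp = v - np.dot(v, axis_n) * axis_n
        if np.linalg.norm(up) < 1e-6 or np.linalg.norm(vp) < 1e-6:
            continue
        same_side = float(np.dot(up, vp)) > 0
        key = tuple(sorted((ranks[b.a1], ranks[b.a2])))
        out.append((key, same_side))
    return sorted(out)


def _superposed_rmsd(a: MoleculeGraph, b: MoleculeGraph) -> float:
    """Minimum RMSD over heavy-atom automorphisms after rigid superposition."""
    autos = _automorphisms(a, cap=2000)
    ca, cb = a.coords, b.coords
    best = np.inf
    for m in (autos or [dict(zip(range(a.n_atoms), range(a.n_atoms)))]):
        perm = [m[i] for i in range(a.n_atoms)]
        try:
            _, _, err = kabsch_superimpose(cb, ca[perm])
        except ValueError:
            d = ca[perm] - cb
            err = float(np.sqrt(np.mean(np.sum(d * d, axis=1))))
        best = min(best, err)
    return best


def _exact_record(mol: MoleculeGraph) -> str:
    from .sdf import write_sdf_string
    text = write_sdf_string(mol)
    return text.split("M  END")[0].split("\n", 2)[2]  # drop name/comment


def unique_molecules(mols, config: UniqueLevel | None = None):
    """Deduplicate in input order; returns (unique, dupes)."""
    config = config or UniqueLevel()
    kept: list[MoleculeGraph] = []
    dupes: list[MoleculeGraph] = []
    index: dict = {}          # hash key -> list of positions in kept
    for mol in mols:
        heavy = remove_hydrogens(mol)
        key = _canonical_key(heavy)
        if config.level in ("Configurations", "Conformations"):
            ranks = _constitution_ranks(heavy)
            key = (key, tuple(_tetrahedral_parities(heavy, ranks)),
                   tuple(_double_bond_geometry(heavy, ranks)))
        elif config.level == "Exact":
            key = _exact_record(mol)
        match = None
        for pos in index.get(key, ()):
            if config.level == "Conformations":
                if _superposed_rmsd(remove_hydrogens(kept[pos]),
                                    heavy) < 1e-4:
                    match = pos
                    break
            else:
                match = pos
                break
        if match is None:
            index.setdefault(key, []).append(len(kept))
            kept.append(mol.copy())
        else:
            first = kept[match]
            if config.dupes_policy == "merge":
                for k, v in mol.properties.items():
                    first.properties.setdefault(k, v)
            elif config.dupes_policy == "overwrite":
                first.properties.update(mol.properties)
            dupes.append(mol)
    return kept, dupes


# ---------------------------------------------------------------------------
# reorder
# ---------------------------------------------------------------------------

def reorder_molecules(mols, sort_key, reverse: bool = False,
                      output_max: int | None = None):
    """Stable sort by a scalar descriptor, ascending (descending with
    ``reverse``), optionally truncated to the first ``output_max``."""
    if isinstance(sort_key, str):
        sort_key = desc.parse_descriptor(sort_key)
    keys = []
    for mol in mols:
        v = desc.evaluate(sort_key, mol)
        if v.shape != (1,):
            raise desc.DescriptorError(
                f"molecule {mol.name!r}: sort key is not scalar "
                f"(length {v.size})")
        keys.append(float(v[0]))
    order = sorted(range(len(mols)), key=lambda i: keys[i])
    if reverse:
        # descending but stable: reverse of ascending sort of negated index
        order = sorted(range(len(mols)), key=lambda i: (-keys[i], i))
    out = [mols[i] for i in order]
    if output_max is not None:
        out = out[:output_max]
    return out


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------

def _murcko_atoms(mol: MoleculeGraph) -> set:
    """Heavy atoms of the Murcko framework: rings, ring-ring linkers, and
    atoms double-bonded directly to a framework atom."""
    ring_atoms = {i for ring in sssr(mol) for i in ring}
    if not ring_atoms:
        return set()
    g = mol.to_networkx()
    keep = set(ring_atoms)
    degree = {i: len(mol.neighbors(i)) for i in range(mol.n_atoms)}
    # iteratively prune terminal atoms outside rings
    changed = True
    alive = {a.index for a in mol.atoms if a.element != "H"}
    deg = {i: sum(1 for n in g.neighbors(i) if n in alive) for i in alive}
    while changed:
        changed = False
        for i in sorted(alive):
            if i in ring_atoms or deg[i] > 1:
                continue
            alive.discard(i)
            for n in g.neighbors(i):
                if n in alive:
                    deg[n] -= 1
            changed = True
    keep = alive
    # re-attach atoms double-bonded to a kept ring atom (ring carbonyls)
    for b in mol.bonds:
        if b.order == 2 and not b.aromatic:
            if b.a1 in keep and b.a2 not in keep and b.a1 in ring_atoms \
                    and mol.atoms[b.a2].element != "H":
                keep.add(b.a2)
            elif b.a2 in keep and b.a1 not in keep and b.a2 in ring_atoms \
                    and mol.atoms[b.a1].element != "H":
                keep.add(b.a1)
    return keep


def _extract(mol: MoleculeGraph, atoms: set) -> list:
    """Connected fragments of the subgraph induced on ``atoms``."""
    drop = set(range(mol.n_atoms)) - set(atoms)
    sub = mol.remove_atoms(drop)
    return connected_components(sub) if sub.n_atoms else []


def split_molecules(mol: MoleculeGraph, implementation: str = "Scaffolds",
                    reference: MoleculeGraph | None = None,
                    comparison: ComparisonTypeConfig = DEFAULT_COMPARISON):
    """Decompose one molecule into fragments.

    implementations: Scaffolds (Murcko framework; empty for acyclic input),
    InverseScaffold (what remains after scaffold removal), Rings (ring
    systems), Chains (non-ring components), Isolate (each disconnected
    component), Largest (heaviest component), LargestCommonSubstructure
    (the fragment matched against ``reference``).
    """
    heavy = remove_hydrogens(mol)
    if implementation == "Scaffolds":
        return _extract(heavy, _murcko_atoms(heavy))
    if implementation == "InverseScaffold":
        scaffold = _murcko_atoms(heavy)
        return _extract(heavy, set(range(heavy.n_atoms)) - scaffold)
    if implementation == "Rings":
        ring_atoms = {i for ring in sssr(heavy) for i in ring}
        return _extract(heavy, ring_atoms)
    if implementation == "Chains":
        ring_atoms = {i for ring in sssr(heavy) for i in ring}
        return _extract(heavy, set(range(heavy.n_atoms)) - ring_atoms)
    if implementation == "Isolate":
        return connected_components(heavy)
    if implementation == "Largest":
        parts = connected_components(heavy)
        return [max(parts, key=lambda m: m.molecular_weight())] if parts \
            else []
    if implementation == "LargestCommonSubstructure":
        if reference is None:
            raise ValueError("LargestCommonSubstructure needs a reference")
        res = mcs(heavy, reference, cmp=comparison, connected=True)
        atoms = {a for a, _ in res.mapping}
        return _extract(heavy, atoms)
    raise ValueError(f"unknown split implementation {implementation!r}")


# ---------------------------------------------------------------------------
# coordinates
# ---------------------------------------------------------------------------

def centroid(mol: MoleculeGraph) -> np.ndarray:
    """Unweighted mean of atom coordinates."""
    if mol.n_atoms == 0:
        raise ValueError("empty molecule has no centroid")
    return mol.coords.mean(axis=0)


def recenter(mols):
    """Translate each molecule so its centroid is the origin."""
    single = isinstance(mols, MoleculeGraph)
    if single:
        mols = [mols]
    out = []
    for mol in mols:
        c = centroid(mol)
        new = mol.copy()
        for a in new.atoms:
            a.coords = a.coords - c
        out.append(new)
    return out[0] if single else out
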