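import numpy as np
import pytest

from moltk.apps import (FilterCriterion, UniqueLevel, centroid,
                        filter_molecules, recenter, reorder_molecules,
                        split_molecules, unique_molecules)
from moltk.fixtures import builtin_molecule


def _set(names):
    return [builtin_molecule(n) for n in names]


# -- filter -------------------------------------------------------------------

def test_filter_all_mode_staged_log():
    mols = _set(("benzene", "toluene", "ethanol", "gefitinib", "water"))
    crits = [
        FilterCriterion(property="Weight", comparator="less",
                        threshold=200.0),
        FilterCriterion(kind="contains_substructure",
                        query_molecules=[builtin_molecule("benzene")]),
    ]
    matched, unmatched, log = filter_molecules(mols, crits)
    assert sorted(m.name for m in matched) == ["benzene", "toluene"]
    assert len(matched) + len(unmatched) == len(mols)
    # stage log: gefitinib fails the weight cut, ethanol/water the ring cut
    assert log["stages"][0] == {"criterion": 0, "in": 5, "removed": 1}
    assert log["stages"][1] == {"criterion": 1, "in": 4, "removed": 2}


def test_filter_any_mode():
    mols = _set(("benzene", "ethanol", "gefitinib"))
    crits = [
        FilterCriterion(property="Weight", comparator="greater",
                        threshold=400.0),
        FilterCriterion(kind="contains_fragments_from",
                        query_molecules=[builtin_molecule("benzene")]),
    ]
    matched, unmatched, _ = filter_molecules(mols, crits, mode="any")
    assert sorted(m.name for m in matched) == ["benzene", "gefitinib"]
    assert [m.name for m in unmatched] == ["ethanol"]


def test_filter_simple_connectivity():
    mol = builtin_molecule("ethanol").copy()
    mol.add_atom("O", 0, (9.0, 9.0, 9.0))
    matched, unmatched, _ = filter_molecules(
        [builtin_molecule("ethanol"), mol],
        [FilterCriterion(kind="simple_connectivity")])
    assert len(matched) == 1 and len(unmatched) == 1


def test_filter_validation():
    with pytest.raises(ValueError):
        FilterCriterion(kind="mystery")
    with pytest.raises(ValueError):
        FilterCriterion(property="Weight", comparator="near", threshold=1)
    with pytest.raises(ValueError):
        filter_molecules([], [])


def test_filter_nonscalar_property_routes_to_unmatched():
    crit = FilterCriterion(property="Combine(Weight, LogP)",
                           comparator="less", threshold=100)
    matched, unmatched, log = filter_molecules([builtin_molecule("benzene")],
                                               [crit])
    assert matched == []
    assert len(unmatched) == 1
    assert log["errors"]


# -- unique -------------------------------------------------------------------

def test_unique_constitutions_ignores_conformation():
    a = builtin_molecule("benzene")
    b = builtin_molecule("benzene")
    for at in b.atoms:
        at.coords = tuple(np.asarray(at.coords) + 5.0)
    kept, dupes = unique_molecules([a, b, builtin_molecule("toluene")])
    assert len(kept) == 2
    assert len(dupes) == 1


def test_unique_configurations_distinguishes_enantiomers():
    r = builtin_molecule("stereo_R")
    s = builtin_molecule("stereo_S")
    kept, _ = unique_molecules([r, s])
    assert len(kept) == 1  # same constitution
    kept, _ = unique_molecules([r, s], UniqueLevel("Configurations"))
    assert len(kept) == 2  # opposite parity


def test_unique_conformations_separates_translated_copy():
    a = builtin_molecule("dasatinib_3d")
    b = a.copy()
    for at in b.atoms:
        at.coords = tuple(np.asarray(at.coords) + [1.0, 0.0, 0.0])
    # rigid superposition removes the translation: still one conformer
    kept, _ = unique_molecules([a, b], UniqueLevel("Conformations"))
    assert len(kept) == 1
    c = a.copy()
    mobile = c.heavy_atom_indices()[0]
    c.atoms[mobile].coords = tuple(np.asarray(c.atoms[mobile].coords)
                                   + [3.0, 0.0, 0.0])
    kept, _ = unique_molecules([a, c], UniqueLevel("Conformations"))
    assert len(kept) == 2


def test_unique_merge_policy_copies_missing_properties():
    a = builtin_molecule("benzene")
    a.properties["Source"] = "first"
    b = builtin_molecule("benzene")
    b.properties["Source"] = "second"
    b.properties["Extra"] = "only-on-dup"
    kept, _ = unique_molecules([a, b], UniqueLevel(dupes_policy="merge"))
    assert kept[0].properties["Source"] == "first"
    assert kept[0].properties["Extra"] == "only-on-dup"
    kept, _ = unique_molecules([a, b], UniqueLevel(dupes_policy="overwrite"))
    assert kept[0].properties["Source"] == "second"


# -- reorder ------------------------------------------------------------------

def test_reorder_by_weight():
    mols = _set(("gefitinib", "benzene", "toluene"))
    out = reorder_molecules(mols, "Weight")
    assert [m.name for m in out] == ["benzene", "toluene", "gefitinib"]
    out = reorder_molecules(mols, "Weight", reverse=True, output_max=2)
    assert [m.name for m in out] == ["gefitinib", "toluene"]


def test_reorder_rejects_vector_key():
    from moltk.descriptors import DescriptorError
    with pytest.raises(DescriptorError):
        reorder_molecules(_set(("benzene",)), "Combine(Weight, LogP)")


# -- split --------------------------------------------------------------------

def test_split_scaffold_of_ethylbenzene_is_ring():
    frags = split_molecules(builtin_molecule("ethylbenzene"), "Scaffolds")
    assert len(frags) == 1
    assert frags[0].n_atoms == 6
    inverse = split_molecules(builtin_molecule("ethylbenzene"),
                              "InverseScaffold")
    assert sum(f.n_atoms for f in inverse) == 2


def test_split_acyclic_has_no_scaffold():
    assert split_molecules(builtin_molecule("propane"), "Scaffolds") == []


def test_split_rings_and_chains():
    rings = split_molecules(builtin_molecule("ethylbenzene"), "Rings")
    chains = split_molecules(builtin_molecule("ethylbenzene"), "Chains")
    assert [f.n_atoms for f in rings] == [6]
    assert sum(f.n_atoms for f in chains) == 2


def test_split_isolate_and_largest():
    mol = builtin_molecule("ethanol").copy()
    mol.add_atom("O", 0, (9.0, 9.0, 9.0))
    parts = split_molecules(mol, "Isolate")
    assert sorted(p.n_atoms for p in parts) == [1, 3]
    largest = split_molecules(mol, "Largest")
    assert len(largest) == 1 and largest[0].n_atoms == 3


def test_split_largest_common_substructure():
    frags = split_molecules(builtin_molecule("toluene"),
                            "LargestCommonSubstructure",
                            reference=builtin_molecule("benzene"))
    assert sum(f.n_atoms for f in frags) == 6


def test_split_unknown_implementation():
    with pytest.raises(ValueError):
        split_molecules(builtin_molecule("benzene"), "Halves")


# -- coordinates --------------------------------------------------------------

def test_centroid_and_recenter():
    mol = builtin_molecule("benzene")
    c = centroid(mol)
    moved = recenter(mol)
    np.testing.assert_allclose(centroid(moved), 0.0, atol=1e-12)
    np.testing.assert_allclose(moved.coords + c, mol.coords, atol=1e-12)
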