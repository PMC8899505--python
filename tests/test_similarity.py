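import numpy as np
import pytest
from hypothesis import given, strategies as st

from moltk.fixtures import builtin_molecule, random_molecule
from moltk.graph import remove_hydrogens
from moltk.similarity import (ComparisonTypeConfig, align_to_scaffold,
                              compare_ensembles, contains_substructure,
                              kabsch_superimpose, mcs, rmsd, symmetry_rmsd,
                              tanimoto, tversky)

CMP = ComparisonTypeConfig()


def test_self_similarity_is_one():
    for name in ("benzene", "toluene", "pyridine", "naphthalene"):
        mol = builtin_molecule(name)
        res = mcs(mol, mol, CMP)
        assert res.size == remove_hydrogens(mol).n_atoms
        assert tanimoto(res) == 1.0


def test_mcs_is_symmetric_in_size():
    pairs = [("benzene", "toluene"), ("pyridine", "pyrrole"),
             ("ethanol", "propane"), ("aniline", "naphthalene")]
    for na, nb in pairs:
        A, B = builtin_molecule(na), builtin_molecule(nb)
        assert mcs(A, B, CMP).size == mcs(B, A, CMP).size


def test_benzene_toluene():
    res = mcs(builtin_molecule("benzene"), builtin_molecule("toluene"), CMP)
    assert res.size == 6
    assert tanimoto(res) == pytest.approx(6 / 7)


def test_benzene_vs_cyclohexane_aromatic_mismatch():
    # aromatic bonds only match aromatic bonds at the default bond level
    res = mcs(builtin_molecule("benzene"), builtin_molecule("cyclohexane"),
              CMP)
    assert res.size <= 1


def test_tversky_special_cases():
    res = mcs(builtin_molecule("benzene"), builtin_molecule("toluene"), CMP)
    # alpha = beta = 0.5 is the Dice coefficient
    dice = tversky(res, 0.5, 0.5)
    assert dice == pytest.approx(2 * 6 / (6 + 7))
    # alpha=1, beta=1 recovers Tanimoto
    assert tversky(res, 1.0, 1.0) == pytest.approx(tanimoto(res))


def test_substructure_containment():
    benzene = builtin_molecule("benzene")
    assert contains_substructure(builtin_molecule("toluene"), benzene, CMP)
    assert not contains_substructure(benzene, builtin_molecule("toluene"),
                                     CMP)
    assert not contains_substructure(builtin_molecule("cyclohexane"),
                                     benzene, CMP)


def test_atom_type_level_is_stricter():
    loose = ComparisonTypeConfig("ElementType", "BondOrderOrAromatic")
    strict = ComparisonTypeConfig("AtomType", "BondOrderOrAromatic")
    A = builtin_molecule("gefitinib")
    B = builtin_molecule("afatinib")
    assert mcs(A, B, strict).size <= mcs(A, B, loose).size


def test_rmsd_identity_and_translation():
    mol = builtin_molecule("naphthalene")
    assert rmsd(mol, mol) == pytest.approx(0.0, abs=1e-12)
    moved = mol.copy()
    for a in moved.atoms:
        a.coords = tuple(np.asarray(a.coords) + [1.0, -2.0, 3.0])
    # in-place comparison: no superposition, so both see the translation
    assert rmsd(mol, moved) == pytest.approx(np.sqrt(14), abs=1e-9)
    assert symmetry_rmsd(mol, moved) == pytest.approx(np.sqrt(14), abs=1e-7)


def test_symmetry_rmsd_handles_equivalent_atom_relabeling():
    mol = remove_hydrogens(builtin_molecule("benzene"))
    # same geometry, atoms stored two ring positions over: plain RMSD pairs
    # atom i with atom i+2, symmetry RMSD finds the relabeling.  The shift
    # must be even so the alternating Kekule pattern maps onto itself
    order = list(range(2, mol.n_atoms)) + [0, 1]
    perm = mol.copy()
    inv = {old: new for new, old in enumerate(order)}
    for new, old in enumerate(order):
        perm.atoms[new].element = mol.atoms[old].element
        perm.atoms[new].coords = mol.atoms[old].coords
        perm.atoms[new].aromatic = mol.atoms[old].aromatic
    for b in perm.bonds:
        b.a1, b.a2 = inv[b.a1], inv[b.a2]
    assert rmsd(mol, perm) > 0.5
    assert symmetry_rmsd(mol, perm) == pytest.approx(0.0, abs=1e-7)


def test_kabsch_exact_recovery():
    rng = np.random.default_rng(3)
    P = rng.normal(size=(8, 3))
    theta = 0.7
    R_true = np.array([[np.cos(theta), -np.sin(theta), 0],
                       [np.sin(theta), np.cos(theta), 0],
                       [0, 0, 1.0]])
    Q = (R_true @ P.T).T + np.array([1.0, 2.0, 3.0])
    R, t, err = kabsch_superimpose(P, Q)
    np.testing.assert_allclose((R @ Q.T).T + t, P, atol=1e-10)
    assert err == pytest.approx(0.0, abs=1e-10)


def test_align_to_scaffold_moves_mapped_atoms_onto_scaffold():
    scaffold = builtin_molecule("benzene")
    mol = builtin_molecule("toluene")
    aligned = align_to_scaffold(scaffold, [mol])[0]
    res = mcs(scaffold, aligned, CMP)
    d = [np.linalg.norm(scaffold.coords[a] - aligned.coords[b])
         for a, b in res.mapping]
    assert float(np.mean(d)) < 0.2


def test_compare_ensembles_matrix_shape_and_diagonal():
    mols = [builtin_molecule(n) for n in ("benzene", "toluene", "pyridine")]
    m = compare_ensembles(mols)
    assert m.shape == (3, 3)
    np.testing.assert_allclose(np.diag(m), 1.0)
    np.testing.assert_allclose(m, m.T)

    two = compare_ensembles(mols, [builtin_molecule("aniline")])
    assert two.shape == (1, 3)


@given(st.integers(min_value=0, max_value=60))
def test_random_molecule_self_mcs_total(seed):
    mol = random_molecule(seed, size_range=(2, 8))
    res = mcs(mol, mol, CMP)
    assert res.size == remove_hydrogens(mol).n_atoms
    assert 0.0 <= tanimoto(res) <= 1.0


@given(st.integers(min_value=0, max_value=30),
       st.integers(min_value=31, max_value=60))
def test_random_pair_tanimoto_bounds(sa, sb):
    A = random_molecule(sa, size_range=(2, 7))
    B = random_molecule(sb, size_range=(2, 7))
    res = mcs(A, B, CMP)
    assert 0 <= res.size <= min(res.size_a, res.size_b)
    assert 0.0 <= tanimoto(res) <= 1.0
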