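"""MMP fragmentation, cliff calling, propensity arithmetic and crosstabs."""

import pytest
from rdkit import Chem

from acprop.curation import CuratedInhibitor, pki_from_ki
from acprop.mmp import (CLASS_HIGH, CLASS_LOW, CLASS_NO, CLASS_WITH,
                        assign_class, enumerate_hydrogen_cuts,
                        enumerate_single_cuts, find_mmps, hydrogen_fragment,
                        kinase_propensity, label_cliffs, propensity_pct,
                        transform_crosstab)

NAPHTHYL_ETHYL = "CCc1ccc2ccccc2c1"  # 12 heavy atoms, two valid acyclic cuts
CYCLOPROPYL_NAPHTHALENE = "C1CC1c1ccc2ccccc2c1"  # 13 heavy, exactly one acyclic bond


def inh(mid, smiles, ki, kid="k1"):
    mol = Chem.MolFromSmiles(smiles)
    return CuratedInhibitor(mid, kid, Chem.MolToSmiles(mol), ki, pki_from_ki(ki))


# ---------------------------------------------------------------------------
# fragmentation

def brute_force_cuts(smiles, max_frag=5, min_core=10):
    """Oracle: try every bond, apply both constraints directly."""
    mol = Chem.MolFromSmiles(smiles)
    total = sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() > 1)
    out = set()
    for bond in mol.GetBonds():
        if bond.IsInRing() or bond.GetBondType() != Chem.BondType.SINGLE:
            continue
        pieces = Chem.GetMolFrags(
            Chem.FragmentOnBonds(mol, [bond.GetIdx()], addDummies=True,
                                 dummyLabels=[(0, 0)]),
            asMols=True)
        heavies = [sum(1 for a in p.GetAtoms() if a.GetAtomicNum() > 1) for p in pieces]
        order = sorted(range(2), key=lambda i: -heavies[i])
        core, frag = pieces[order[0]], pieces[order[1]]
        ch, fh = heavies[order[0]], heavies[order[1]]
        if fh <= max_frag and ch >= min_core:
            assert ch + fh == total
            out.add((Chem.MolToSmiles(core), Chem.MolToSmiles(frag), ch, fh))
    return out


@pytest.mark.parametrize("smiles", [
    NAPHTHYL_ETHYL, "CCOc1ccc2ncncc2c1", "CC(C)Cc1ccc(-c2ccccc2)cc1",
    "O=C(C)Nc1ccc2ccccc2c1", "FC(F)(F)c1cccc2cnccc12", "CCCCCCc1ccccc1CC",
    "c1ccc2[nH]c3ccccc3c2c1", "CC(C)(C)OC(=O)N1CCN(c2ccccc2)CC1",
])
def test_fragmentation_matches_brute_force(smiles):
    got = {(c.core, c.fragment, c.core_heavy, c.fragment_heavy)
           for c in enumerate_single_cuts(smiles)}
    assert got == brute_force_cuts(smiles)


def test_fragmentation_trivial_cases():
    assert enumerate_single_cuts("CCO") == []            # 3 heavy atoms
    assert enumerate_single_cuts("c1ccccc1") == []       # all bonds in rings
    cuts = enumerate_single_cuts(CYCLOPROPYL_NAPHTHALENE)
    assert len(cuts) == 1
    assert (cuts[0].core_heavy, cuts[0].fragment_heavy) == (10, 3)


def test_cut_conservation_invariant():
    for smiles in ("CCOc1ccc2ncncc2c1", "CC(C)Cc1ccc(-c2ccccc2)cc1"):
        total = sum(1 for a in Chem.MolFromSmiles(smiles).GetAtoms()
                    if a.GetAtomicNum() > 1)
        for c in enumerate_single_cuts(smiles):
            assert c.core_heavy + c.fragment_heavy == total
            assert c.fragment_heavy <= 5 and c.core_heavy >= 10


def test_hydrogen_cuts():
    cuts = enumerate_hydrogen_cuts("c1ccc2ncncc2c1")
    assert cuts and all(c.fragment == hydrogen_fragment() and c.fragment_heavy == 0
                        for c in cuts)
    assert enumerate_hydrogen_cuts("CCO") == []  # below the core minimum


# ---------------------------------------------------------------------------
# MMP detection

def test_h_to_f_transform_is_an_mmp():
    a = inh("a", "c1ccc2ncncc2c1", 1.0)
    b = inh("b", "Fc1ccc2ncncc2c1", 250.0)
    mmps = find_mmps([a, b])
    assert len(mmps) == 1
    m = mmps[0]
    assert {m.frag_a, m.frag_b} == {hydrogen_fragment(), "*F"}
    assert m.delta_pki == pytest.approx(pki_from_ki(1.0) - pki_from_ki(250.0), abs=1e-12)


def test_identical_molecules_form_no_mmp():
    a = inh("a", NAPHTHYL_ETHYL, 1.0)
    b = inh("b", NAPHTHYL_ETHYL, 100.0)
    assert find_mmps([a, b]) == []


def test_oversized_substituent_is_not_an_mmp():
    a = inh("a", "Cc1ccc2ncncc2c1", 1.0)                  # methyl on the scaffold
    b = inh("b", "c1ccc(-c2ccc3ncncc3c2)cc1", 10.0)       # phenyl: 6 heavy atoms
    assert find_mmps([a, b]) == []


def test_mmp_order_independence_and_transform_symmetry():
    mols = [inh("a", "Cc1ccc2ncncc2c1", 1.0), inh("b", "CCc1ccc2ncncc2c1", 5.0),
            inh("c", "OCc1ccc2ncncc2c1", 80.0)]
    fwd = find_mmps(mols)
    rev = find_mmps(mols[::-1])
    assert {(m.mol_a, m.mol_b, m.core) for m in fwd} == \
        {(m.mol_a, m.mol_b, m.core) for m in rev}
    for m in fwd:
        assert m.transform_key == tuple(sorted((m.frag_a, m.frag_b)))
        assert m.mol_a < m.mol_b


def test_pair_reported_once_with_largest_core():
    # methyl vs ethyl: shareable through the bare scaffold core and through
    # the scaffold+CH2 core; the larger core must win
    a = inh("a", "Cc1ccc2ncncc2c1", 1.0)
    b = inh("b", "CCc1ccc2ncncc2c1", 5.0)
    mmps = find_mmps([a, b])
    assert len(mmps) == 1
    assert mmps[0].core.count("*") == 1
    core_heavy = sum(1 for at in Chem.MolFromSmiles(mmps[0].core).GetAtoms()
                     if at.GetAtomicNum() > 1)
    assert core_heavy == 11  # scaffold (10) + shared CH2
    assert {mmps[0].frag_a, mmps[0].frag_b} == {hydrogen_fragment(), "*C"}


# ---------------------------------------------------------------------------
# cliffs, propensity, classes

def test_cliff_threshold_at_100_fold():
    mk = lambda ki_a, ki_b: find_mmps([inh("a", "Cc1ccc2ncncc2c1", ki_a),
                                       inh("b", "CCc1ccc2ncncc2c1", ki_b)])
    assert label_cliffs(mk(1.0, 250.0))[0].is_cliff          # ratio 250
    assert not label_cliffs(mk(1.0, 50.0))[0].is_cliff       # ratio 50
    assert label_cliffs(mk(0.5, 50.0))[0].is_cliff           # exactly 100-fold


def test_propensity_arithmetic_matches_survey_rows():
    assert round(propensity_pct(858, 24), 1) == 2.8    # ABL1
    assert round(propensity_pct(184, 15), 1) == 8.2    # KIT
    assert round(propensity_pct(54, 1), 1) == 1.9      # ACK1
    assert propensity_pct(100, 0) == 0.0
    assert propensity_pct(0, 0) == 0.0


def test_assign_class_schemes():
    assert assign_class(0.0) == CLASS_NO
    assert assign_class(0.0, "A") == CLASS_NO
    assert assign_class(0.0, "B") == CLASS_NO
    assert assign_class(1.0) == CLASS_LOW          # boundary inclusive
    assert assign_class(1.01) == CLASS_HIGH
    assert assign_class(0.5, "A") == CLASS_WITH
    assert assign_class(2.59, "B") == CLASS_LOW    # boundary inclusive
    assert assign_class(3.0, "B") == CLASS_HIGH
    with pytest.raises(ValueError):
        assign_class(1.0, "Z")


def test_kinase_propensity_counts():
    mols = [inh("a", "Cc1ccc2ncncc2c1", 1.0), inh("b", "CCc1ccc2ncncc2c1", 500.0),
            inh("c", "OCc1ccc2ncncc2c1", 2.0)]
    mmps = label_cliffs(find_mmps(mols))
    prop = kinase_propensity("k1", mmps, len(mols))
    assert prop.n_mmps == 3 and prop.n_acs == 2
    assert prop.acs_over_mmps_pct == pytest.approx(100 * 2 / 3)
    assert prop.n_acs <= prop.n_mmps


# ---------------------------------------------------------------------------
# crosstab

def _mmp(kid, frags, cliff):
    from acprop.mmp import MatchedMolecularPair

    return MatchedMolecularPair("a", "b", kid, "core", frags[0], frags[1],
                                3.0 if cliff else 0.1, cliff)


def test_transform_crosstab_behaviors():
    t = ("F[*]", "[H][*]")
    mmps = [_mmp(f"k{i}", t, i < 2) for i in range(10)]          # AC in 2, not in 8
    mmps += [_mmp("k1", ("C[*]", "O[*]"), True),
             _mmp("k2", ("C[*]", "O[*]"), True)]                 # always AC
    mmps += [_mmp("k1", ("N[*]", "O[*]"), False)]                # single kinase
    tabs = {tab.transform_key: tab for tab in transform_crosstab(mmps)}
    var = tabs[tuple(sorted(t))]
    assert (var.n_ac_kinases, var.n_nonac_kinases, var.behavior) == (2, 8, "varying")
    exc = tabs[("C[*]", "O[*]")]
    assert exc.behavior == "exclusive_AC" and exc.n_nonac_kinases == 0
    assert ("N[*]", "O[*]") not in tabs
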