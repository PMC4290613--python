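"""Fragment descriptor correctness: frozen examples and independent oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from rdkit import Chem

from gqsar.chemistry import CappedFragment, cap_fragment, parse_substituent
from gqsar.dataset import SeriesCompound
from gqsar.descriptors import (ATOMIC_WEIGHTS, chi2, descriptor_block,
                               h_acceptor_count, mol_weight, nitrogens_count,
                               read_descriptor_matrix, slogp,
                               substituent_descriptors,
                               write_descriptor_matrix)
from gqsar.errors import DataError


def sub(smiles, site="R6"):
    return parse_substituent(smiles, site)


# ---------------------------------------------------------------- mol_weight
@pytest.mark.parametrize("smiles, mw", [
    ("[*][S]", 32.065),            # bare sulfur atom
    ("[H]", 1.008),                # hydrogen substituent
    ("[*]C", 15.035),              # methyl: 12.011 + 3×1.008
    ("[*]S", 33.073),              # thiol: S + 1 implicit H
    ("[*]OC", 31.034),             # methoxy / CH3O
    ("[*]F", 18.998),
])
def test_mol_weight_frozen_values(smiles, mw):
    assert mol_weight(sub(smiles)) == pytest.approx(mw, abs=1e-9)


def test_mol_weight_is_additive_over_joined_fragments():
    # joining two fragments by one bond removes one implicit H from each side
    # and adds no atoms, so MW(joined) = MW(A) + MW(B) − 2×MW(H); with the
    # attachment bond already accounted by the dummy the substituent weights
    # of e.g. ethyl equal methyl + CH2
    assert mol_weight(sub("[*]CC")) == pytest.approx(
        mol_weight(sub("[*]C")) + ATOMIC_WEIGHTS["C"] + 2 * ATOMIC_WEIGHTS["H"])
    assert mol_weight(sub("[*]OCC")) == pytest.approx(
        mol_weight(sub("[*]OC")) + ATOMIC_WEIGHTS["C"] + 2 * ATOMIC_WEIGHTS["H"])


# ---------------------------------------------------------------- counts
@pytest.mark.parametrize("smiles, n", [
    ("[*]N", 1), ("[*]C", 0), ("[*]N=NC", 2),
])
def test_nitrogens_count(smiles, n):
    assert nitrogens_count(sub(smiles)) == n


@pytest.mark.parametrize("smiles, acc", [
    ("[*]OC", 1), ("[*]C", 0), ("[*]N(=O)=O", 3), ("[H]", 0),
])
def test_h_acceptor_count_default_rule(smiles, acc):
    assert h_acceptor_count(sub(smiles)) == acc


def test_h_acceptor_strict_rule_excludes_weak_acceptors():
    # pyrrole NH and amide N are excluded under the strict rule
    assert h_acceptor_count(sub("[*]c1cc[nH]c1"), rule="strict") == 0
    assert h_acceptor_count(sub("[*]C(N)=O"), rule="strict") == 1  # carbonyl O only
    with pytest.raises(DataError):
        h_acceptor_count(sub("[*]C"), rule="bogus")


# ---------------------------------------------------------------- chi2
@pytest.mark.parametrize("smiles, value", [
    ("[*][S]", 0.0),                       # single heavy atom: no 2-edge path
    ("[*]CCC", 1 / np.sqrt(2)),            # linear 3-chain (propane graph)
    ("[*]C(C)(C)C", 3 / np.sqrt(3)),       # 3-leaf star (isobutane graph)
])
def test_chi2_frozen_values(smiles, value):
    assert chi2(cap_fragment(sub(smiles))) == pytest.approx(value, abs=1e-9)


def _chi2_bruteforce(mol) -> float:
    """Independent oracle: enumerate every simple 2-edge path explicitly."""
    import networkx as nx

    g = nx.Graph()
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() > 1:
            g.add_node(atom.GetIdx())
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtom(), bond.GetEndAtom()
        if i.GetAtomicNum() > 1 and j.GetAtomicNum() > 1:
            g.add_edge(i.GetIdx(), j.GetIdx())
    total = 0.0
    nodes = list(g.nodes)
    for a in nodes:
        for b in g[a]:
            for c in g[b]:
                if c != a and a < c:  # each simple path once
                    total += (g.degree[a] * g.degree[b] * g.degree[c]) ** -0.5
    return total


def _random_carbon_graph(rng) -> Chem.Mol:
    """Random connected heavy-atom graph (tree + optional extra edge),
    max degree 4, realised as a saturated carbon skeleton."""
    n = int(rng.integers(1, 9))
    mol = Chem.RWMol()
    for _ in range(n):
        mol.AddAtom(Chem.Atom(6))
    degree = [0] * n
    for i in range(1, n):
        candidates = [j for j in range(i) if degree[j] < 4]
        j = int(rng.choice(candidates))
        mol.AddBond(i, j, Chem.BondType.SINGLE)
        degree[i] += 1
        degree[j] += 1
    if n >= 4 and rng.random() < 0.4:
        pairs = [(a, b) for a in range(n) for b in range(a + 1, n)
                 if degree[a] < 4 and degree[b] < 4
                 and mol.GetBondBetweenAtoms(a, b) is None]
        if pairs:
            a, b = pairs[int(rng.integers(len(pairs)))]
            mol.AddBond(a, b, Chem.BondType.SINGLE)
    m = mol.GetMol()
    Chem.SanitizeMol(m)
    return m


def test_chi2_matches_bruteforce_on_random_graphs():
    rng = np.random.default_rng(20240917)
    origin = sub("[H]")
    for _ in range(200):
        mol = _random_carbon_graph(rng)
        frag = CappedFragment(smiles=Chem.MolToSmiles(mol), origin=origin)
        assert chi2(frag) == pytest.approx(_chi2_bruteforce(frag.mol), abs=1e-10)


# ---------------------------------------------------------------- slogp
def test_slogp_methane_value():
    # capped methyl is the methane graph: C1 (0.1441) + 4×H (0.1230) = 0.6361
    assert slogp(cap_fragment(sub("[*]C"))) == pytest.approx(0.6361, abs=1e-4)


def test_slogp_benzene_value():
    origin = sub("[H]")
    frag = CappedFragment(smiles="c1ccccc1", origin=origin)
    assert slogp(frag) == pytest.approx(1.6866, abs=1e-4)


def test_slogp_invariant_under_smiles_rewriting():
    spellings = ["[*]OCc1ccccc1", "[*]OC c1ccccc1".replace(" ", ""),
                 "c1ccccc1CO[*]", "[*]OCc1ccccc1"]
    values = {round(slogp(cap_fragment(sub(s))), 10) for s in spellings}
    assert len(values) == 1


def test_slogp_conserves_atomic_contributions():
    """Whole-fragment SLogP equals the sum of its per-atom contributions."""
    from rdkit.Chem import rdMolDescriptors

    for smiles in ["[*]OC", "[*]Oc1ccccc1", "[*]C(F)(F)F", "[*]N(C)C"]:
        mol = Chem.AddHs(cap_fragment(sub(smiles)).mol)
        contribs = rdMolDescriptors._CalcCrippenContribs(mol)
        assert slogp(cap_fragment(sub(smiles))) == pytest.approx(
            sum(c[0] for c in contribs), abs=1e-9)


# ---------------------------------------------------------------- block
def test_descriptor_block_single_methyl_row():
    comp = SeriesCompound(id="c1", assignment={"R1": sub("[*]C", "R1")}, pic50=5.0)
    block = descriptor_block([comp], ["R1"])
    row = block.loc["c1"]
    assert row["R1-HAcceptorCount"] == 0
    assert row["R1-chi2"] == 0
    assert row["R1-NitrogensCount"] == 0
    assert row["R1-MolecularWeight"] == pytest.approx(15.035)
    assert row["R1-slogp"] == pytest.approx(0.6361, abs=1e-4)


def test_descriptor_block_hydrogen_everywhere():
    comp = SeriesCompound(
        id="c1", assignment={s: sub("[H]", s) for s in ("R4", "R5", "R6")}, pic50=5.0)
    block = descriptor_block([comp], ("R4", "R5", "R6"))
    for site in ("R4", "R5", "R6"):
        assert block.loc["c1", f"{site}-HAcceptorCount"] == 0
        assert block.loc["c1", f"{site}-chi2"] == 0
        assert block.loc["c1", f"{site}-NitrogensCount"] == 0
        assert block.loc["c1", f"{site}-MolecularWeight"] == pytest.approx(1.008)


def test_descriptor_block_order_and_errors():
    c1 = SeriesCompound(id="a", assignment={"R1": sub("[*]C", "R1")}, pic50=5.0)
    c2 = SeriesCompound(id="b", assignment={"R1": sub("[*]F", "R1")}, pic50=5.5)
    b12 = descriptor_block([c1, c2], ["R1"])
    b21 = descriptor_block([c2, c1], ["R1"])
    pd.testing.assert_frame_equal(b12, b21.reindex(b12.index))
    with pytest.raises(DataError, match="no substituent at site"):
        descriptor_block([c1], ["R2"])


def test_descriptor_matrix_roundtrip(tmp_path):
    c1 = SeriesCompound(id="a", assignment={"R1": sub("[*]OC", "R1")}, pic50=5.0)
    block = descriptor_block([c1], ["R1"])
    path = tmp_path / "m.tsv"
    write_descriptor_matrix(block, path)
    back = read_descriptor_matrix(path)
    pd.testing.assert_frame_equal(block, back)
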