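"""Fragment-level 2D descriptors for group QSAR.

Five descriptors per substitution site feed the model:

``HAcceptorCount``
    hydrogen-bond acceptor atoms in the fragment; the default rule counts
    every nitrogen and oxygen, the ``"strict"`` rule excludes classic weak
    acceptors (pyrrole-type NH, amide N, aromatic furan-type O).
``slogp``
    Wildman–Crippen atomic-contribution log P of the hydrogen-capped
    fragment, hydrogens included (computed through RDKit's Crippen module).
``chi2``
    simple second-order molecular connectivity index ²χ of the heavy-atom
    graph: the sum over all two-edge paths i–j–k (i ≠ k) of
    (δi·δj·δk)^(−1/2) with δ the heavy-atom degree.  Zero for fragments with
    fewer than three heavy atoms.
``NitrogensCount``
    number of nitrogen atoms in the fragment.
``MolecularWeight``
    sum of standard atomic weights of the substituent's own atoms, implicit
    hydrogens included, the attachment dummy excluded and no cap added.  The
    weights come from a bundled IUPAC table so values are toolkit-independent.

Molecular weight is the only descriptor computed on the *uncapped*
substituent; the graph/logP descriptors use the hydrogen-capped fragment and
the attachment dummy is never a vertex of the descriptor graph.
"""

from __future__ import annotations

import warnings
from itertools import combinations
from typing import Iterable, Sequence

import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen

from .chemistry import CappedFragment, Substituent, cap_fragment
from .errors import DataError

#: Standard atomic weights (IUPAC 2005 table, 3 decimals), bundled so that
#: MolecularWeight is bit-reproducible and independent of toolkit versions.
ATOMIC_WEIGHTS: dict[str, float] = {
    "H": 1.008, "B": 10.811, "C": 12.011, "N": 14.007, "O": 15.999,
    "F": 18.998, "Na": 22.990, "Mg": 24.305, "Al": 26.982, "Si": 28.086,
    "P": 30.974, "S": 32.065, "Cl": 35.453, "K": 39.098, "Ca": 40.078,
    "Se": 78.96, "Br": 79.904, "I": 126.904,
}

#: Canonical per-site descriptor names, in canonical column order.
DESCRIPTOR_NAMES: tuple[str, ...] = (
    "HAcceptorCount", "slogp", "chi2", "NitrogensCount", "MolecularWeight",
)


def column_name(site_label: str, descriptor: str) -> str:
    """Canonical site-prefixed column name, e.g. ``R6-MolecularWeight``."""
    return f"{site_label}-{descriptor}"


def split_column_name(column: str) -> tuple[str, str]:
    site, _, descriptor = column.partition("-")
    if not site or descriptor not in DESCRIPTOR_NAMES:
        raise DataError(f"not a canonical descriptor column name: {column!r}")
    return site, descriptor


def mol_weight(s: Substituent) -> float:
    """Molecular weight (Da) of the substituent's own atoms, dummy excluded.

    Implicit hydrogens follow SMILES semantics: ``[*]C`` is a methyl
    (15.035 Da) while a bare bracket atom like ``[*][S]`` contributes the
    atomic weight alone (32.065 Da).
    """
    if s.is_hydrogen:
        return ATOMIC_WEIGHTS["H"]
    total = 0.0
    for atom in s.mol.GetAtoms():
        if atom.GetAtomicNum() == 0:
            continue
        symbol = atom.GetSymbol()
        if symbol not in ATOMIC_WEIGHTS:
            raise DataError(f"no bundled atomic weight for element {symbol!r}")
        total += ATOMIC_WEIGHTS[symbol]
        total += atom.GetTotalNumHs() * ATOMIC_WEIGHTS["H"]
    return total


def nitrogens_count(s: Substituent) -> int:
    """Number of nitrogen atoms in the fragment."""
    if s.is_hydrogen:
        return 0
    return sum(1 for a in s.mol.GetAtoms() if a.GetAtomicNum() == 7)


_WEAK_ACCEPTOR_SMARTS = (
    Chem.MolFromSmarts("[nH]"),          # pyrrole-type NH
    Chem.MolFromSmarts("[N;$(NC=O)]"),   # amide nitrogen
    Chem.MolFromSmarts("[o]"),           # furan-type aromatic O
)


def h_acceptor_count(s: Substituent, rule: str = "NO") -> int:
    """Hydrogen-bond acceptor atom count.

    ``rule="NO"`` (default) counts every N and O atom; ``rule="strict"``
    excludes weak acceptors (pyrrole NH, amide N, aromatic O).
    """
    if s.is_hydrogen:
        return 0
    mol = s.mol
    acceptors = {a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() in (7, 8)}
    if rule == "NO":
        return len(acceptors)
    if rule == "strict":
        weak: set[int] = set()
        for patt in _WEAK_ACCEPTOR_SMARTS:
            for match in mol.GetSubstructMatches(patt):
                weak.update(match)
        return len(acceptors - weak)
    raise DataError(f"unknown H-acceptor rule {rule!r}")


def chi2(f: CappedFragment) -> float:
    """Simple second-order connectivity index ²χ of the heavy-atom graph.

    Sum over all simple two-edge paths i–j–k (i ≠ k) of
    (δi·δj·δk)^(−1/2), δ = heavy-atom degree.  Fragments with fewer than
    three heavy atoms have no two-edge path and score 0.
    """
    mol = f.mol
    heavy = [a for a in mol.GetAtoms() if a.GetAtomicNum() > 1]
    if len(heavy) < 3:
        return 0.0
    neighbors: dict[int, list[int]] = {}
    degree: dict[int, int] = {}
    for atom in heavy:
        nbrs = [n.GetIdx() for n in atom.GetNeighbors() if n.GetAtomicNum() > 1]
        neighbors[atom.GetIdx()] = nbrs
        degree[atom.GetIdx()] = len(nbrs)
    total = 0.0
    for j, nbrs in neighbors.items():
        for i, k in combinations(nbrs, 2):
            total += (degree[i] * degree[j] * degree[k]) ** -0.5
    return total


def slogp(f: CappedFragment) -> float:
    """Wildman–Crippen log P of the hydrogen-capped fragment, hydrogens included."""
    mol = Chem.AddHs(f.mol)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return Crippen.MolLogP(mol)


def substituent_descriptors(s: Substituent, acceptor_rule: str = "NO") -> dict[str, float]:
    """All five descriptors of one substituent, unprefixed names."""
    capped = cap_fragment(s)
    return {
        "HAcceptorCount": float(h_acceptor_count(s, acceptor_rule)),
        "slogp": slogp(capped),
        "chi2": chi2(capped),
        "NitrogensCount": float(nitrogens_count(s)),
        "MolecularWeight": mol_weight(s),
    }


def descriptor_block(compounds: Sequence, sites: Iterable[str],
                     acceptor_rule: str = "NO") -> pd.DataFrame:
    """Compounds × site-prefixed descriptor matrix.

    One row per compound (indexed by compound id, input order preserved);
    columns are the five descriptors for every requested site in canonical
    order.  Deterministic: permuting compound order permutes rows only.
    """
    sites = list(sites)
    if not sites:
        raise DataError("at least one site is required")
    columns = [column_name(site, d) for site in sites for d in DESCRIPTOR_NAMES]
    cache: dict[str, dict[str, float]] = {}
    rows, index = [], []
    for comp in compounds:
        row = {}
        for site in sites:
            if site not in comp.assignment:
                raise DataError(f"compound {comp.id!r} has no substituent at site {site!r}")
            sub = comp.assignment[site]
            if sub.smiles not in cache:
                cache[sub.smiles] = substituent_descriptors(sub, acceptor_rule)
            for name, value in cache[sub.smiles].items():
                row[column_name(site, name)] = value
        rows.append(row)
        index.append(comp.id)
    return pd.DataFrame(rows, index=pd.Index(index, name="id"), columns=columns)


def write_descriptor_matrix(df: pd.DataFrame, path) -> None:
    """Write a descriptor matrix as tab-delimited text with a header row."""
    df.to_csv(path, sep="\t", index=True, float_format="%.10g")


def read_descriptor_matrix(path) -> pd.DataFrame:
    """Read a matrix written by :func:`write_descriptor_matrix`."""
    return pd.read_csv(path, sep="\t", index_col="id").astype(float)
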