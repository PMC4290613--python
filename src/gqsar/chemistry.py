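"""Substituent fragments, scaffold templates and molecule assembly.

The structural conventions used throughout the package:

* A substituent is exchanged as SMILES carrying exactly one attachment-point
  dummy atom ``[*]``.  The reserved token ``[H]`` denotes the hydrogen
  substituent (zero heavy atoms).
* A scaffold template is a molecular graph whose substitution sites R1..Rn
  are marked by atom-mapped dummies ``[*:1]`` .. ``[*:n]``.
* Descriptors are computed on the fragment alone, never on the assembled
  molecule — fragment-level (group) descriptors are what make the approach
  site-interpretable.  Graph/logP-type descriptors use the hydrogen-capped
  fragment; see :mod:`gqsar.descriptors`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from rdkit import Chem, RDLogger
from rdkit.Chem import rdmolops

from .errors import AssemblyError, SubstituentError

RDLogger.DisableLog("rdApp.*")

#: Reserved SMILES token for the hydrogen substituent.
HYDROGEN_TOKEN = "[H]"


def _canonical_fragment_smiles(mol: Chem.Mol) -> str:
    return Chem.MolToSmiles(mol)


@dataclass(frozen=True)
class Substituent:
    """One R-group fragment bound for a named substitution site.

    ``smiles`` is canonical and contains exactly one ``[*]`` dummy, except for
    the hydrogen substituent which is stored as the reserved token ``[H]``.
    """

    site_label: str
    smiles: str
    display_name: str = ""

    @property
    def is_hydrogen(self) -> bool:
        return self.smiles == HYDROGEN_TOKEN

    @property
    def mol(self) -> Chem.Mol | None:
        """RDKit molecule with the dummy atom; ``None`` for hydrogen."""
        if self.is_hydrogen:
            return None
        return Chem.MolFromSmiles(self.smiles)

    @property
    def heavy_atom_count(self) -> int:
        if self.is_hydrogen:
            return 0
        return sum(1 for a in self.mol.GetAtoms() if a.GetAtomicNum() > 1)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        name = f" ({self.display_name})" if self.display_name else ""
        return f"{self.site_label}:{self.smiles}{name}"


@dataclass(frozen=True)
class CappedFragment:
    """Substituent with the attachment dummy replaced by an explicit hydrogen.

    This is the canonical form on which graph- and logP-type descriptors are
    computed.  The heavy-atom graph is identical to the substituent's own.
    """

    smiles: str
    origin: Substituent

    @property
    def mol(self) -> Chem.Mol:
        m = Chem.MolFromSmiles(self.smiles, sanitize=True)
        if m is None:  # pragma: no cover - canonical SMILES always re-parse
            raise SubstituentError(f"capped fragment no longer parses: {self.smiles!r}")
        return m

    @property
    def heavy_atom_count(self) -> int:
        return sum(1 for a in self.mol.GetAtoms() if a.GetAtomicNum() > 1)


def parse_substituent(text: str, site_label: str, display_name: str = "") -> Substituent:
    """Parse a substituent SMILES with one attachment dummy into a :class:`Substituent`.

    The reserved token ``[H]`` yields the hydrogen substituent.  Parsing is
    idempotent under canonicalisation: feeding the stored SMILES back returns
    an identical fragment.
    """
    text = text.strip()
    if text == HYDROGEN_TOKEN or text == "H" or text == "":
        return Substituent(site_label=site_label, smiles=HYDROGEN_TOKEN,
                           display_name=display_name or "H")
    mol = Chem.MolFromSmiles(text)
    if mol is None:
        raise SubstituentError(f"unparsable substituent SMILES: {text!r}")
    dummies = [a for a in mol.GetAtoms() if a.GetAtomicNum() == 0]
    if len(dummies) != 1:
        raise SubstituentError(
            f"substituent must carry exactly one attachment dummy, found "
            f"{len(dummies)} in {text!r}"
        )
    dummy = dummies[0]
    if dummy.GetDegree() != 1:
        raise SubstituentError(
            f"attachment dummy must have exactly one bond, found "
            f"{dummy.GetDegree()} in {text!r}"
        )
    if len(rdmolops.GetMolFrags(mol)) != 1:
        raise SubstituentError(f"substituent must be a single connected fragment: {text!r}")
    # normalise: strip any map number off the dummy so equality is structural
    dummy.SetAtomMapNum(0)
    return Substituent(site_label=site_label,
                       smiles=_canonical_fragment_smiles(mol),
                       display_name=display_name)


def cap_fragment(s: Substituent) -> CappedFragment:
    """Replace the attachment dummy by an explicit hydrogen.

    The hydrogen substituent caps to a lone hydrogen atom.  Heavy-atom count
    is unchanged by capping.
    """
    if s.is_hydrogen:
        return CappedFragment(smiles="[H]", origin=s)
    rw = Chem.RWMol(s.mol)
    for atom in rw.GetAtoms():
        if atom.GetAtomicNum() == 0:
            atom.SetAtomicNum(1)
            atom.SetAtomMapNum(0)
            atom.SetNoImplicit(True)
    mol = rw.GetMol()
    Chem.SanitizeMol(mol)
    mol = Chem.RemoveHs(mol)
    return CappedFragment(smiles=Chem.MolToSmiles(mol), origin=s)


@dataclass(frozen=True)
class ScaffoldTemplate:
    """Shared core of a congeneric series with mapped substitution sites.

    ``smiles`` marks each site with an atom-mapped dummy ``[*:k]``; ``sites``
    orders the site labels, label i ↔ map number i+1.
    """

    smiles: str
    sites: tuple[str, ...]

    def __post_init__(self):
        if len(set(self.sites)) != len(self.sites):
            raise AssemblyError("site labels must be unique")
        mol = Chem.MolFromSmiles(self.smiles)
        if mol is None:
            raise AssemblyError(f"unparsable template SMILES: {self.smiles!r}")
        maps = sorted(a.GetAtomMapNum() for a in mol.GetAtoms() if a.GetAtomicNum() == 0)
        if maps != list(range(1, len(self.sites) + 1)):
            raise AssemblyError(
                f"template must carry one mapped dummy per site; found map "
                f"numbers {maps} for {len(self.sites)} sites"
            )

    @property
    def mol(self) -> Chem.Mol:
        return Chem.MolFromSmiles(self.smiles)

    def site_map_number(self, site_label: str) -> int:
        try:
            return self.sites.index(site_label) + 1
        except ValueError:
            raise AssemblyError(f"unknown site label {site_label!r}") from None

    @property
    def core_heavy_atom_count(self) -> int:
        return sum(1 for a in self.mol.GetAtoms() if a.GetAtomicNum() > 1)


#: Bundled arylthioindole scaffold: a 3-(phenylthio)indole core with six
#: marked sites — R1 at indole C2, R2 on the indole nitrogen, R3 at C7,
#: R6 at C5 on the indole core, and R4 (para) / R5 (meta) on the aryl ring.
ARYLTHIOINDOLE = ScaffoldTemplate(
    smiles="[*:2]n1c([*:1])c(Sc2ccc([*:4])c([*:5])c2)c3cc([*:6])cc([*:3])c13",
    sites=("R1", "R2", "R3", "R4", "R5", "R6"),
)


def assemble(template: ScaffoldTemplate, assignment: dict[str, Substituent]) -> Chem.Mol:
    """Attach one substituent per template site and return the molecule.

    Hydrogen substituents cap their site with an (implicit) hydrogen.  The
    output is canonicalizable and deterministic: the same assignment always
    yields the same canonical SMILES.
    """
    missing = [s for s in template.sites if s not in assignment]
    if missing:
        raise AssemblyError(f"unassigned template sites: {missing}")
    extra = [s for s in assignment if s not in template.sites]
    if extra:
        raise AssemblyError(f"assignment names unknown sites: {extra}")

    combo = template.mol
    for site in template.sites:
        sub = assignment[site]
        if sub.is_hydrogen:
            continue
        frag = Chem.MolFromSmiles(sub.smiles)
        for atom in frag.GetAtoms():
            if atom.GetAtomicNum() == 0:
                atom.SetAtomMapNum(template.site_map_number(site))
        combo = Chem.CombineMols(combo, frag)
    try:
        zipped = Chem.molzip(combo)
    except Exception as exc:  # pragma: no cover - molzip rarely raises here
        raise AssemblyError(f"assembly failed: {exc}") from exc

    # hydrogen-cap any remaining site dummies
    rw = Chem.RWMol(zipped)
    for atom in rw.GetAtoms():
        if atom.GetAtomicNum() == 0:
            atom.SetAtomicNum(1)
            atom.SetAtomMapNum(0)
            atom.SetNoImplicit(True)
    mol = rw.GetMol()
    try:
        Chem.SanitizeMol(mol)
    except Exception as exc:
        bad_sites = ", ".join(sorted(assignment))
        raise AssemblyError(
            f"valence violation assembling sites {{{bad_sites}}}: {exc}"
        ) from exc
    return Chem.RemoveHs(mol)


def read_pool_file(path, site_label: str) -> list[Substituent]:
    """Read a substituent pool: one ``SMILES[<TAB>display name]`` per line.

    Blank lines and ``#`` comments are skipped.
    """
    members = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            smiles = parts[0].strip()
            name = parts[1].strip() if len(parts) > 1 else ""
            members.append(parse_substituent(smiles, site_label, name))
    return members
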