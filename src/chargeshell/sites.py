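"""Detection of nucleophilic and electrophilic atomic sites via SMARTS.

Each role (nucleophile / electrophile) carries an ordered pattern table:
specific functional groups first, then generic charge patterns, then generic
multiple-bond / lone-pair patterns. The first pattern that claims an atom
wins, so every ``(atom_index, role)`` pair appears once with its most
specific group label.

Nucleophilic sites are anchored at the atom that donates the electron pair
(carbonyl oxygen for acids/esters/amides/aldehydes/ketones, the alpha-carbon
for enolates, the terminal carbon for isonitriles). Electrophilic sites are
anchored at the atom that accepts it (carbonyl carbon, the beta-carbon of
Michael acceptors, the carbon bonded to an oxonium oxygen).
"""

from __future__ import annotations

from dataclasses import dataclass

from rdkit import Chem

from .molprep import MoleculeRecord, parse_molecule

__all__ = [
    "AtomicSite",
    "NUCLEOPHILE",
    "ELECTROPHILE",
    "find_nucleophilic_sites",
    "find_electrophilic_sites",
    "find_sites",
    "exemplar_panel",
    "Exemplar",
]

NUCLEOPHILE = "nucleophile"
ELECTROPHILE = "electrophile"


@dataclass(frozen=True)
class AtomicSite:
    """An atomic site tagged with its role and functional-group class."""

    atom_index: int
    role: str
    group_label: str
    smiles: str


# (group label, SMARTS, index of the site atom within the match)
# Order encodes label specificity: first claim wins.
_NUCLEOPHILE_PATTERNS: list[tuple[str, str, int]] = [
    ("isonitriles", "[C-]#[N+]", 0),
    ("cyanoalkyl/nitrile anions", "[#6-][CX2]#[NX1]", 0),
    ("enolates", "[CX3]=[CX3][O-]", 0),
    ("nitronates", "[#6]=[NX3+]([O-])[O-]", 0),
    ("carbanions", "[#6-]", 0),
    ("nitranions", "[#7-]", 0),
    ("carboxylic acids", "[OX1]=[CX3][OX2H1]", 0),
    ("esters", "[OX1]=[CX3][OX2][#6]", 0),
    ("amides", "[OX1]=[CX3][NX3]", 0),
    ("aldehydes", "[OX1]=[CX3;H1]", 0),
    ("ketones", "[OX1]=[CX3]([#6])[#6]", 0),
    ("nitriles", "[NX1]#[CX2]", 0),
    ("imines", "[NX2;+0]=[CX3]", 0),
    ("amines", "[NX3;+0;!$([NX3][#6,#16,#15]=[O,S,N,P]);!$([NX3][CX2]#[NX1])]", 0),
    ("ethers", "[OX2;+0;!$([OX2][#6]=[O,S,N])]([#6])[#6]", 0),
    ("anions", "[!#1;-1]", 0),
    ("double/triple-bonded atoms", "[!#1;$([*]=[*]),$([*]#[*]),$([a])]", 0),
    ("lone pairs", "[#7,#8,#16,#15,F,Cl,Br,I;+0]", 0),
]

_ELECTROPHILE_PATTERNS: list[tuple[str, str, int]] = [
    ("acyl halides", "[CX3](=[OX1])[F,Cl,Br,I]", 0),
    ("anhydrides", "[CX3](=[OX1])[OX2][CX3]=[OX1]", 0),
    ("carbamates", "[CX3](=[OX1])([OX2])[NX3]", 0),
    ("esters", "[CX3](=[OX1])[OX2][#6]", 0),
    ("amides", "[CX3](=[OX1])[NX3]", 0),
    ("aldehydes", "[CX3;H1]=[OX1]", 0),
    ("ketones", "[CX3](=[OX1])([#6])[#6]", 0),
    ("Michael acceptors", "[CX3]=[CX3][CX3]=[OX1]", 0),
    ("Michael acceptors", "[CX3]=[CX3][CX2]#[NX1]", 0),
    ("Michael acceptors", "[CX3]=[CX3][NX3+](=[OX1])[O-]", 0),
    ("iminium ions", "[CX3]=[NX3+]", 0),
    ("imines", "[CX3]=[NX2;+0]", 0),
    ("carbocations", "[#6+]", 0),
    ("oxonium ions", "[#6][OX3+]", 0),
    ("boranes", "[BX3;+0]", 0),
    ("cations", "[!#1;+1]", 0),
    ("double/triple-bonded atoms", "[!#1;$([*]=[*]),$([*]#[*]),$([a])]", 0),
]

_ROLE_PATTERNS = {
    NUCLEOPHILE: _NUCLEOPHILE_PATTERNS,
    ELECTROPHILE: _ELECTROPHILE_PATTERNS,
}

_compiled_cache: dict[str, list[tuple[str, Chem.Mol, int]]] = {}


def _compiled(role: str) -> list[tuple[str, Chem.Mol, int]]:
    if role not in _compiled_cache:
        table = []
        for label, smarts, pos in _ROLE_PATTERNS[role]:
            patt = Chem.MolFromSmarts(smarts)
            if patt is None:  # pragma: no cover - guards pattern typos
                raise ValueError(f"bad SMARTS for {label!r}: {smarts}")
            table.append((label, patt, pos))
        _compiled_cache[role] = table
    return _compiled_cache[role]


def find_sites(mol: MoleculeRecord, role: str) -> list[AtomicSite]:
    """Match the role's SMARTS table against a parsed molecule.

    Returns one :class:`AtomicSite` per claimed atom, sorted by atom index;
    duplicate matches collapse onto the most specific group label.
    """
    if role not in _ROLE_PATTERNS:
        raise ValueError(f"unknown role {role!r}")
    m = mol.rdkit_mol
    claimed: dict[int, str] = {}
    for label, patt, pos in _compiled(role):
        for match in m.GetSubstructMatches(patt, uniquify=True):
            idx = match[pos]
            if idx not in claimed:
                claimed[idx] = label
    return [
        AtomicSite(atom_index=i, role=role, group_label=claimed[i], smiles=mol.smiles)
        for i in sorted(claimed)
    ]


def find_nucleophilic_sites(mol: MoleculeRecord) -> list[AtomicSite]:
    """Nucleophilic sites: lone-pair donors, anions, pi systems and the
    named oxygen/nitrogen/carbanion functional groups."""
    return find_sites(mol, NUCLEOPHILE)


def find_electrophilic_sites(mol: MoleculeRecord) -> list[AtomicSite]:
    """Electrophilic sites: carbonyl and related carbons, cations, boranes,
    Michael-acceptor beta-carbons and pi systems."""
    return find_sites(mol, ELECTROPHILE)


@dataclass(frozen=True)
class Exemplar:
    """A hand-written exemplar molecule for one functional-group class.

    ``locator`` is a small SMARTS whose first-atom matches identify the
    expected site atom(s) on the canonical molecule, keeping the fixture
    independent of atom numbering.
    """

    smiles: str
    group_label: str
    locator: str

    def expected_atoms(self, mol: MoleculeRecord) -> set[int]:
        patt = Chem.MolFromSmarts(self.locator)
        return {m[0] for m in mol.rdkit_mol.GetSubstructMatches(patt)}


_NUCLEOPHILE_EXEMPLARS = [
    Exemplar("[CH2-]C#N", "cyanoalkyl/nitrile anions", "[C-]"),
    Exemplar("C=C([O-])C", "enolates", "[CX3H2]=[CX3]"),
    Exemplar("C=[N+]([O-])[O-]", "nitronates", "[CX3H2]"),
    Exemplar("[CH2-]c1ccccc1", "carbanions", "[C-]"),
    Exemplar("c1cc[n-]c1", "nitranions", "[#7-]"),
    Exemplar("CC(=O)O", "carboxylic acids", "[OX1]"),
    Exemplar("CC(=O)OC", "esters", "[OX1]"),
    Exemplar("CC(N)=O", "amides", "[OX1]"),
    Exemplar("CC=O", "aldehydes", "[OX1]"),
    Exemplar("CC(C)=O", "ketones", "[OX1]"),
    Exemplar("C[N+]#[C-]", "isonitriles", "[C-]"),
    Exemplar("CC#N", "nitriles", "[NX1]"),
    Exemplar("CC=NC", "imines", "[NX2]"),
    Exemplar("CN", "amines", "[NX3]"),
    Exemplar("CCOCC", "ethers", "[OX2]"),
    Exemplar("CC[S-]", "anions", "[S-]"),
    Exemplar("C=C", "double/triple-bonded atoms", "[CX3]"),
    Exemplar("CSC", "lone pairs", "[SX2]"),
]

_ELECTROPHILE_EXEMPLARS = [
    Exemplar("CC(Cl)=O", "acyl halides", "[CX3](=[OX1])[Cl]"),
    Exemplar("CC(=O)OC(C)=O", "anhydrides", "[CX3](=[OX1])[OX2]"),
    Exemplar("CNC(=O)OC", "carbamates", "[CX3](=[OX1])([OX2])[NX3]"),
    Exemplar("CC(=O)OC", "esters", "[CX3](=[OX1])[OX2]"),
    Exemplar("CC(N)=O", "amides", "[CX3](=[OX1])[NX3]"),
    Exemplar("CC=O", "aldehydes", "[CX3;H1]=[OX1]"),
    Exemplar("CC(C)=O", "ketones", "[CX3](=[OX1])([#6])[#6]"),
    Exemplar("C=CC(=O)OC", "Michael acceptors", "[CX3H2]=[CX3]"),
    Exemplar("CC=NC", "imines", "[CX3]=[NX2]"),
    Exemplar("C=[N+](C)C", "iminium ions", "[CX3]=[NX3+]"),
    Exemplar("C[C+](C)C", "carbocations", "[C+]"),
    Exemplar("C[O+](C)C", "oxonium ions", "[#6][OX3+]"),
    Exemplar("CB(C)C", "boranes", "[BX3]"),
    Exemplar("[NH4+]", "cations", "[N+]"),
    Exemplar("c1ccccc1", "double/triple-bonded atoms", "[c]"),
]


def exemplar_panel(role: str) -> list[Exemplar]:
    """Hand-curated exemplar molecules, one or more per named class.

    The panel is the coverage test surface for the pattern tables: every
    class named for the role appears with a molecule on which its pattern
    must claim the expected atom.
    """
    if role == NUCLEOPHILE:
        return list(_NUCLEOPHILE_EXEMPLARS)
    if role == ELECTROPHILE:
        return list(_ELECTROPHILE_EXEMPLARS)
    raise ValueError(f"unknown role {role!r}")


def detect(smiles: str, role: str) -> list[AtomicSite]:
    """Convenience wrapper: parse then match."""
    return find_sites(parse_molecule(smiles), role)
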