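"""Molecule preparation: parsing, admission filters, conformers, charges.

The preparation pipeline mirrors the descriptor workflow used to build
atom-centred reactivity models: a SMILES string is canonicalised, hydrogens
are made explicit, ``min(1 + 3 * n_rot, 20)`` conformers are embedded and
optimised with MMFF94s, the lowest-energy conformer is selected and per-atom
partial charges are computed on it.

Two charge backends are exposed:

``gasteiger``
    Geometry-free empirical Gasteiger charges from RDKit. This is the
    default backend: it needs no external engine and is what the test suite
    and the synthetic-data generator use.
``xtb-cm5``
    Charge Model 5 charges extracted from a GFN1-xTB single-point
    calculation on the selected conformer. Requires the ``xtb`` python
    bindings; if they are not importable an :class:`EngineUnavailableError`
    is raised.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem, rdMolDescriptors

logger = logging.getLogger(__name__)

__all__ = [
    "MoleculeRecord",
    "ConformerSet",
    "ChargeVector",
    "MoleculeInputError",
    "ProcessingError",
    "EngineUnavailableError",
    "parse_molecule",
    "admit_for_training",
    "embed_conformers",
    "optimize_and_select",
    "compute_charges",
    "requested_conformer_count",
    "prepare",
]

FALLBACK_BACKEND = "gasteiger"
REFERENCE_BACKEND = "xtb-cm5"

#: hard cap on embedded conformers in descriptor mode
MAX_CONFORMERS = 20
#: conformer count used when reproducing the QM-dataset protocol
QM_DATASET_CONFORMERS = 20


class MoleculeInputError(ValueError):
    """Raised for malformed molecular input (bad SMILES, wrong shapes)."""


class ProcessingError(RuntimeError):
    """Raised when a preparation stage fails (embedding, force field, SCF)."""


class EngineUnavailableError(ProcessingError):
    """Raised when the semiempirical engine backend is requested but absent."""


@dataclass
class ConformerSet:
    """Embedded 3D conformers with force-field energies.

    ``energies`` are MMFF94s energies in kcal/mol once
    :func:`optimize_and_select` has run; ``selected`` indexes the
    lowest-energy conformer (ties broken by lowest index).
    """

    coordinates: list  # list of (n_atoms, 3) float arrays, Angstrom
    energies: list  # kcal/mol
    seed: int
    selected: int = 0

    def __post_init__(self):
        if len(self.coordinates) != len(self.energies):
            raise ValueError("coordinates and energies must have equal length")


@dataclass
class ChargeVector:
    """Per-atom partial charges (elementary charge units) and their backend."""

    values: np.ndarray
    backend: str

    def __len__(self):
        return len(self.values)


@dataclass
class MoleculeRecord:
    """A parsed molecule with explicit hydrogens and derived counts."""

    smiles: str  # canonical
    atoms: list  # (atomic number, formal charge, degree)
    bonds: list  # adjacency pairs (i, j), i < j
    n_rot: int
    n_heavy: int
    total_charge: int
    rdkit_mol: Chem.Mol = field(repr=False, default=None)
    conformers: ConformerSet | None = None
    charges: ChargeVector | None = None

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def neighbors(self, idx: int) -> list:
        return [a.GetIdx() for a in self.rdkit_mol.GetAtomWithIdx(idx).GetNeighbors()]


def parse_molecule(smiles: str) -> MoleculeRecord:
    """Parse a SMILES string into a :class:`MoleculeRecord`.

    The molecule is canonicalised (so atom indices are independent of the
    input spelling) and hydrogens are made explicit.

    Raises
    ------
    MoleculeInputError
        If the SMILES cannot be parsed.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise MoleculeInputError(f"unparsable SMILES: {smiles!r}")
    canonical = Chem.MolToSmiles(mol)
    # re-parse from the canonical string so atom order is spelling-independent
    mol = Chem.MolFromSmiles(canonical)
    n_rot = rdMolDescriptors.CalcNumRotatableBonds(
        mol, rdMolDescriptors.NumRotatableBondsOptions.Strict
    )
    n_heavy = mol.GetNumHeavyAtoms()
    molh = Chem.AddHs(mol)
    atoms = [
        (a.GetAtomicNum(), a.GetFormalCharge(), a.GetDegree())
        for a in molh.GetAtoms()
    ]
    bonds = [
        (b.GetBeginAtomIdx(), b.GetEndAtomIdx()) for b in molh.GetBonds()
    ]
    bonds = [(min(i, j), max(i, j)) for i, j in bonds]
    total_charge = Chem.GetFormalCharge(molh)
    return MoleculeRecord(
        smiles=canonical,
        atoms=atoms,
        bonds=bonds,
        n_rot=n_rot,
        n_heavy=n_heavy,
        total_charge=total_charge,
        rdkit_mol=molh,
    )


def admit_for_training(mol: MoleculeRecord) -> tuple[bool, str]:
    """Dataset admission filter for training molecules.

    Accepts neutral closed-shell molecules with 10-30 heavy atoms and at
    most 24 rotatable bonds. Returns ``(accepted, reason)`` where ``reason``
    names the first violated rule (empty string when accepted).
    """
    if mol.total_charge != 0:
        return False, "not neutral"
    if any(a.GetNumRadicalElectrons() > 0 for a in mol.rdkit_mol.GetAtoms()):
        return False, "open shell"
    if mol.n_heavy < 10:
        return False, "n_heavy < 10"
    if mol.n_heavy > 30:
        return False, "n_heavy > 30"
    if mol.n_rot > 24:
        return False, "n_rot > 24"
    return True, ""


def requested_conformer_count(n_rot: int, mode: str = "descriptor") -> int:
    """Number of conformers to embed: ``min(1 + 3*n_rot, 20)`` in descriptor
    mode, a flat 20 in ``qm_dataset`` mode."""
    if mode == "descriptor":
        return min(1 + 3 * n_rot, MAX_CONFORMERS)
    if mode == "qm_dataset":
        return QM_DATASET_CONFORMERS
    raise ValueError(f"unknown conformer mode: {mode!r}")


def embed_conformers(
    mol: MoleculeRecord, seed: int = 0xF00D, mode: str = "descriptor"
) -> ConformerSet:
    """Embed 3D conformers with the ETKDG distance-geometry method.

    Deterministic for a fixed seed. Up to three embedding attempts with
    incremented seeds are made before giving up.

    Raises
    ------
    ProcessingError
        If embedding fails after retries.
    """
    n_req = requested_conformer_count(mol.n_rot, mode)
    m = Chem.Mol(mol.rdkit_mol)
    for attempt in range(3):
        params = AllChem.ETKDGv3()
        params.randomSeed = int(seed) + attempt
        params.useRandomCoords = attempt > 0
        conf_ids = AllChem.EmbedMultipleConfs(m, numConfs=n_req, params=params)
        if len(conf_ids) > 0:
            break
    else:
        raise ProcessingError(f"conformer embedding failed for {mol.smiles!r}")
    coords = [
        np.asarray(m.GetConformer(cid).GetPositions(), dtype=float)
        for cid in conf_ids
    ]
    if any(not np.all(np.isfinite(c)) for c in coords):
        raise ProcessingError(f"non-finite embedded coordinates for {mol.smiles!r}")
    mol.rdkit_mol = m
    cs = ConformerSet(coordinates=coords, energies=[math.nan] * len(coords), seed=int(seed))
    mol.conformers = cs
    return cs


def optimize_and_select(mol: MoleculeRecord, max_iters: int = 200) -> ConformerSet:
    """MMFF94s-optimise every conformer and select the lowest-energy one.

    Energies are stored in kcal/mol. Ties break toward the lowest conformer
    index via ``argmin``. The conformer count is preserved.

    Raises
    ------
    ProcessingError
        If MMFF parameters are missing for the molecule. Callers that only
        need charges should fall back to the geometry-free backend.
    """
    if mol.conformers is None or len(mol.conformers.coordinates) == 0:
        raise ProcessingError("no embedded conformers to optimize")
    m = mol.rdkit_mol
    if not AllChem.MMFFHasAllMoleculeParams(m):
        raise ProcessingError(
            f"MMFF94s parameters unavailable for {mol.smiles!r}"
        )
    results = AllChem.MMFFOptimizeMoleculeConfs(
        m, mmffVariant="MMFF94s", maxIters=max_iters
    )
    energies = [float(e) for _, e in results]
    coords = [
        np.asarray(m.GetConformer(cid).GetPositions(), dtype=float)
        for cid in range(m.GetNumConformers())
    ]
    cs = mol.conformers
    cs.coordinates = coords
    cs.energies = energies
    cs.selected = int(np.argmin(energies))
    return cs


def _gasteiger_charges(mol: MoleculeRecord) -> np.ndarray:
    m = mol.rdkit_mol
    AllChem.ComputeGasteigerCharges(m)
    q = np.array(
        [float(a.GetProp("_GasteigerCharge")) for a in m.GetAtoms()], dtype=float
    )
    if not np.all(np.isfinite(q)):
        # rare elements outside the Gasteiger parameter table come back NaN
        logger.warning(
            "non-finite Gasteiger charges zeroed for %s", mol.smiles
        )
        q = np.nan_to_num(q, nan=0.0, posinf=0.0, neginf=0.0)
    return q


def _xtb_cm5_charges(mol: MoleculeRecord) -> np.ndarray:
    try:
        from xtb.interface import Calculator  # noqa: F401
        from xtb.utils import get_method
    except ImportError as exc:  # pragma: no cover - engine-gated path
        raise EngineUnavailableError(
            "the xtb python bindings are required for the 'xtb-cm5' backend; "
            "install xtb-python or use backend='gasteiger'"
        ) from exc
    # pragma: no cover - exercised only where the engine is installed
    from xtb.interface import Calculator, Param

    if mol.conformers is None:
        raise ProcessingError("xtb-cm5 backend needs a selected conformer")
    coords_ang = mol.conformers.coordinates[mol.conformers.selected]
    numbers = np.array([z for z, _, _ in mol.atoms])
    bohr = 1.8897259886
    calc = Calculator(
        Param.GFN1xTB, numbers, coords_ang * bohr, charge=float(mol.total_charge)
    )
    res = calc.singlepoint()
    return np.asarray(res.get_charges(), dtype=float)


_BACKENDS = {
    FALLBACK_BACKEND: _gasteiger_charges,
    REFERENCE_BACKEND: _xtb_cm5_charges,
}


def compute_charges(mol: MoleculeRecord, backend: str = FALLBACK_BACKEND) -> ChargeVector:
    """Compute per-atom partial charges, including explicit hydrogens.

    Parameters
    ----------
    backend
        ``"gasteiger"`` (empirical, geometry-free; default) or ``"xtb-cm5"``
        (CM5 charges from a GFN1-xTB single point on the selected conformer).
    """
    try:
        fn = _BACKENDS[backend]
    except KeyError:
        raise MoleculeInputError(
            f"unknown charge backend {backend!r}; choose from {sorted(_BACKENDS)}"
        ) from None
    values = fn(mol)
    if len(values) != mol.n_atoms:
        raise ProcessingError(
            f"backend {backend} returned {len(values)} charges for "
            f"{mol.n_atoms} atoms ({mol.smiles})"
        )
    cv = ChargeVector(values=values, backend=backend)
    mol.charges = cv
    return cv


def prepare(
    smiles: str,
    backend: str = FALLBACK_BACKEND,
    seed: int = 0xF00D,
    embed: bool | None = None,
) -> MoleculeRecord:
    """One-call preparation: parse, (optionally) embed + optimise, charge.

    The geometry pipeline only runs when the backend needs coordinates
    (``embed=None`` auto-selects); the Gasteiger fallback is geometry-free,
    which keeps the descriptor path fast and engine-free.
    """
    mol = parse_molecule(smiles)
    needs_geometry = backend == REFERENCE_BACKEND if embed is None else embed
    if needs_geometry:
        embed_conformers(mol, seed=seed)
        try:
            optimize_and_select(mol)
        except ProcessingError:
            if backend == REFERENCE_BACKEND:
                raise
            logger.warning("MMFF setup failed for %s; using unoptimised geometry", smiles)
    compute_charges(mol, backend=backend)
    return mol
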