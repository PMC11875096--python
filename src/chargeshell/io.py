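"""Reading molecule lists and feature tables from the common text formats."""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from rdkit import Chem

from .molprep import MoleculeInputError

__all__ = ["read_smi", "read_smiles_csv", "read_sdf_smiles", "feature_columns"]


def read_smi(path) -> list[tuple[str, str]]:
    """Read a .smi file: one molecule per line, optional whitespace-separated
    name. Returns ``(smiles, name)`` pairs (name defaults to the SMILES)."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split(None, 1)
        out.append((parts[0], parts[1].strip() if len(parts) > 1 else parts[0]))
    return out


def read_smiles_csv(path, smiles_column: str = "smiles") -> list[str]:
    df = pd.read_csv(path)
    if smiles_column not in df.columns:
        raise MoleculeInputError(
            f"column {smiles_column!r} not found in {path} "
            f"(columns: {list(df.columns)})"
        )
    return df[smiles_column].astype(str).tolist()


def read_sdf_smiles(path) -> list[str]:
    """Read an SDF and return canonical SMILES (first conformer semantics
    are handled downstream when embedding is disabled)."""
    supplier = Chem.SDMolSupplier(str(path), removeHs=False)
    out = []
    for mol in supplier:
        if mol is None:
            continue
        out.append(Chem.MolToSmiles(Chem.RemoveHs(mol)))
    return out


def feature_columns(n: int = 53) -> list[str]:
    return [f"f{i}" for i in range(n)]
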