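"""Molecule records backed by RDKit.

A :class:`MoleculeRecord` couples an identifier with an RDKit molecule and
(optionally) a single 3D conformer.  The record exposes light-weight views
(atoms, bonds, coordinates) so the rest of the package never needs to touch
RDKit objects directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional, Sequence

import numpy as np
from rdkit import Chem
from rdkit import RDLogger

from ..errors import StructureParseError

RDLogger.DisableLog("rdApp.*")  # RDKit is chatty about sanitization on stderr


@dataclass
class MoleculeRecord:
    """A named molecule, optionally with one embedded conformer.

    Attributes
    ----------
    id:
        Stable identifier used to join against concentration tables.
    name:
        Optional human-readable name.
    mol:
        The underlying RDKit molecule.  Explicit hydrogens are added when a
        conformer is embedded; before that hydrogens are implicit.
    """

    id: str
    mol: Chem.Mol
    name: Optional[str] = None

    @classmethod
    def from_smiles(cls, smiles: str, id: str, name: Optional[str] = None) -> "MoleculeRecord":
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise StructureParseError(id, f"invalid SMILES {smiles!r}")
        return cls(id=id, mol=mol, name=name)

    # ------------------------------------------------------------------ views
    @property
    def smiles(self) -> str:
        return Chem.MolToSmiles(self.mol)

    @property
    def atoms(self) -> list[tuple[str, int, int]]:
        """(element, formal charge, bonded-hydrogen count) per atom."""
        return [
            (a.GetSymbol(), a.GetFormalCharge(), a.GetTotalNumHs())
            for a in self.mol.GetAtoms()
        ]

    @property
    def bonds(self) -> list[tuple[tuple[int, int], float, bool]]:
        """((i, j), bond order, in-ring flag) per bond."""
        return [
            ((b.GetBeginAtomIdx(), b.GetEndAtomIdx()), b.GetBondTypeAsDouble(), b.IsInRing())
            for b in self.mol.GetBonds()
        ]

    @property
    def net_charge(self) -> int:
        return Chem.GetFormalCharge(self.mol)

    @property
    def coords3d(self) -> Optional[np.ndarray]:
        """(n_atoms, 3) array in Å, or None if no conformer is embedded."""
        if self.mol.GetNumConformers() == 0:
            return None
        return np.asarray(self.mol.GetConformer().GetPositions(), dtype=float)

    def with_mol(self, mol: Chem.Mol) -> "MoleculeRecord":
        return MoleculeRecord(id=self.id, mol=mol, name=self.name)

    def copy(self) -> "MoleculeRecord":
        return self.with_mol(Chem.Mol(self.mol))


# ---------------------------------------------------------------------- I/O
def read_smi(path: str | Path) -> list[MoleculeRecord]:
    """Read a one-molecule-per-line .smi file: SMILES, whitespace, id [name...].

    Blank lines and lines starting with ``#`` are skipped.
    """
    records: list[MoleculeRecord] = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split(None, 2)
        smiles = parts[0]
        mol_id = parts[1] if len(parts) > 1 else f"line{lineno}"
        name = parts[2] if len(parts) > 2 else None
        records.append(MoleculeRecord.from_smiles(smiles, id=mol_id, name=name))
    return records


def read_sdf(path: str | Path) -> list[MoleculeRecord]:
    """Read a V2000 SDF file; the molecule title (or ``_Name``) is the id."""
    records: list[MoleculeRecord] = []
    supplier = Chem.SDMolSupplier(str(path), removeHs=False)
    for i, mol in enumerate(supplier):
        if mol is None:
            raise StructureParseError(f"sdf-entry-{i + 1}", "unreadable SDF block")
        mol_id = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"sdf-entry-{i + 1}"
        records.append(MoleculeRecord(id=mol_id, mol=mol))
    return records
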