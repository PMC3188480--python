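"""Seeded single-conformer 3D embedding."""

from __future__ import annotations

from rdkit import Chem
from rdkit.Chem import AllChem

from ..errors import EmbeddingError
from .molecule import MoleculeRecord


def embed_3d(record: MoleculeRecord, seed: int = 1) -> MoleculeRecord:
    """Return a copy of *record* with explicit hydrogens and one conformer.

    Uses the ETKDG distance-geometry method with a fixed random seed followed
    by an MMFF94 (falling back to UFF) relaxation, so the same (structure,
    seed) pair always yields identical coordinates.
    """
    mol = Chem.AddHs(Chem.Mol(record.mol))
    if mol.GetNumAtoms() == 1:
        conf = Chem.Conformer(1)
        conf.SetAtomPosition(0, (0.0, 0.0, 0.0))
        mol.AddConformer(conf)
        return record.with_mol(mol)

    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed)
    if AllChem.EmbedMolecule(mol, params) != 0:
        # second chance with random coordinate initialization, still seeded
        params.useRandomCoords = True
        if AllChem.EmbedMolecule(mol, params) != 0:
            raise EmbeddingError(record.id, seed)
    try:
        if AllChem.MMFFHasAllMoleculeParams(mol):
            AllChem.MMFFOptimizeMolecule(mol, maxIters=500)
        else:
            AllChem.UFFOptimizeMolecule(mol, maxIters=500)
    except Exception:
        pass  # an unrelaxed DG conformer is still usable for surface areas
    return record.with_mol(mol)
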