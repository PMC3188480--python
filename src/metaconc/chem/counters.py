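"""Topological descriptor counters: NCA, HBD/HBA/HBI, NRB.

All counters work on the 2D graph of the pH-7 protonated molecule; they are
invariant to atom ordering and to 3D coordinates.  The conventions follow the
Lipinski-style hydrogen-bond inventory and a formal-charge representation of
ionized groups (a carboxylate counts as one charged oxygen).
"""

from __future__ import annotations

from rdkit import Chem

from .molecule import MoleculeRecord

_AMIDE_CN = Chem.MolFromSmarts("[CX3](=O)-[NX3]")


def count_charged_atoms(record: MoleculeRecord) -> int:
    """NCA: atoms with nonzero formal charge, each counted once."""
    return sum(1 for a in record.mol.GetAtoms() if a.GetFormalCharge() != 0)


def hydrogen_bond_inventory(record: MoleculeRecord) -> tuple[int, int, int]:
    """(HBD, HBA, HBI).

    HBD counts hydrogens attached to N or O (water contributes two donors);
    HBA counts N and O heavy atoms, excluding positively charged nitrogens
    whose lone pair is engaged (ammonium, guanidinium imine); HBI is the sum.
    """
    hbd = 0
    hba = 0
    for atom in record.mol.GetAtoms():
        sym = atom.GetSymbol()
        if sym not in ("N", "O"):
            continue
        hbd += atom.GetTotalNumHs()
        if sym == "N" and atom.GetFormalCharge() > 0:
            continue  # no lone pair left to accept
        hba += 1
    return hbd, hba, hbd + hba


def count_rotatable_bonds(record: MoleculeRecord) -> int:
    """NRB: freely rotating single bonds.

    A bond counts when it is a single, non-ring bond between two heavy atoms
    and each end carries at least one additional heavy-atom neighbour
    (i.e. neither end is terminal).  Amide C-N bonds are excluded: their
    partial double-bond character blocks rotation in solution.
    """
    mol = record.mol
    amide_pairs = {
        frozenset((m[0], m[2])) for m in mol.GetSubstructMatches(_AMIDE_CN)
    }
    n = 0
    for bond in mol.GetBonds():
        if bond.GetBondType() != Chem.BondType.SINGLE or bond.IsInRing():
            continue
        a, b = bond.GetBeginAtom(), bond.GetEndAtom()
        if a.GetAtomicNum() <= 1 or b.GetAtomicNum() <= 1:
            continue
        if frozenset((a.GetIdx(), b.GetIdx())) in amide_pairs:
            continue
        if _heavy_degree(a) < 2 or _heavy_degree(b) < 2:
            continue
        n += 1
    return n


def _heavy_degree(atom: Chem.Atom) -> int:
    return sum(1 for nb in atom.GetNeighbors() if nb.GetAtomicNum() > 1)
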