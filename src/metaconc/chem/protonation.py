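"""Rule-based protonation at pH 7.

Metabolite concentrations are measured in near-neutral cytosol, so every
structure is first converted to its majority microspecies at pH 7.  Rather
than a pKa model, a short list of functional-group rules is applied:

* carboxylic acids (pKa ~ 2-5)        -> carboxylate, -1 on the hydroxyl O
* sulfonic acids (pKa < 2)            -> sulfonate, -1
* phosphate P-OH groups (pKa1 ~ 2,
  pKa2 ~ 6.5)                         -> up to two deprotonations per P, so a
                                         phosphate monoester carries -2 and a
                                         phosphodiester -1
* aliphatic primary/secondary/tertiary
  amines (pKa ~ 9-11)                 -> ammonium, +1
* guanidines (pKa ~ 12.5)             -> guanidinium, +1 on the imine N

Aromatic nitrogens (imidazole pKa ~ 6, so histidine stays neutral), amide
nitrogens, anilines, thiols and alcohols are left untouched.  The rules only
match neutral groups, which makes the operation idempotent.
"""

from __future__ import annotations

from rdkit import Chem

from ..errors import StructureParseError
from .molecule import MoleculeRecord

# (name, SMARTS, index of the atom to modify within the match, new charge)
_DEPROTONATION_RULES = [
    ("carboxylic-acid", "[CX3](=O)[OX2H1]", 2, -1),
    ("sulfonic-acid", "[SX4](=O)(=O)[OX2H1]", 3, -1),
]

# aliphatic amine: sp3 N, neutral, not bonded to aromatic ring or to a
# carbon double-bonded to a heteroatom (amides, amidines, guanidine arms),
# not adjacent to S/P oxo groups (sulfonamides, phosphoramides)
_AMINE = Chem.MolFromSmarts(
    "[NX3;H2,H1,H0;+0;!$([N]-[a]);!$([N]-[C]=[O,N,S]);!$([N]-[S,P]=O);!$([N]-[O,N])]"
)
_GUANIDINE = Chem.MolFromSmarts("[NX2;+0;!$([N]-[a])]=[CX3]([NX3;+0])[NX3;+0]")
_PHOSPHATE_OH = Chem.MolFromSmarts("[OX2H1][PX4](=O)")

_COMPILED_DEPROT = [
    (name, Chem.MolFromSmarts(sm), idx, q) for name, sm, idx, q in _DEPROTONATION_RULES
]

# at pH 7 a phosphate group loses at most two protons (pKa3 ~ 12)
_MAX_DEPROTONATIONS_PER_P = 2


def protonate_ph7(record: MoleculeRecord) -> MoleculeRecord:
    """Return a copy of *record* in its majority pH-7 protonation state.

    Idempotent: charged groups produced by the rules no longer match the
    neutral-group patterns, so a second application is a no-op.
    """
    mol = Chem.RWMol(record.mol)

    for _name, patt, idx, charge in _COMPILED_DEPROT:
        for match in mol.GetSubstructMatches(patt):
            mol.GetAtomWithIdx(match[idx]).SetFormalCharge(charge)

    # phosphates: group the acidic oxygens by their phosphorus
    by_p: dict[int, list[int]] = {}
    for o_idx, p_idx, _ in mol.GetSubstructMatches(_PHOSPHATE_OH):
        by_p.setdefault(p_idx, []).append(o_idx)
    for p_idx, oxygens in by_p.items():
        for o_idx in sorted(oxygens)[:_MAX_DEPROTONATIONS_PER_P]:
            mol.GetAtomWithIdx(o_idx).SetFormalCharge(-1)

    for match in mol.GetSubstructMatches(_AMINE):
        mol.GetAtomWithIdx(match[0]).SetFormalCharge(+1)
    for match in mol.GetSubstructMatches(_GUANIDINE):
        mol.GetAtomWithIdx(match[0]).SetFormalCharge(+1)

    out = mol.GetMol()
    try:
        Chem.SanitizeMol(out)
    except Exception as exc:  # pragma: no cover - defensive
        raise StructureParseError(record.id, f"sanitization after protonation: {exc}")
    return record.with_mol(out)
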