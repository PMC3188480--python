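"""Per-metabolite physico-chemical descriptor vectors.

The eight parameters used throughout the concentration analysis:

=====  ==============================================  =====
MW     average molecular mass (implicit H included)    Da
PSA    polar surface area                              Å²
NPSA   non-polar surface area                          Å²
NCA    number of formally charged atoms at pH 7        count
HBI    hydrogen-bond donors + acceptors                count
NRB    rotatable bonds                                 count
LogP   octanol/water partition (externally predicted)  --
LogS   aqueous solubility (externally predicted)       --
=====  ==============================================  =====

LogP and LogS come from external prediction tools and are consumed as input
columns; everything else is computed here from the structure.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional

import pandas as pd
from rdkit.Chem import Descriptors as RDDescriptors

from ..errors import MetaconcError, StructureParseError
from .counters import count_charged_atoms, count_rotatable_bonds, hydrogen_bond_inventory
from .embed import embed_3d
from .molecule import MoleculeRecord
from .protonation import protonate_ph7
from .surface import DEFAULT_N_POINTS, RadiusTable, surface_areas

#: Canonical parameter order used in tables and figures.
PARAMETER_NAMES = ("MW", "PSA", "NPSA", "NCA", "HBI", "NRB", "LogP", "LogS")


@dataclass(frozen=True)
class DescriptorVector:
    """All physico-chemical parameters of one metabolite."""

    id: str
    name: Optional[str]
    mw: float
    total_sa: float
    psa: float
    npsa: float
    nca: int
    hbd: int
    hba: int
    hbi: int
    nrb: int
    logp: Optional[float] = None
    logs: Optional[float] = None

    def __post_init__(self):
        if self.mw <= 0 or self.psa < -1e-9 or self.npsa < -1e-9:
            raise ValueError(f"invalid descriptor values for {self.id!r}")

    def as_row(self) -> dict:
        return {
            "id": self.id,
            "name": self.name,
            "MW": self.mw,
            "PSA": self.psa,
            "NPSA": self.npsa,
            "NCA": self.nca,
            "HBD": self.hbd,
            "HBA": self.hba,
            "HBI": self.hbi,
            "NRB": self.nrb,
            "LogP": self.logp,
            "LogS": self.logs,
        }


def compute_descriptors(
    record: MoleculeRecord,
    external: Optional[Mapping[str, float]] = None,
    radii: Optional[RadiusTable] = None,
    n_points: int = DEFAULT_N_POINTS,
    seed: int = 1,
) -> DescriptorVector:
    """Protonate at pH 7, embed a conformer, and compute all descriptors.

    Parameters
    ----------
    external:
        Optional mapping with ``logp`` / ``logs`` keys holding externally
        predicted values for this metabolite.
    """
    try:
        prot = protonate_ph7(record)
        embedded = embed_3d(prot, seed=seed)
        total, psa, npsa = surface_areas(embedded, radii=radii, n_points=n_points)
        hbd, hba, hbi = hydrogen_bond_inventory(prot)
        external = external or {}
        return DescriptorVector(
            id=record.id,
            name=record.name,
            mw=float(RDDescriptors.MolWt(prot.mol)),
            total_sa=total,
            psa=psa,
            npsa=npsa,
            nca=count_charged_atoms(prot),
            hbd=hbd,
            hba=hba,
            hbi=hbi,
            nrb=count_rotatable_bonds(prot),
            logp=external.get("logp"),
            logs=external.get("logs"),
        )
    except MetaconcError:
        raise
    except Exception as exc:
        raise StructureParseError(record.id, str(exc)) from exc


def descriptor_table(
    records: Iterable[MoleculeRecord],
    external: Optional[Mapping[str, Mapping[str, float]]] = None,
    radii: Optional[RadiusTable] = None,
    n_points: int = DEFAULT_N_POINTS,
    seed: int = 1,
) -> pd.DataFrame:
    """Descriptor table (one row per molecule), indexed by id."""
    external = external or {}
    rows = [
        compute_descriptors(
            rec, external=external.get(rec.id), radii=radii, n_points=n_points, seed=seed
        ).as_row()
        for rec in records
    ]
    return pd.DataFrame(rows).set_index("id")
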