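"""Numerical solvent-accessible surface areas (Shrake-Rupley).

Each atom is inflated by the solvent probe radius and covered with a
deterministic Fibonacci (golden-angle spiral) point lattice.  A lattice point
is *exposed* if it lies strictly outside every other atom's probe-expanded
sphere; points exactly on another sphere count as buried, a deterministic
tie-break.  The atom's accessible area is its exposed point fraction times
the full sphere area 4*pi*(r + probe)^2.

The polar surface area (PSA) is the part of the total contributed by polar
atoms — nitrogen, oxygen, and hydrogens bonded to either — and the non-polar
surface area (NPSA) is the remainder, so PSA + NPSA equals the total exactly
by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..errors import MetaconcError, MissingRadiusError
from .molecule import MoleculeRecord

#: Bondi van-der-Waals radii in Å.
BONDI_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "P": 1.80,
    "S": 1.80,
    "F": 1.47,
    "Cl": 1.75,
    "Br": 1.85,
    "I": 1.98,
}

#: Water-probe radius in Å.
DEFAULT_PROBE = 1.4

#: Lattice points per atom; relative error of an unoccluded sphere is
#: below 1% at this density.
DEFAULT_N_POINTS = 960


@dataclass(frozen=True)
class RadiusTable:
    """Element -> van-der-Waals radius (Å) plus the probe radius (Å)."""

    radii: dict[str, float] = field(default_factory=lambda: dict(BONDI_RADII))
    probe_radius: float = DEFAULT_PROBE

    def __post_init__(self):
        if any(r <= 0 for r in self.radii.values()) or self.probe_radius < 0:
            raise ValueError("radii must be positive and probe radius non-negative")

    def radius(self, element: str) -> float:
        try:
            return self.radii[element]
        except KeyError:
            raise MissingRadiusError(element) from None


def fibonacci_sphere(n: int) -> np.ndarray:
    """(n, 3) quasi-uniform unit vectors on the golden-angle spiral lattice."""
    i = np.arange(n, dtype=float)
    z = 1.0 - 2.0 * (i + 0.5) / n
    theta = np.pi * (1.0 + 5.0**0.5) * i
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])


def polar_atom_flags(record: MoleculeRecord) -> np.ndarray:
    """Boolean flag per atom: N, O, or H bonded to N/O."""
    mol = record.mol
    flags = np.zeros(mol.GetNumAtoms(), dtype=bool)
    for atom in mol.GetAtoms():
        sym = atom.GetSymbol()
        if sym in ("N", "O"):
            flags[atom.GetIdx()] = True
        elif sym == "H":
            if any(nb.GetSymbol() in ("N", "O") for nb in atom.GetNeighbors()):
                flags[atom.GetIdx()] = True
    return flags


def per_atom_areas(
    coords: np.ndarray,
    elements: list[str],
    radii: RadiusTable | None = None,
    n_points: int = DEFAULT_N_POINTS,
) -> np.ndarray:
    """Accessible area in Å² for each atom, given fixed coordinates."""
    radii = radii or RadiusTable()
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3 or coords.shape[0] != len(elements):
        raise ValueError("coords must be (n_atoms, 3) and match the element list")
    expanded = np.array([radii.radius(el) for el in elements]) + radii.probe_radius
    unit = fibonacci_sphere(n_points)
    n = len(elements)
    areas = np.empty(n)
    for i in range(n):
        pts = coords[i] + expanded[i] * unit
        exposed = np.ones(n_points, dtype=bool)
        for j in range(n):
            if j == i:
                continue
            d2 = np.sum((pts - coords[j]) ** 2, axis=1)
            exposed &= d2 > expanded[j] ** 2  # boundary points count as buried
        areas[i] = exposed.mean() * 4.0 * np.pi * expanded[i] ** 2
    return areas


def surface_areas(
    record: MoleculeRecord,
    radii: RadiusTable | None = None,
    n_points: int = DEFAULT_N_POINTS,
) -> tuple[float, float, float]:
    """Return (total_sa, psa, npsa) in Å² for an embedded molecule.

    Requires a 3D conformer (see :func:`metaconc.chem.embed.embed_3d`) with
    explicit hydrogens, since polar hydrogens contribute to the PSA.
    """
    coords = record.coords3d
    if coords is None:
        raise MetaconcError(f"record {record.id!r} has no 3D coordinates")
    if n_points < 100:
        raise ValueError("n_points must be at least 100 for a usable estimate")
    elements = [a.GetSymbol() for a in record.mol.GetAtoms()]
    areas = per_atom_areas(coords, elements, radii=radii, n_points=n_points)
    polar = polar_atom_flags(record)
    total = float(areas.sum())
    psa = float(areas[polar].sum())
    return total, psa, total - psa
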